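"""Shallow feature-based classifier presets.

Thin configuration wrappers over scikit-learn mirroring the shortlisted
shallow models: cubic-kernel SVM, medium-Gaussian SVM (kernel scale 37), and
cosine 10-nearest-neighbours, each one-vs-one where applicable and emitting
class probabilities for ROC analysis.
"""

from __future__ import annotations

from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def cubic_svm(box_constraint: float = 1.0) -> Pipeline:
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="poly", degree=3, C=box_constraint,
            decision_function_shape="ovo", probability=True, random_state=0),
    )


def medium_gaussian_svm(kernel_scale: float = 37.0,
                        box_constraint: float = 1.0) -> Pipeline:
    # sklearn's rbf gamma = 1 / kernel_scale^2
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", gamma=1.0 / kernel_scale**2, C=box_constraint,
            decision_function_shape="ovo", probability=True, random_state=0),
    )


def cosine_knn(n_neighbors: int = 10) -> Pipeline:
    return make_pipeline(
        StandardScaler(),
        KNeighborsClassifier(n_neighbors=n_neighbors, metric="cosine",
                             weights="uniform"),
    )


SHALLOW_PRESETS = {
    "cubic_svm": cubic_svm,
    "medium_gaussian_svm": medium_gaussian_svm,
    "cosine_knn": cosine_knn,
}
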