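"""Similarity-based segment exclusion and age/sex cohort matching.

Segments are embedded from the 1406-dimensional feature space into three
dimensions with t-SNE; each segment is scored by the summed Euclidean
distance to its nearest embedded neighbours (lower = more central), and the
most dissimilar half is excluded. Cohorts are then balanced by matching each
TBI recording to a same-sex Normal and Stroke recording with the smallest
age difference, up to 5 years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .recording import Recording

logger = logging.getLogger(__name__)

TSNE_PERPLEXITY = 30.0
# 1000 gradient steps leave the 3-D embedding visibly unconverged (KL still
# falling, planted outliers not yet peripheral); 3000 converges on the
# problem sizes this package targets.
TSNE_ITER = 3000
DEFAULT_K_NEIGHBORS = 50
MAX_AGE_GAP = 5.0


@dataclass
class SimilarityScore:
    segment_id: str
    embedding: np.ndarray  # 3 reals
    score: float           # summed distance to the k nearest embedded points


@dataclass
class MatchedTriplet:
    anchor_id: str
    normal_id: str | None
    stroke_id: str | None
    anchor_age: float | None = None
    anchor_sex: str | None = None


@dataclass
class MatchedCohort:
    triplets: list[MatchedTriplet] = field(default_factory=list)
    skipped_missing_demographics: int = 0
    dropped_no_match: int = 0


def embed_and_score(
    features: np.ndarray,
    segment_ids: list[str] | None = None,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> list[SimilarityScore]:
    """3-D t-SNE of the feature matrix plus nearest-neighbour distance scores.

    ``k_neighbors`` is capped at n-1; k = n-1 reproduces a literal
    all-neighbours reading of the similarity score. Perplexity is 30, capped
    at (n-1)/3 for small inputs.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 segments for a meaningful embedding")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if segment_ids is None:
        segment_ids = [f"seg{i:06d}" for i in range(n)]
    perplexity = min(TSNE_PERPLEXITY, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=3,
        perplexity=perplexity,
        learning_rate="auto",
        init="pca",
        max_iter=TSNE_ITER,
        random_state=seed,
    )
    emb = tsne.fit_transform(X)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, _ = nn.kneighbors(emb)
    scores = dist[:, 1:].sum(axis=1)  # drop self-distance
    return [
        SimilarityScore(segment_id=sid, embedding=emb[i], score=float(scores[i]))
        for i, sid in enumerate(segment_ids)
    ]


def select_most_similar(
    scores: list[SimilarityScore], keep_fraction: float = 0.5
) -> list[str]:
    """Keep the floor(keep_fraction * n) lowest-scoring segment ids.

    Ties are broken by segment_id order, so the result is deterministic.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n_keep = math.floor(keep_fraction * len(scores))
    ranked = sorted(scores, key=lambda s: (s.score, s.segment_id))
    return [s.segment_id for s in ranked[:n_keep]]


def _eligible(anchor: Recording, pool: list[Recording], max_age_gap: float):
    cands = [
        r for r in pool
        if r.demographics.sex == anchor.demographics.sex
        and r.demographics.age is not None
    ]
    if not cands:
        return []
    gaps = np.array([abs(r.demographics.age - anchor.demographics.age) for r in cands])
    best = gaps.min()
    if best > max_age_gap:
        return []
    return [c for c, g in zip(cands, gaps) if g == best]


def match_cohort(
    anchors: list[Recording],
    pool_normal: list[Recording],
    pool_stroke: list[Recording],
    max_age_gap: float = MAX_AGE_GAP,
    seed: int = 0,
    with_replacement: bool = True,
) -> MatchedCohort:
    """Match each TBI anchor to a same-sex, age-closest Normal and Stroke
    recording (|age difference| <= ``max_age_gap``); equal-minimum ties are
    resolved by seeded uniform random choice. Recordings without age or sex
    are skipped with a logged count. With ``with_replacement`` (default) a
    pool recording may serve several anchors.
    """
    if not pool_normal or not pool_stroke:
        raise ValueError("candidate pools must be non-empty")
    rng = np.random.default_rng(seed)
    cohort = MatchedCohort()
    used_normal: set[str] = set()
    used_stroke: set[str] = set()
    for anchor in anchors:
        d = anchor.demographics
        if d.age is None or d.sex is None:
            cohort.skipped_missing_demographics += 1
            continue
        picks: dict[str, str | None] = {}
        for pool, used in (
            (pool_normal, used_normal),
            (pool_stroke, used_stroke),
        ):
            avail = pool if with_replacement else [
                r for r in pool if r.recording_id not in used
            ]
            ties = _eligible(anchor, avail, max_age_gap)
            if ties:
                pick = ties[int(rng.integers(len(ties)))]
                used.add(pick.recording_id)
            else:
                pick = None
            picks["normal" if pool is pool_normal else "stroke"] = (
                pick.recording_id if pick else None
            )
        if picks.get("normal") is None and picks.get("stroke") is None:
            cohort.dropped_no_match += 1
            logger.info("anchor %s: no eligible match in either pool",
                        anchor.recording_id)
            continue
        if picks.get("normal") is None or picks.get("stroke") is None:
            cohort.dropped_no_match += 1
            logger.info("anchor %s: missing match in one pool", anchor.recording_id)
        cohort.triplets.append(
            MatchedTriplet(
                anchor_id=anchor.recording_id,
                normal_id=picks.get("normal"),
                stroke_id=picks.get("stroke"),
                anchor_age=d.age,
                anchor_sex=d.sex,
            )
        )
    return cohort
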