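"""Weighted-precision thresholding of classifier confidence scores.

Records scoring below a confidence threshold are routed to "Unknown" rather
than being classified. The threshold maximizes the weighted precision

    w_p(s) = (4 p(s) + r(s)) / 5

where p(s) is the precision among retained records and r(s) the proportion
of all true positives that remain retained at score s. Precision dominates
the trade-off 4:1, deliberately favouring a conservative classifier at the
cost of data loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def weighted_precision(p: float, r: float) -> float:
    """(4p + r) / 5, both arguments in [0, 1]."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("p and r must lie in [0, 1]")
    return (4.0 * p + r) / 5.0


@dataclass
class TriageResult:
    threshold: float
    weighted_precision: float
    precision: float
    true_positive_proportion: float
    table: list[dict] = field(default_factory=list)  # per-threshold rows


def select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
    r_over_retained: bool = False,
) -> TriageResult:
    """Pick the confidence threshold maximizing w_p on a grid.

    ``labels`` flags in-category (1) vs out-of-category (0) records. The
    default grid is the set of observed scores plus {0, 1}. Records below
    the threshold are routed to "Unknown"; p is the precision among retained
    records. r is by default the retained share of all true positives;
    ``r_over_retained`` switches to the share of retained records that are
    true positives (an alternative reading of "proportion of true
    positives", equal to p). Ties in w_p resolve toward the higher
    threshold (more conservative retention); thresholds retaining nothing
    are skipped with a log entry.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels disagree in shape")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if grid is None:
        grid = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    else:
        grid = np.unique(np.asarray(grid, dtype=float))
        if np.any((grid < 0) | (grid > 1)):
            raise ValueError("grid thresholds must lie in [0, 1]")

    total_pos = labels.sum()
    table = []
    best = None
    for s in grid:
        retained = scores >= s
        n_ret = int(retained.sum())
        if n_ret == 0:
            logger.info("threshold %.4f retains no records; skipped", s)
            continue
        tp = int((labels & retained).sum())
        p = tp / n_ret
        if r_over_retained:
            r = p
        else:
            r = tp / total_pos if total_pos > 0 else 0.0
        wp = weighted_precision(p, r)
        table.append(
            {"threshold": float(s), "precision": p, "r": r,
             "weighted_precision": wp, "retained": n_ret}
        )
        # ties resolve toward the higher threshold: >= on an ascending grid
        if best is None or wp >= best["weighted_precision"]:
            best = table[-1]
    if best is None:
        raise ValueError("no threshold retained any records")
    return TriageResult(
        threshold=best["threshold"],
        weighted_precision=best["weighted_precision"],
        precision=best["precision"],
        true_positive_proportion=best["r"],
        table=table,
    )
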