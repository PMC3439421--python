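"""Evaluation statistics for suitability surfaces and binary ranges.

Covers presence–background ROC AUC, threshold binarization, the two-way
range-similarity statistic against a reference range, current-vs-future
range change with its gained/lost/stable decomposition, the loser /
non-loser trend label, and Spearman's rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .environment import GridSpec
from .exceptions import EvaluationError
from .maxent import SuitabilitySurface

__all__ = [
    "BinaryRange",
    "RangeComparison",
    "compute_auc",
    "apply_threshold",
    "compare_to_reference",
    "range_change",
    "classify_trend",
    "spearman_rho",
]

log = logging.getLogger(__name__)


@dataclass
class BinaryRange:
    """A presence/absence surface obtained by thresholding (or from truth)."""

    grid: GridSpec
    present: np.ndarray  # bool, False outside valid cells
    threshold_used: float
    area_weighted: float | None = None

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != self.grid.shape:
            raise ValueError("present mask shape does not match grid")

    @property
    def area_cells(self) -> int:
        return int(self.present.sum())


@dataclass
class RangeComparison:
    """Two-way overlap percentages and (optionally) the change decomposition.

    ``similarity`` is the arithmetic mean of the percentage of the predicted
    range lying inside the reference range and the percentage of the
    reference range covered by the prediction.
    """

    pct_predicted_in_reference: float
    pct_reference_covered: float
    similarity: float
    stable_cells: int | None = None
    lost_cells: int | None = None
    gained_cells: int | None = None
    change_in_area: float | None = None


def compute_auc(presence_scores, background_scores) -> float:
    """Presence–background ROC AUC via the Mann–Whitney statistic.

    The fraction of (presence, background) pairs in which the presence
    score outranks the background score, ties counted one half — equal to
    the trapezoidal area under the ROC curve.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise EvaluationError("AUC needs non-empty presence and background scores")
    if not (np.all(np.isfinite(pres)) and np.all(np.isfinite(bg))):
        raise EvaluationError("AUC scores must be finite")
    ranks = rankdata(np.concatenate([pres, bg]))  # midranks
    r_pres = float(ranks[: pres.size].sum())
    m, n = pres.size, bg.size
    u = r_pres - m * (m + 1) / 2.0
    return u / (m * n)


def apply_threshold(surface: SuitabilitySurface, threshold: float) -> BinaryRange:
    """Binarize a suitability surface: present where probability ≥ threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    present = np.zeros(surface.grid.shape, dtype=bool)
    vm = surface.valid_mask
    present[vm] = surface.probability[vm] >= threshold
    return BinaryRange(grid=surface.grid, present=present, threshold_used=threshold)


def _check_grids(a: BinaryRange, b: BinaryRange) -> None:
    if not a.grid.compatible(b.grid):
        raise EvaluationError("binary ranges live on incompatible grids")


def compare_to_reference(predicted: BinaryRange, reference: BinaryRange) -> RangeComparison:
    """Two-way overlap between a predicted range and a reference range.

    Returns the percentage of the predicted range inside the reference, the
    percentage of the reference covered by the prediction, and their mean.
    An empty prediction yields 0/0/0 with a warning (a factorial run must
    not abort); an empty reference is an error.
    """
    _check_grids(predicted, reference)
    n_ref = reference.area_cells
    if n_ref == 0:
        raise EvaluationError("reference range is empty")
    n_pred = predicted.area_cells
    inter = int((predicted.present & reference.present).sum())
    if n_pred == 0:
        log.warning("predicted range is empty; similarity components set to 0")
        pct_in_ref = 0.0
    else:
        pct_in_ref = 100.0 * inter / n_pred
    pct_covered = 100.0 * inter / n_ref
    return RangeComparison(
        pct_predicted_in_reference=pct_in_ref,
        pct_reference_covered=pct_covered,
        similarity=(pct_in_ref + pct_covered) / 2.0,
    )


def range_change(current: BinaryRange, future: BinaryRange) -> RangeComparison:
    """Current-vs-future change: stable/lost/gained cells and percent area change.

    ``change_in_area`` is 100·|future|/|current|, so an unchanged range
    scores 100 and a contraction scores below 100.
    """
    _check_grids(current, future)
    n_cur = current.area_cells
    if n_cur == 0:
        raise EvaluationError("current range is empty; change in area undefined")
    stable = int((current.present & future.present).sum())
    lost = int((current.present & ~future.present).sum())
    gained = int((future.present & ~current.present).sum())
    n_fut = future.area_cells
    inter = stable
    pct_in = 100.0 * inter / n_cur
    pct_cov = 100.0 * inter / n_fut if n_fut else 0.0
    return RangeComparison(
        pct_predicted_in_reference=pct_in,
        pct_reference_covered=pct_cov,
        similarity=(pct_in + pct_cov) / 2.0,
        stable_cells=stable,
        lost_cells=lost,
        gained_cells=gained,
        change_in_area=100.0 * n_fut / n_cur,
    )


def classify_trend(change_in_area: float) -> str:
    """"loser" when the projected future range is smaller than the current one."""
    return "loser" if change_in_area < 100.0 else "non-loser"


def spearman_rho(x, y) -> tuple[float, int]:
    """Spearman's rank correlation: Pearson correlation of midranks.

    Returns ``(rho, n)``.  Constant inputs make the correlation undefined
    and raise :class:`EvaluationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise EvaluationError("vectors must have equal length")
    if x.size < 3:
        raise EvaluationError("Spearman correlation needs at least 3 pairs")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, int(x.size)
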