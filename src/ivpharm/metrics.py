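"""Quantitative comparison of thresholding methods against manual references.

Three complementary segmentation-quality measures are computed against a
manually thresholded reference mask:

* **ME** (misclassification error) — the fraction of pixels whose
  foreground/background assignment disagrees with the reference:
  ``ME = 1 - (|B_o ∩ B_T| + |F_o ∩ F_T|) / (|B_o| + |F_o|)``.
* **TRNU** (total region number nonuniformity) — relative error in the number
  of connected regions: ``|R_T - R_o| / R_o``.
* **VNU** (variance nonuniformity) — relative error of the foreground
  intensity variance: ``|var_T - var_M| / var_M``, variances taken over each
  mask's own foreground pixels (population variances, divide by N).

TRNU and VNU are *adopted forms* (``trnu_def="abs_rel"``,
``vnu_def="rel_var"``): alternative definitions can be slotted in behind the
same interface.

Methods are compared over a set of images by ranking them within each image
(rank 1 = best, mid-ranks on ties), testing the rank table with Friedman's
rank-sums test, and — only where Friedman is significant at p < 0.05 —
running pairwise two-sample Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as _sk_label

from .errors import StructuralError, UndefinedMetricError

__all__ = [
    "MetricReport",
    "misclassification_error",
    "trnu",
    "vnu",
    "count_regions",
    "evaluate_mask",
    "compare_methods",
]

METRICS = ("me", "trnu", "vnu")

TRNU_DEF = "abs_rel"
VNU_DEF = "rel_var"


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=bool)
    if m.ndim != 2:
        raise StructuralError(f"mask must be 2-D, got {m.shape}")
    return m


def misclassification_error(manual: np.ndarray, test: np.ndarray) -> float:
    """Fraction of pixels classified differently from the manual reference.

    0 means perfect agreement, 1 total disagreement.  Symmetric under
    simultaneous complementation of both masks.
    """
    manual, test = _as_mask(manual), _as_mask(test)
    if manual.shape != test.shape:
        raise StructuralError(f"mask shapes differ: {manual.shape} vs {test.shape}")
    agree = int(np.count_nonzero(manual == test))
    return 1.0 - agree / manual.size


def trnu(manual_region_count: int, test_region_count: int) -> float:
    """Relative error in total region number, ``|R_T - R_o| / R_o``."""
    if manual_region_count < 1:
        raise UndefinedMetricError("TRNU undefined: manual mask has no regions")
    if test_region_count < 0:
        raise StructuralError("region counts cannot be negative")
    return abs(test_region_count - manual_region_count) / manual_region_count


def vnu(frame: np.ndarray, manual: np.ndarray, test: np.ndarray) -> float:
    """Relative foreground-variance error, ``|var_T - var_M| / var_M``.

    ``var_M`` is the population variance of the frame over the manual
    foreground; ``var_T`` over the test foreground (0 if the test foreground
    is empty, so a method that finds nothing scores exactly 1).
    """
    frame = np.asarray(frame, dtype=float)
    manual, test = _as_mask(manual), _as_mask(test)
    if not (frame.shape == manual.shape == test.shape):
        raise StructuralError("frame and mask shapes must agree")
    fm = frame[manual]
    if fm.size < 2:
        raise UndefinedMetricError("VNU undefined: manual foreground has < 2 pixels")
    var_m = float(np.var(fm))
    if var_m == 0:
        raise UndefinedMetricError("VNU undefined: manual foreground has zero variance")
    ft = frame[test]
    var_t = float(np.var(ft)) if ft.size else 0.0
    return abs(var_t - var_m) / var_m


def count_regions(mask: np.ndarray) -> int:
    """Number of 8-connected foreground regions (the R of TRNU)."""
    return int(_sk_label(_as_mask(mask), connectivity=2).max())


def evaluate_mask(frame: np.ndarray, manual: np.ndarray | list, test: np.ndarray) -> dict:
    """All three metrics of one test mask against one or more manual references.

    With several reference masks (independent reviewers), each metric is
    averaged over references.
    """
    refs = manual if isinstance(manual, (list, tuple)) else [manual]
    rows = []
    for ref in refs:
        rows.append(
            {
                "me": misclassification_error(ref, test),
                "trnu": trnu(count_regions(ref), count_regions(test)),
                "vnu": vnu(frame, ref, test),
            }
        )
    return {k: float(np.mean([r[k] for r in rows])) for k in METRICS}


@dataclass
class MetricReport:
    """Outcome of a multi-method, multi-image thresholding comparison.

    rows : long table (image_id, method, me, trnu, vnu).
    rank_table : per-metric DataFrame of within-image ranks
        (index = image_id, columns = methods; rank 1 = best).
    friedman : per-metric {"statistic", "p_value"}.
    pairwise : per-metric {(method_a, method_b): p_value}; empty for metrics
        whose Friedman test is not significant at ``alpha``.
    """

    rows: pd.DataFrame
    rank_table: dict[str, pd.DataFrame]
    friedman: dict[str, dict[str, float]]
    pairwise: dict[str, dict[tuple[str, str], float]]
    alpha: float = 0.05

    def mean_ranks(self, metric: str) -> pd.Series:
        return self.rank_table[metric].mean(axis=0)


def friedman_statistic(rank_table: np.ndarray) -> float:
    """Friedman's rank-sums statistic from an (n_images, k_methods) rank table.

    ``chi2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` with ``R_j`` the
    column rank sums.  With mid-ranks an all-tied table gives exactly 0.
    """
    n, k = rank_table.shape
    rank_sums = rank_table.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1))


def compare_methods(rows: pd.DataFrame, alpha: float = 0.05) -> MetricReport:
    """Rank thresholding methods across images and test for differences.

    ``rows`` must be a complete design: one record per (image_id, method)
    with columns ``image_id, method, me, trnu, vnu``.  Within each image and
    metric, methods are ranked ascending (rank 1 = lowest = best, mid-ranks
    on ties).  Friedman's test is applied to each metric's rank table;
    pairwise Wilcoxon rank-sum p-values are reported only for metrics where
    the Friedman p-value is below ``alpha``.
    """
    rows = pd.DataFrame(rows).copy()
    required = {"image_id", "method", *METRICS}
    missing = required - set(rows.columns)
    if missing:
        raise StructuralError(f"rows missing columns: {sorted(missing)}")
    methods = sorted(rows["method"].unique())
    images = sorted(rows["image_id"].unique())
    if len(methods) < 2 or len(images) < 2:
        raise StructuralError("need >= 2 methods and >= 2 images")
    pivot_check = rows.pivot_table(index="image_id", columns="method", values="me", aggfunc="count")
    if pivot_check.isna().any().any() or (pivot_check != 1).any().any():
        raise StructuralError("incomplete design: every method must score every image exactly once")

    rank_table: dict[str, pd.DataFrame] = {}
    friedman: dict[str, dict[str, float]] = {}
    pairwise: dict[str, dict[tuple[str, str], float]] = {}
    k = len(methods)
    for metric in METRICS:
        pivot = rows.pivot(index="image_id", columns="method", values=metric).loc[images, methods]
        ranks = pd.DataFrame(
            np.apply_along_axis(stats.rankdata, 1, pivot.to_numpy()),
            index=pivot.index,
            columns=pivot.columns,
        )
        rank_table[metric] = ranks
        statistic = friedman_statistic(ranks.to_numpy())
        p_value = float(stats.chi2.sf(statistic, k - 1))
        friedman[metric] = {"statistic": statistic, "p_value": p_value}
        pairs: dict[tuple[str, str], float] = {}
        if p_value < alpha:
            for a, b in itertools.combinations(methods, 2):
                res = stats.ranksums(pivot[a].to_numpy(), pivot[b].to_numpy())
                pairs[(a, b)] = float(res.pvalue)
        pairwise[metric] = pairs
    return MetricReport(
        rows=rows, rank_table=rank_table, friedman=friedman, pairwise=pairwise, alpha=alpha
    )
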