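"""Paired nonparametric comparisons with Bonferroni multiplicity control.

Per-participant accuracy values (typically MAPE) are compared between
devices and between conditions with two-sided Wilcoxon signed-rank tests:
exact null distribution for small samples without ties among the nonzero
differences, a tie/zero-corrected normal approximation otherwise.  Zero
differences are dropped (the classic Wilcoxon convention; the dropped
count is logged).  Pairwise device matrices apply a Bonferroni-adjusted
alpha = alpha / C over C = k(k-1)/2 comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonMatrix",
    "wilcoxon_paired",
    "pairwise_device_tests",
    "condition_test",
]

EXACT_N_MAX = 25  # exact signed-rank null up to this n, without ties


def wilcoxon_paired(
    a: Sequence[float],
    b: Sequence[float],
    exact_n_max: int = EXACT_N_MAX,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Pairs with a missing value on either side are dropped; zero differences
    are dropped.  With n <= ``exact_n_max`` usable pairs and no ties among
    the absolute differences the exact null distribution is used, else the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    d = a[ok] - b[ok]
    if d.size < 5:
        raise ValueError(f"need at least 5 complete pairs, got {d.size}")
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("wilcoxon_paired: dropped %d zero differences", n_zero)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("wilcoxon_paired: all differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= exact_n_max and not ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue)


@dataclass(frozen=True)
class ComparisonMatrix:
    """Symmetric pairwise p-value matrix with Bonferroni-adjusted decisions.

    Untestable cells (fewer than 5 complete subject pairs) hold NaN and are
    never significant.  ``n_comparisons`` counts all unordered pairs,
    testable or not, so the adjustment does not depend on data loss.
    """

    labels: tuple[str, ...]
    p_values: pd.DataFrame
    alpha: float
    n_comparisons: int

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values < self.alpha_adjusted

    def to_upper_triangular_csv(self, path) -> None:
        out = self.p_values.copy()
        mask = np.tril(np.ones(out.shape, dtype=bool))
        out = out.mask(mask)
        out.to_csv(path, float_format="%.4f")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "alpha_adjusted": self.alpha_adjusted,
            "p_values": {
                f"{x}|{y}": (None if np.isnan(self.p_values.loc[x, y]) else float(self.p_values.loc[x, y]))
                for i, x in enumerate(self.labels) for y in self.labels[i + 1:]
            },
        }


def pairwise_device_tests(
    values_by_device: Mapping[str, pd.Series],
    alpha: float = 0.05,
) -> ComparisonMatrix:
    """All-pairs Wilcoxon comparisons of per-subject values between devices.

    ``values_by_device`` maps device id -> Series of per-subject values
    indexed by subject id.  Subjects missing either device are dropped per
    comparison (pairwise-complete).  Cells with < 5 usable subjects are
    flagged untestable (NaN, logged).
    """
    labels = tuple(values_by_device)
    if len(labels) < 2:
        raise ValueError("need at least 2 devices to compare")
    k = len(labels)
    n_comparisons = k * (k - 1) // 2
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            sx, sy = values_by_device[x], values_by_device[y]
            common = sx.index.intersection(sy.index)
            ax, ay = sx.loc[common], sy.loc[common]
            usable = (~(ax.isna() | ay.isna())).sum()
            if usable < 5:
                logger.warning("pairwise_device_tests: %s vs %s untestable (%d usable subjects)", x, y, usable)
                p = np.nan
            else:
                p = wilcoxon_paired(ax.to_numpy(), ay.to_numpy())
            pmat.loc[x, y] = pmat.loc[y, x] = p
    return ComparisonMatrix(labels, pmat, float(alpha), n_comparisons)


def condition_test(
    steady: pd.Series, transition: pd.Series
) -> float:
    """Paired test of per-subject accuracy between steady and transition states.

    Series are aligned on subject id; subjects missing either condition are
    dropped.  Returns the two-sided signed-rank p-value.
    """
    common = steady.index.intersection(transition.index)
    if len(common) < len(steady.index.union(transition.index)):
        logger.info("condition_test: %d subjects present in only one condition dropped",
                    len(steady.index.union(transition.index)) - len(common))
    return wilcoxon_paired(steady.loc[common].to_numpy(), transition.loc[common].to_numpy())
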