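"""Replicate aggregation, paired/unpaired nonparametric tests, fold changes,
and the PCR error-propagation extrapolation.

Per-locus error-rate distributions are strongly right-skewed (most loci
sit near a central rate, a few are far above it), so condition contrasts
use rank-based tests on per-locus replicate medians: the Wilcoxon
signed-rank test for locus-wise (paired) shifts and the Mann-Whitney U
test for global median shifts. Cells with no coverage, and cells whose
rate worked out to exactly zero, are mean-imputed from the remaining
non-zero replicates at the same locus and condition before medians are
taken, so sparsely-covered loci are not down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class StatError(ValueError):
    """A test's preconditions are not met; carries a diagnostic message."""


@dataclass
class ConditionMatrix:
    """Locus x replicate rate matrix for one condition."""

    condition: str
    matrix: pd.DataFrame  # index locus, columns replicate labels; NaN = missing
    n_imputed: int = 0

    @property
    def medians(self) -> pd.Series:
        return self.matrix.median(axis=1)


def condition_matrix(totals: pd.DataFrame, condition: str) -> ConditionMatrix:
    """Pivot a per-locus totals table (see rates.locus_totals) for one
    condition into a locus x replicate matrix."""
    sub = totals[totals["condition"] == condition]
    mat = sub.pivot_table(index="locus", columns="replicate", values="rate", aggfunc="first")
    return ConditionMatrix(condition, mat)


def impute_and_median(cm: ConditionMatrix) -> ConditionMatrix:
    """Mean-impute missing and exactly-zero cells per locus.

    Donors are the non-zero, non-missing replicates of the same locus and
    condition; a locus with no donors keeps zeros. Returns a new matrix
    with medians recomputed.
    """
    mat = cm.matrix.to_numpy(dtype=float).copy()
    needs = np.isnan(mat) | (mat == 0.0)
    donors = ~needs
    n_imputed = 0
    for i in range(mat.shape[0]):
        if needs[i].any() and donors[i].any():
            mat[i, needs[i]] = mat[i, donors[i]].mean()
            n_imputed += int(needs[i].sum())
        elif needs[i].all():
            mat[i] = 0.0
    out = pd.DataFrame(mat, index=cm.matrix.index, columns=cm.matrix.columns)
    return ConditionMatrix(cm.condition, out, n_imputed)


def _has_rank_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox") -> float:
    """Two-tailed paired signed-rank p-value for aligned rate vectors.

    Zero differences are dropped by default (``zero_method='pratt'``
    keeps them in the ranking); ties are mid-ranked. The exact null is
    used up to 25 non-zero differences when ranks are unique, otherwise
    the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatError("paired test requires equal-length aligned vectors")
    d = y - x
    nz = d[d != 0]
    if len(nz) < 5:
        raise StatError(
            f"only {len(nz)} non-zero differences; need >= 5 for a meaningful signed-rank test"
        )
    exact = len(nz) <= 25 and not _has_rank_ties(np.abs(nz)) and (zero_method != "pratt" or (d != 0).all())
    res = sps.wilcoxon(
        y,
        x,
        zero_method=zero_method,
        alternative="two-sided",
        correction=True,
        method="exact" if exact else "approx",
    )
    return float(res.pvalue)


def mann_whitney_u(x, y) -> float:
    """Two-tailed Mann-Whitney U p-value for two rate samples.

    Exact enumeration when the smaller sample has <= 10 observations and
    there are no cross-sample ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatError("empty sample")
    pooled = np.concatenate([x, y])
    exact = min(len(x), len(y)) <= 10 and not _has_rank_ties(pooled)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        use_continuity=True,
        method="exact" if exact else "asymptotic",
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class FoldChange:
    mean_ratio: float  # mean over loci of y_l / x_l
    median_ratio: float  # median(y) / median(x)
    n_used: int
    n_skipped: int


def fold_change(x, y) -> FoldChange:
    """Per-locus mean ratio and ratio of overall medians (y relative to x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatError("fold change requires aligned vectors")
    ok = x != 0
    if not ok.any():
        raise StatError("all denominators are zero")
    mean_ratio = float(np.mean(y[ok] / x[ok]))
    med_x = float(np.median(x))
    median_ratio = float(np.median(y) / med_x) if med_x != 0 else float("nan")
    return FoldChange(mean_ratio, median_ratio, int(ok.sum()), int((~ok).sum()))


@dataclass(frozen=True)
class ComparisonResult:
    condition_x: str
    condition_y: str
    test: str
    p: float
    n: int
    fold: FoldChange
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def compare_conditions(
    cm_x: ConditionMatrix,
    cm_y: ConditionMatrix,
    paired: bool = True,
) -> ComparisonResult:
    """Impute, take per-locus medians, test, and compute fold changes.

    Loci are inner-joined; the paired contrast uses the signed-rank test,
    the unpaired one the Mann-Whitney U test.
    """
    ix = impute_and_median(cm_x)
    iy = impute_and_median(cm_y)
    common = ix.matrix.index.intersection(iy.matrix.index)
    mx = ix.medians.loc[common].to_numpy()
    my = iy.medians.loc[common].to_numpy()
    if paired:
        p = wilcoxon_signed_rank(mx, my)
        test = "wilcoxon_signed_rank"
    else:
        p = mann_whitney_u(mx, my)
        test = "mann_whitney_u"
    return ComparisonResult(
        cm_x.condition, cm_y.condition, test, p, len(common), fold_change(mx, my)
    )


def pcr_error_propagation(e: float, length: int, cycles: int) -> np.ndarray:
    """Fraction of templates carrying >= 1 error after each PCR cycle.

    Every base is replicated once per cycle with independent per-base
    per-duplication error probability ``e``, so after c cycles
    F(c) = 1 - (1 - e)^(length * c). Returns F for cycles 0..cycles.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("error rate outside [0, 1]")
    if length < 1 or cycles < 0:
        raise ValueError("length must be >= 1 and cycles >= 0")
    c = np.arange(cycles + 1)
    return 1.0 - np.power(1.0 - e, length * c)
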