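"""Selection-quality measures, with and without access to the true support.

Oracle measures (require the true coefficients): normalized coefficient error
NE = ‖x − x̂‖₂/‖x‖₂, false positive rate, positive predictive value and its
complement the false discovery rate.  Observable measures (computable on real
data): the μP-value — the median two-tailed t-test p-value from regressing
the phenotype on each selected marker in turn — and its threshold-adjusted
variant μ*P-value; plus the proximity-adjusted PPV* that counts a selection
within 500 kb of a reference marker as a true positive.

Degenerate cases (empty selection, all-true support) are reported as NaN
("missing"), never as 0, so failures are not masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._seeds import substream
from .genotypes import GenotypeMatrix, MarkerInfo

__all__ = [
    "SelectionMetrics",
    "ProximityTruthSet",
    "normalized_error",
    "confusion_metrics",
    "marginal_pvalues",
    "mu_pvalue",
    "adjusted_ppv",
    "adjusted_mu_pvalue",
    "max_ld_to_truth",
    "null_adjusted_ppv",
    "evaluate_selection",
]


@dataclass
class SelectionMetrics:
    """All per-experiment selection measures; NaN marks undefined values."""

    ne: float
    fpr: float
    ppv: float
    fdr: float
    mu_pvalue: float
    n_selected: int
    n_true_positive: int


@dataclass(frozen=True)
class ProximityTruthSet:
    """Reference (chromosome, bp) points with a true-positive window.

    A selected marker counts as a true positive iff some reference point
    shares its chromosome and lies within ``window_bp`` basepairs
    (inclusive: |Δbp| ≤ window_bp).
    """

    positions: tuple[tuple[str, int], ...]
    window_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    def contains(self, chromosome: str, bp: int) -> bool:
        return any(
            c == chromosome and abs(b - bp) <= self.window_bp for c, b in self.positions
        )


def normalized_error(x_true: np.ndarray, x_hat: np.ndarray) -> float:
    """NE = ‖x_true − x_hat‖₂ / ‖x_true‖₂."""
    x_true = np.asarray(x_true, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    denom = np.linalg.norm(x_true)
    if denom == 0:
        raise ValueError("NE undefined for an all-zero true coefficient vector")
    return float(np.linalg.norm(x_true - x_hat) / denom)


def confusion_metrics(
    true_support: Iterable[int], selected: Iterable[int], p: int
) -> tuple[float, float, float, int]:
    """(FPR, PPV, FDR, TP count) for a selected index set.

    FPR = |selected \\ true| / (p − |true|); PPV = TP/|selected|; FDR = 1 − PPV.
    PPV and FDR are NaN for an empty selection; FPR is NaN when every marker
    is truly nonzero.
    """
    true_set = set(int(i) for i in true_support)
    sel_set = set(int(i) for i in selected)
    tp = len(sel_set & true_set)
    fp = len(sel_set - true_set)
    n_null = p - len(true_set)
    fpr = fp / n_null if n_null > 0 else math.nan
    if sel_set:
        ppv = tp / len(sel_set)
        fdr = 1.0 - ppv
    else:
        ppv = math.nan
        fdr = math.nan
    return fpr, ppv, fdr, tp


def marginal_pvalues(
    A: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Two-tailed t-test p-values from univariate regressions of y on markers.

    Each marker is tested in a simple linear regression with intercept; the
    p-value is the two-tailed tail probability of the slope t statistic on
    n − 2 degrees of freedom.  Constant columns get p = 1.
    """
    M = A.standardized if isinstance(A, GenotypeMatrix) else np.asarray(A, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = M.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a t test")
    if indices is not None:
        M = M[:, np.asarray(indices, dtype=np.int64)]
    xc = M - M.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc**2, axis=0)
    syy = float(np.sum(yc**2))
    sxy = xc.T @ yc
    const = sxx <= 0
    sxx_safe = np.where(const, 1.0, sxx)
    r2 = np.where(syy > 0, sxy**2 / (sxx_safe * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    # t^2 = (n-2) r^2 / (1 - r^2); survival function handles r^2 -> 1
    with np.errstate(divide="ignore"):
        tstat = np.sqrt((n - 2) * r2 / np.maximum(1.0 - r2, 1e-300))
    pvals = 2.0 * stats.t.sf(tstat, df=n - 2)
    pvals = np.where(const, 1.0, np.clip(pvals, 0.0, 1.0))
    return pvals


def mu_pvalue(pvals: np.ndarray) -> float:
    """Median p-value over the selected markers (NaN for an empty set).

    For an even count, the mean of the two central order statistics.
    """
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return math.nan
    return float(np.median(pvals))


def adjusted_ppv(
    selected_markers: Sequence[MarkerInfo | tuple[str, int]],
    truth: ProximityTruthSet,
) -> float:
    """PPV* — proximity-adjusted precision against a reference position set."""
    if len(selected_markers) == 0:
        return math.nan
    tp = 0
    for m in selected_markers:
        chrom, bp = (m.chromosome, m.bp_position) if isinstance(m, MarkerInfo) else m
        if truth.contains(str(chrom), int(bp)):
            tp += 1
    return tp / len(selected_markers)


def adjusted_mu_pvalue(pvals: np.ndarray, threshold: float) -> float:
    """μ*P-value — median of the p-values below ``threshold``, over threshold.

    NaN when no p-value survives the cutoff.  Dividing by the threshold
    removes the dependence on the choice of cutoff.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pvals = np.asarray(pvals, dtype=np.float64)
    surviving = pvals[pvals < threshold]
    if surviving.size == 0:
        return math.nan
    return float(np.median(surviving) / threshold)


def max_ld_to_truth(
    A: GenotypeMatrix | np.ndarray,
    candidates: Sequence[int],
    true_support: Sequence[int],
) -> np.ndarray:
    """Per-candidate max |r| (positive root of r²) to any true nonzero."""
    M = A.standardized if isinstance(A, GenotypeMatrix) else np.asarray(A, dtype=np.float64)
    cand = np.asarray(candidates, dtype=np.int64)
    true = np.asarray(true_support, dtype=np.int64)
    if true.size == 0:
        raise ValueError("true support is empty")
    C = M[:, cand]
    T = M[:, true]
    cn = np.sqrt(np.sum(C**2, axis=0))
    tn = np.sqrt(np.sum(T**2, axis=0))
    cn[cn == 0] = 1.0
    tn[tn == 0] = 1.0
    R = np.abs((C.T @ T) / np.outer(cn, tn))
    return np.clip(R.max(axis=1), 0.0, 1.0)


def null_adjusted_ppv(
    markers: Sequence[MarkerInfo],
    n_select: int,
    truth: ProximityTruthSet,
    reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of PPV* when ``n_select`` markers are drawn at random."""
    p = len(markers)
    if n_select > p:
        raise ValueError(f"cannot select {n_select} of {p} markers")
    rng = substream(seed)
    hits = np.array(
        [truth.contains(m.chromosome, m.bp_position) for m in markers], dtype=np.float64
    )
    out = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(p, size=n_select, replace=False)
        out[r] = hits[idx].mean()
    return out


def evaluate_selection(
    A: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    x_true: np.ndarray,
    x_hat: np.ndarray,
) -> SelectionMetrics:
    """Bundle every measure for one experiment into a :class:`SelectionMetrics`."""
    x_true = np.asarray(x_true)
    x_hat = np.asarray(x_hat)
    p = x_true.shape[0]
    true_support = np.flatnonzero(x_true)
    selected = np.flatnonzero(x_hat)
    ne = normalized_error(x_true, x_hat) if np.any(x_true) else math.nan
    fpr, ppv, fdr, tp = confusion_metrics(true_support, selected, p)
    if selected.size:
        mu = mu_pvalue(marginal_pvalues(A, y, indices=selected))
    else:
        mu = math.nan
    return SelectionMetrics(
        ne=ne,
        fpr=fpr,
        ppv=ppv,
        fdr=fdr,
        mu_pvalue=mu,
        n_selected=int(selected.size),
        n_true_positive=tp,
    )
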