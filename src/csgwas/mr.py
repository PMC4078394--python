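"""Marginal regression — the standard single-marker GWAS baseline.

Each marker is tested in its own univariate regression of the phenotype on
the standardized genotype; markers whose two-tailed t-test p-value falls
strictly below a significance threshold are selected.  No genomic-control
correction or LD clumping is applied.  The sweep utility maps the
observable recovery measures (PPV*, μ*P-value) over sample size and
threshold, mirroring how a phase transition can be sought in standard GWAS
output by subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seeds import substream
from .genotypes import GenotypeMatrix
from .metrics import ProximityTruthSet, adjusted_mu_pvalue, adjusted_ppv, marginal_pvalues

__all__ = ["MRScan", "mr_scan", "mr_select", "mr_sweep", "selection_overlap"]


@dataclass
class MRScan:
    """Genome-wide marginal p-values, optionally with a selection threshold."""

    pvalues: np.ndarray
    threshold: float | None = None

    @property
    def selected(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no threshold set on this scan")
        return np.flatnonzero(self.pvalues < self.threshold)


def mr_scan(A: GenotypeMatrix | np.ndarray, y: np.ndarray) -> MRScan:
    """Univariate t-test p-values for every marker."""
    return MRScan(pvalues=marginal_pvalues(A, y))


def mr_select(scan: MRScan, threshold: float) -> np.ndarray:
    """Markers with p strictly below the threshold (ties at the cutoff excluded)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    return np.flatnonzero(scan.pvalues < threshold)


def mr_sweep(
    A_full: GenotypeMatrix,
    y_full: np.ndarray,
    truth: ProximityTruthSet,
    thresholds: np.ndarray,
    n_values: np.ndarray,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """PPV* and μ*P-value surfaces over (sample size, threshold).

    For each n, subjects are subsampled without replacement (independently
    per n) and the subsample re-standardized; for each threshold the
    surviving markers are scored.  Cells with no survivors are NaN, never 0.
    Returns ``{"ppv_star", "mu_star", "n_selected"}`` arrays of shape
    ``(len(n_values), len(thresholds))``.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    n_values = np.asarray(n_values, dtype=np.int64)
    N = A_full.n_subjects
    ppv_star = np.full((len(n_values), len(thresholds)), math.nan)
    mu_star = np.full_like(ppv_star, math.nan)
    n_selected = np.zeros(ppv_star.shape, dtype=np.int64)
    for i, n in enumerate(n_values):
        if n > N:
            raise ValueError(f"n={n} exceeds available subjects ({N})")
        rng = substream(seed, i)
        rows = rng.choice(N, size=int(n), replace=False)
        gm = A_full.subsample(rows)
        scan = mr_scan(gm, y_full[rows])
        for j, thr in enumerate(thresholds):
            sel = mr_select(scan, float(thr))
            n_selected[i, j] = sel.size
            if sel.size == 0:
                continue
            ppv_star[i, j] = adjusted_ppv([gm.markers[k] for k in sel], truth)
            mu_star[i, j] = adjusted_mu_pvalue(scan.pvalues[sel], float(thr))
    return {"ppv_star": ppv_star, "mu_star": mu_star, "n_selected": n_selected}


def selection_overlap(selected_a: np.ndarray, selected_b: np.ndarray) -> dict[str, int]:
    """Set-overlap report between two selections (e.g. MR vs L1)."""
    a, b = set(np.asarray(selected_a).tolist()), set(np.asarray(selected_b).tolist())
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_shared": len(a & b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
    }
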