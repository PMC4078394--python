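"""SNP genotype matrices used as the compressed-sensing measurement matrix.

A genotype matrix holds minor-allele counts (0/1/2, with a missing code) for
``n`` subjects at ``p`` markers.  For regression each column is standardized
to zero mean and unit variance under the 1/n (population) convention, so that
the squared column norm equals the number of non-missing entries; missing
genotypes become exactly zero (the column mean) after standardization.

The module also provides the matrix diagnostics that matter for sparse
recovery: *coherence* (the largest squared standardized entry, which blows up
for very rare alleles) and an *isotropy* deviation (the largest off-diagonal
sample correlation, zero in linkage equilibrium), plus pairwise LD as squared
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeds import substream

__all__ = [
    "MarkerInfo",
    "GenotypeMatrix",
    "BlockLD",
    "MonomorphicMarkerError",
    "simulate_genotypes",
    "standardize",
    "coherence",
    "isotropy_deviation",
    "ld_r2",
    "ld_matrix",
    "read_text",
    "write_text",
]

MISSING = -1  # internal missing genotype code in raw matrices


class MonomorphicMarkerError(ValueError):
    """Raised when a column has fewer than two distinct non-missing values."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one SNP marker.

    ``maf`` is the minor allele frequency, in (0, 0.5]; monomorphic markers
    are rejected because their standardized columns are undefined and their
    coherence diverges. ``bp_position`` is 1-based.
    """

    marker_id: str
    chromosome: str
    bp_position: int
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"marker {self.marker_id}: maf must be in (0, 0.5], got {self.maf}"
            )
        if self.bp_position < 1:
            raise ValueError(
                f"marker {self.marker_id}: bp_position must be >= 1, got {self.bp_position}"
            )


@dataclass
class GenotypeMatrix:
    """Raw and standardized genotypes with per-marker metadata.

    Attributes
    ----------
    raw
        ``(n, p)`` int8 matrix of minor-allele counts; missing entries are
        coded :data:`MISSING`.
    standardized
        ``(n, p)`` float64 matrix; each column centered and scaled over its
        non-missing entries (1/n variance convention), missing set to 0.
    markers
        Per-column :class:`MarkerInfo`.
    """

    raw: np.ndarray
    standardized: np.ndarray
    markers: list[MarkerInfo] = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return self.raw.shape[0]

    @property
    def p_markers(self) -> int:
        return self.raw.shape[1]

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        markers: Sequence[MarkerInfo] | None = None,
        missing_code: int = MISSING,
    ) -> "GenotypeMatrix":
        """Build from a raw 0/1/2 matrix, standardizing and inferring metadata.

        When ``markers`` is omitted, marker ids ``snp1..snpP`` are assigned on
        a single synthetic chromosome at 10-kb spacing and MAFs are estimated
        from the data (folded to <= 0.5).
        """
        raw = np.asarray(raw)
        if raw.ndim != 2:
            raise ValueError("raw genotype matrix must be 2-dimensional")
        raw8 = raw.astype(np.int8, copy=True)
        if missing_code != MISSING:
            raw8[raw == missing_code] = MISSING
        valid = (raw8 == 0) | (raw8 == 1) | (raw8 == 2) | (raw8 == MISSING)
        if not valid.all():
            raise ValueError("raw genotypes must be 0, 1, 2 or the missing code")
        ids = None if markers is None else [m.marker_id for m in markers]
        A = standardize(raw8, marker_ids=ids)
        if markers is None:
            markers = _infer_markers(raw8)
        markers = list(markers)
        if len(markers) != raw8.shape[1]:
            raise ValueError("marker metadata length does not match column count")
        if len({m.marker_id for m in markers}) != len(markers):
            raise ValueError("marker ids must be unique")
        return cls(raw=raw8, standardized=A, markers=markers)

    def subsample(self, rows: np.ndarray) -> "GenotypeMatrix":
        """Subject subsample, re-standardized on the retained rows.

        Column norms must be exact for the coordinate-descent update, so each
        analyzed subsample is standardized afresh rather than sliced from the
        parent's standardized matrix.
        """
        rows = np.asarray(rows)
        sub_raw = self.raw[rows]
        A = standardize(
            sub_raw, marker_ids=[m.marker_id for m in self.markers], monomorphic="zero"
        )
        return GenotypeMatrix(raw=sub_raw, standardized=A, markers=list(self.markers))


def _infer_markers(raw: np.ndarray, spacing_bp: int = 10_000, chromosome: str = "1") -> list[MarkerInfo]:
    markers = []
    for j in range(raw.shape[1]):
        col = raw[:, j]
        obs = col[col != MISSING]
        freq = float(obs.mean()) / 2.0
        maf = min(freq, 1.0 - freq)
        markers.append(
            MarkerInfo(
                marker_id=f"snp{j + 1}",
                chromosome=chromosome,
                bp_position=(j + 1) * spacing_bp,
                maf=maf,
            )
        )
    return markers


def standardize(
    raw: np.ndarray,
    marker_ids: Sequence[str] | None = None,
    missing_code: int = MISSING,
    monomorphic: str = "error",
) -> np.ndarray:
    """Center and scale each column over non-missing entries; missing -> 0.

    Uses the population (1/m) variance over the m non-missing entries, so the
    squared norm of a complete column equals n exactly.

    ``monomorphic`` controls degenerate columns: ``"error"`` (default) raises
    a :class:`MonomorphicMarkerError` naming the marker; ``"zero"`` maps the
    whole column to zeros (used when re-standardizing a subject subsample, in
    which a rare allele may be absent by chance — a zero column carries no
    signal and can never be selected).
    """
    raw = np.asarray(raw)
    miss = raw == missing_code
    X = raw.astype(np.float64)
    X[miss] = np.nan
    m = np.sum(~miss, axis=0).astype(np.float64)
    degenerate = m < 2
    with np.errstate(invalid="ignore"):
        mean = np.nansum(X, axis=0) / np.maximum(m, 1.0)
        var = np.nansum((X - mean) ** 2, axis=0) / np.maximum(m, 1.0)
    degenerate |= var <= 0
    if np.any(degenerate):
        if monomorphic == "error":
            j = int(np.argmax(degenerate))
            name = marker_ids[j] if marker_ids is not None else f"column {j}"
            raise MonomorphicMarkerError(f"marker {name}: monomorphic (zero variance)")
        if monomorphic != "zero":
            raise ValueError(f"unknown monomorphic policy {monomorphic!r}")
        var = np.where(degenerate, 1.0, var)
    A = (X - mean) / np.sqrt(var)
    A[miss] = 0.0
    A[:, degenerate] = 0.0
    return A


@dataclass(frozen=True)
class BlockLD:
    """Contiguous-block LD descriptor: ``block_size`` markers per block with
    pairwise correlation approximately ``r`` between standardized columns."""

    block_size: int
    r: float

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0.0 <= self.r < 1.0):
            raise ValueError("target within-block correlation r must be in [0, 1)")


_MAX_RESAMPLE = 20


def simulate_genotypes(
    n: int,
    p: int,
    maf_spec: tuple[float, float] | Sequence[float] = (0.05, 0.5),
    ld_spec: str | BlockLD = "independent",
    seed: int = 0,
    spacing_bp: int = 10_000,
    chromosome: str = "1",
) -> GenotypeMatrix:
    """Simulate a standardized SNP matrix with a configurable MAF spectrum.

    Markers are Binomial(2, maf_j) counts, independent across subjects.  With
    ``ld_spec="independent"`` columns are mutually independent, emulating
    markers sampled at random across the genome (linkage equilibrium).  With a
    :class:`BlockLD`, markers within each contiguous block are perturbed
    copies of a shared latent subject dosage: each entry of a block member is
    redrawn from Binomial(2, maf) with probability ``1 - sqrt(r)``, giving
    pairwise correlation ~``r`` between block members (block members share
    the block's MAF, as strong LD requires similar allele frequencies).

    Positions are assigned at ``spacing_bp`` intervals on one synthetic
    chromosome, blocks contiguous, so positional (500-kb window) rules can be
    exercised.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 subjects and p >= 1 markers")
    rng = substream(seed)
    if isinstance(ld_spec, str):
        if ld_spec != "independent":
            raise ValueError(f"unknown ld_spec {ld_spec!r}")
        ld = None
    else:
        ld = ld_spec

    if isinstance(maf_spec, tuple) and len(maf_spec) == 2 and np.isscalar(maf_spec[0]):
        low, high = float(maf_spec[0]), float(maf_spec[1])
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf range must satisfy 0 < low <= high <= 0.5")
        mafs = rng.uniform(low, high, size=p)
    else:
        mafs = np.asarray(maf_spec, dtype=np.float64)
        if mafs.shape != (p,):
            raise ValueError(f"explicit maf list must have length p={p}")
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("all MAFs must lie in (0, 0.5]")

    raw = np.empty((n, p), dtype=np.int8)
    if ld is None:
        raw[:] = rng.binomial(2, mafs, size=(n, p))
        _resample_monomorphic(raw, mafs, rng)
    else:
        k = ld.block_size
        eps = 1.0 - np.sqrt(ld.r)
        for start in range(0, p, k):
            stop = min(start + k, p)
            maf = float(mafs[start])  # block members share one MAF
            mafs[start:stop] = maf
            for attempt in range(_MAX_RESAMPLE + 1):
                template = rng.binomial(2, maf, size=n).astype(np.int8)
                block = np.repeat(template[:, None], stop - start, axis=1)
                redraw = rng.random(block.shape) < eps
                block[redraw] = rng.binomial(2, maf, size=int(redraw.sum()))
                if all(len(np.unique(block[:, c])) > 1 for c in range(block.shape[1])):
                    break
            else:
                raise MonomorphicMarkerError(
                    f"block starting at column {start} stayed monomorphic after "
                    f"{_MAX_RESAMPLE} resampling attempts"
                )
            raw[:, start:stop] = block

    markers = [
        MarkerInfo(
            marker_id=f"snp{j + 1}",
            chromosome=chromosome,
            bp_position=(j + 1) * spacing_bp,
            maf=float(mafs[j]),
        )
        for j in range(p)
    ]
    A = standardize(raw, marker_ids=[m.marker_id for m in markers])
    return GenotypeMatrix(raw=raw, standardized=A, markers=markers)


def _resample_monomorphic(raw: np.ndarray, mafs: np.ndarray, rng: np.random.Generator) -> None:
    n = raw.shape[0]
    for j in range(raw.shape[1]):
        attempt = 0
        while len(np.unique(raw[:, j])) < 2:
            attempt += 1
            if attempt > _MAX_RESAMPLE:
                raise MonomorphicMarkerError(
                    f"column {j} stayed monomorphic after {_MAX_RESAMPLE} resamples "
                    f"(maf={mafs[j]:.4g}, n={n})"
                )
            raw[:, j] = rng.binomial(2, mafs[j], size=n)


# ---------------------------------------------------------------------------
# diagnostics


def _std_matrix(A: GenotypeMatrix | np.ndarray) -> np.ndarray:
    return A.standardized if isinstance(A, GenotypeMatrix) else np.asarray(A, dtype=np.float64)


def coherence(A: GenotypeMatrix | np.ndarray) -> float:
    """Largest squared entry of the standardized matrix.

    Rare alleles produce extreme standardized values ((2 - mu)/sigma grows as
    MAF shrinks), so coherence motivates pruning very-low-MAF markers before
    sparse recovery.
    """
    M = _std_matrix(A)
    return float(np.max(M**2))


def isotropy_deviation(A: GenotypeMatrix | np.ndarray) -> float:
    """Max absolute off-diagonal of A'A/n — a linkage-equilibrium diagnostic.

    Zero for exactly orthogonal columns; shrinks as O(1/sqrt(n)) for
    independent markers. Forms the p x p Gram matrix, so intended for
    diagnostic use at moderate p.
    """
    M = _std_matrix(A)
    n, p = M.shape
    if p == 1:
        return 0.0
    G = (M.T @ M) / n
    np.fill_diagonal(G, 0.0)
    return float(np.max(np.abs(G)))


def ld_r2(A: GenotypeMatrix | np.ndarray, j: int, k: int) -> float:
    """Squared Pearson correlation between standardized columns j and k."""
    M = _std_matrix(A)
    a, b = M[:, j], M[:, k]
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    r = float((a @ b) / denom)
    return min(r * r, 1.0)


def ld_matrix(A: GenotypeMatrix | np.ndarray, indices: Sequence[int] | None = None) -> np.ndarray:
    """Full (or index-restricted) matrix of pairwise r^2 values."""
    M = _std_matrix(A)
    if indices is not None:
        M = M[:, np.asarray(indices)]
    norms = np.sqrt(np.sum(M**2, axis=0))
    norms[norms == 0] = 1.0
    C = (M.T @ M) / np.outer(norms, norms)
    return np.clip(C**2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# delimited-text fallback IO


def write_text(gm: GenotypeMatrix, prefix: str, missing_token: str = "NA") -> None:
    """Write genotypes as subjects x markers TSV plus a marker sidecar table."""
    import pandas as pd

    ids = [m.marker_id for m in gm.markers]
    df = pd.DataFrame(gm.raw, columns=ids).astype(object)
    df[gm.raw == MISSING] = missing_token
    df.to_csv(f"{prefix}.geno.tsv", sep="\t", index=False)
    side = pd.DataFrame(
        {
            "marker_id": ids,
            "chromosome": [m.chromosome for m in gm.markers],
            "bp_position": [m.bp_position for m in gm.markers],
            "maf": [m.maf for m in gm.markers],
        }
    )
    side.to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)


def read_text(prefix: str, missing_token: str = "NA") -> GenotypeMatrix:
    """Read the :func:`write_text` format back into a :class:`GenotypeMatrix`."""
    import pandas as pd

    df = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", dtype=str, keep_default_na=False)
    raw = df.to_numpy()
    out = np.empty(raw.shape, dtype=np.int8)
    miss = raw == missing_token
    out[miss] = MISSING
    out[~miss] = raw[~miss].astype(np.int8)
    side = pd.read_csv(f"{prefix}.markers.tsv", sep="\t")
    markers = [
        MarkerInfo(
            marker_id=str(r.marker_id),
            chromosome=str(r.chromosome),
            bp_position=int(r.bp_position),
            maf=float(r.maf),
        )
        for r in side.itertuples()
    ]
    return GenotypeMatrix.from_raw(out, markers=markers)
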