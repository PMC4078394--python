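"""Sparse coefficient ensembles and heritability-scaled phenotype simulation.

Phenotypes follow the additive model y = A x + e.  The breeding values g = A x
are rescaled so their empirical (1/n) variance equals the target narrow-sense
heritability h² exactly, and residuals are i.i.d. Normal(0, 1 - h²), so the
phenotypic variance is one in expectation.  Because g is rescaled, the
effective coefficient vector is rescaled by the same factor; the realization
exposes it (``x``) so that coefficient-error metrics compare against the
coefficients that actually generated the data.

Coefficient ensembles:

* ``signs`` — all nonzero magnitudes 1 (the {−1, +1} ensemble).
* ``hyperexponential`` — rank-i magnitude exp(−i/τ₁) + exp(−i/τ₂), a
  deterministic decreasing effect-size curve summing two equal-amplitude
  exponentials.  Presets: Hyperexponential 1 uses (τ₁, τ₂) = (0.05·s, p),
  Hyperexponential 2 uses (0.2·s, p).

In every ensemble exactly ⌊s/2⌋ of the nonzeros are flipped negative, chosen
uniformly at random, and the nonzeros are placed either uniformly among all
markers or restricted to a MAF window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._seeds import substream
from .genotypes import GenotypeMatrix, MarkerInfo

__all__ = [
    "EnsembleSpec",
    "TrueModel",
    "PhenotypeRealization",
    "draw_coefficients",
    "place_support",
    "make_true_model",
    "simulate_phenotype",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Distribution of the s nonzero coefficient magnitudes."""

    kind: Literal["signs", "hyperexponential"]
    s: int
    tau1: float | None = None
    tau2: float | None = None
    negative_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.kind == "hyperexponential":
            if self.tau1 is None or self.tau2 is None:
                raise ValueError("hyperexponential ensemble needs tau1 and tau2")
            if self.tau1 <= 0 or self.tau2 <= 0:
                raise ValueError("decay constants must be positive")
        elif self.kind != "signs":
            raise ValueError(f"unknown ensemble kind {self.kind!r}")

    @classmethod
    def signs(cls, s: int) -> "EnsembleSpec":
        return cls(kind="signs", s=s)

    @classmethod
    def hyperexponential1(cls, s: int, p: int) -> "EnsembleSpec":
        return cls(kind="hyperexponential", s=s, tau1=0.05 * s, tau2=float(p))

    @classmethod
    def hyperexponential2(cls, s: int, p: int) -> "EnsembleSpec":
        return cls(kind="hyperexponential", s=s, tau1=0.2 * s, tau2=float(p))


@dataclass
class TrueModel:
    """Ground-truth sparse coefficient vector and noise level."""

    x: np.ndarray
    support: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        nz = np.flatnonzero(self.x)
        if set(nz.tolist()) != set(np.asarray(self.support).tolist()):
            raise ValueError("support does not match the nonzero entries of x")

    @property
    def s(self) -> int:
        return int(len(self.support))

    @property
    def sigma_e2(self) -> float:
        return 1.0 - self.h2


@dataclass
class PhenotypeRealization:
    """One simulated phenotype: y = g + e with var(g) = h² exactly."""

    y: np.ndarray
    g: np.ndarray
    realized_h2: float
    x: np.ndarray = field(repr=False)  # effective (rescaled) coefficients
    support: np.ndarray = field(repr=False)


def draw_coefficients(spec: EnsembleSpec, p: int, seed: int = 0) -> np.ndarray:
    """Draw the length-s signed magnitude vector for an ensemble.

    Magnitudes are rank-ordered nonincreasing; exactly ⌊s/2⌋ entries (chosen
    uniformly at random) are made negative.
    """
    if spec.s > p:
        raise ValueError(f"s={spec.s} exceeds p={p}")
    rng = substream(seed)
    if spec.kind == "signs":
        mags = np.ones(spec.s)
    else:
        ranks = np.arange(1, spec.s + 1, dtype=np.float64)
        mags = np.exp(-ranks / spec.tau1) + np.exp(-ranks / spec.tau2)
    values = mags.copy()
    n_neg = spec.s // 2
    if n_neg:
        neg = rng.choice(spec.s, size=n_neg, replace=False)
        values[neg] *= -1.0
    return values


def place_support(
    values: np.ndarray,
    markers: Sequence[MarkerInfo],
    strategy: Literal["uniform", "maf_window"] = "uniform",
    maf_low: float = 0.0,
    maf_high: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter the signed magnitudes onto marker indices.

    ``uniform`` samples s indices without replacement from all p markers;
    ``maf_window`` restricts eligibility to markers with MAF in
    ``[maf_low, maf_high]``.  Returns ``(x, support)`` with x of length p.
    """
    values = np.asarray(values, dtype=np.float64)
    s, p = len(values), len(markers)
    if strategy == "uniform":
        eligible = np.arange(p)
    elif strategy == "maf_window":
        eligible = np.array(
            [j for j, m in enumerate(markers) if maf_low <= m.maf <= maf_high],
            dtype=np.int64,
        )
    else:
        raise ValueError(f"unknown placement strategy {strategy!r}")
    if len(eligible) < s:
        raise ValueError(
            f"only {len(eligible)} markers eligible for placement, need {s}"
        )
    rng = substream(seed)
    support = rng.choice(eligible, size=s, replace=False)
    x = np.zeros(p)
    x[support] = values
    return x, np.sort(support)


def make_true_model(
    spec: EnsembleSpec,
    markers: Sequence[MarkerInfo],
    h2: float,
    strategy: Literal["uniform", "maf_window"] = "uniform",
    maf_low: float = 0.0,
    maf_high: float = 0.5,
    seed: int = 0,
) -> TrueModel:
    """Draw coefficients and place them: the full ground-truth model."""
    values = draw_coefficients(spec, len(markers), seed=seed)
    x, support = place_support(
        values, markers, strategy=strategy, maf_low=maf_low, maf_high=maf_high,
        seed=seed + 1,
    )
    return TrueModel(x=x, support=support, h2=h2)


def simulate_phenotype(
    A: GenotypeMatrix | np.ndarray,
    model: TrueModel,
    seed: int = 0,
) -> PhenotypeRealization:
    """Simulate y = g + e with the breeding-value variance pinned to h².

    g = c·(A x) with c chosen so the empirical (1/n) variance of g equals h²
    exactly; the same c rescales the coefficients reported on the
    realization.  e is i.i.d. Normal(0, 1 − h²); y is not rescaled, so its
    variance is ≈ 1 in expectation.
    """
    M = A.standardized if isinstance(A, GenotypeMatrix) else np.asarray(A)
    x = np.asarray(model.x, dtype=np.float64)
    if M.shape[1] != x.shape[0]:
        raise ValueError("coefficient vector length does not match marker count")
    n = M.shape[0]
    g0 = M @ x
    var_g0 = float(np.var(g0))  # population (1/n) variance
    if model.h2 > 0:
        if var_g0 <= 0:
            raise ValueError("breeding values are identically zero but h2 > 0")
        c = np.sqrt(model.h2 / var_g0)
    else:
        c = 0.0
    g = c * g0
    rng = substream(seed)
    e = rng.normal(0.0, np.sqrt(1.0 - model.h2), size=n)
    y = g + e
    return PhenotypeRealization(
        y=y,
        g=g,
        realized_h2=float(np.var(g)),
        x=c * x,
        support=np.asarray(model.support),
    )
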