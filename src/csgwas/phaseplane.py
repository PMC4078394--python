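"""Phase-plane experiments: replicate sweeps over (δ, ρ) and the L1 boundary.

The undersampling coordinates are δ = n/p (sample relative to markers) and
ρ = s/n (nonzeros relative to sample).  Below a universal curve ρ = ρ_L1(δ),
noiseless L1 minimization recovers a signed sparse vector with probability
approaching one; above it recovery fails.  :func:`theoretical_boundary`
evaluates that curve; :func:`run_experiment` and :func:`sweep_plane` measure
empirical recovery surfaces on simulated (or real) genotype matrices; and
:func:`detect_transition` formalizes the verbal transition criteria — the
interpolated NE = 0.5 crossing, and the sustained drop of the normalized
μP-value below a small fraction of its maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._seeds import substream
from .genotypes import GenotypeMatrix
from .lasso import LassoConfig, lasso_path, select
from .metrics import SelectionMetrics, evaluate_selection
from .phenosim import EnsembleSpec, make_true_model, simulate_phenotype

__all__ = [
    "PhasePoint",
    "PhasePlaneResult",
    "TransitionResult",
    "theoretical_boundary",
    "run_experiment",
    "sweep_plane",
    "detect_transition",
    "detect_plateau",
    "minimum_sample_size",
]

logger = logging.getLogger(__name__)

_METRIC_NAMES = ("ne", "fpr", "ppv", "fdr", "mu_pvalue")


@dataclass
class PhasePoint:
    """Replicate metrics and their medians at one (δ, ρ) grid point."""

    delta: float
    rho: float
    n: int
    s: int
    h2: float
    replicates: list[SelectionMetrics]
    aggregates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aggregates:
            self.aggregates = {
                name: float(np.nanmedian([getattr(m, name) for m in self.replicates]))
                if self.replicates
                else math.nan
                for name in _METRIC_NAMES
            }


@dataclass
class PhasePlaneResult:
    """A grid of :class:`PhasePoint` with provenance."""

    points: list[PhasePoint]
    h2: float
    p_markers: int
    seed: int

    def surface(self, metric: str) -> np.ndarray:
        """(delta, rho, median metric) rows for all grid points."""
        return np.array(
            [[pt.delta, pt.rho, pt.aggregates[metric]] for pt in self.points]
        )


@dataclass
class TransitionResult:
    """Detected critical value of a scan, with censoring flag and the scan."""

    critical: float
    censored: bool
    xs: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# theoretical boundary


def _dt_objective(z: float, delta: float) -> float:
    F = (1.0 + z * z) * stats.norm.cdf(-z) - z * stats.norm.pdf(z)
    num = 1.0 - (2.0 / delta) * F
    den = 1.0 + z * z - 2.0 * F
    return num / den


def theoretical_boundary(delta: float | np.ndarray) -> float | np.ndarray:
    """Asymptotic L1 weak phase-transition curve ρ_L1(δ) for signed vectors.

    Evaluates the cross-polytope (signed-coefficient) weak threshold under
    Gaussian sensing via its Gaussian-integral representation

        ρ(δ) = max_{z ≥ 0} [1 − (2/δ)F(z)] / [1 + z² − 2F(z)],
        F(z) = (1 + z²)Φ(−z) − z·φ(z),

    maximized numerically.  ρ is strictly increasing in δ, with ρ → 1 as
    δ → 1: a fully determined system recovers everything.
    """
    if np.ndim(delta) > 0:
        return np.array([theoretical_boundary(float(d)) for d in np.asarray(delta)])
    d = float(delta)
    if not (0.0 < d < 1.0):
        raise ValueError(f"delta must lie in (0, 1), got {d}")
    res = optimize.minimize_scalar(
        lambda z: -_dt_objective(z, d),
        bounds=(1e-8, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(max(-res.fun, 0.0))


# ---------------------------------------------------------------------------
# experiments


def run_experiment(
    A_full: GenotypeMatrix,
    n: int,
    s: int,
    h2: float,
    ensemble: str | EnsembleSpec = "signs",
    support_strategy: str = "uniform",
    maf_low: float = 0.0,
    maf_high: float = 0.5,
    reps: int = 5,
    seed: int = 0,
    config: LassoConfig | None = None,
) -> PhasePoint:
    """Replicated selection experiment at one (n, s, h²) setting.

    Per replicate: subsample ``n`` subjects without replacement and
    re-standardize; draw the coefficient ensemble and support; simulate the
    phenotype at heritability ``h2``; run the warm-started lasso path down to
    the theoretical λ_min with σ_E² = 1 − h²; and score the terminal support
    with every selection measure.  Replicates use independent substreams of
    ``seed``; aggregates are medians.
    """
    N, p = A_full.n_subjects, A_full.p_markers
    if n > N:
        raise ValueError(f"cannot subsample n={n} from {N} subjects")
    if s > p:
        raise ValueError(f"s={s} exceeds p={p}")
    spec = _resolve_ensemble(ensemble, s, p)
    replicates: list[SelectionMetrics] = []
    for r in range(reps):
        rng = substream(seed, r)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rows = rng.choice(N, size=n, replace=False)
        gm = A_full.subsample(rows) if n < N else A_full
        model = make_true_model(
            spec, gm.markers, h2=h2, strategy=support_strategy,
            maf_low=maf_low, maf_high=maf_high, seed=rep_seed,
        )
        real = simulate_phenotype(gm, model, seed=rep_seed + 2)
        cfg = config or LassoConfig()
        cfg = LassoConfig(
            n_lambda_steps=cfg.n_lambda_steps,
            tol=cfg.tol,
            max_sweeps=cfg.max_sweeps,
            sigma_e2=1.0 - h2,
            n_noise_draws=cfg.n_noise_draws,
            seed=rep_seed + 3,
            use_active_set=cfg.use_active_set,
        )
        path = lasso_path(gm, real.y, config=cfg)
        sel = select(path)
        replicates.append(evaluate_selection(gm, real.y, real.x, sel.x_hat))
    return PhasePoint(
        delta=n / p, rho=s / n, n=n, s=s, h2=h2, replicates=replicates
    )


def _resolve_ensemble(ensemble: str | EnsembleSpec, s: int, p: int) -> EnsembleSpec:
    if isinstance(ensemble, EnsembleSpec):
        return ensemble
    if ensemble == "signs":
        return EnsembleSpec.signs(s)
    if ensemble in ("hyper1", "hyperexponential1"):
        return EnsembleSpec.hyperexponential1(s, p)
    if ensemble in ("hyper2", "hyperexponential2"):
        return EnsembleSpec.hyperexponential2(s, p)
    raise ValueError(f"unknown ensemble {ensemble!r}")


def sweep_plane(
    A_full: GenotypeMatrix,
    grid: list[tuple[float, float]],
    h2: float,
    ensemble: str | EnsembleSpec = "signs",
    reps: int = 5,
    seed: int = 0,
    config: LassoConfig | None = None,
) -> PhasePlaneResult:
    """Run :func:`run_experiment` at each (δ, ρ) grid point, p held fixed.

    Integer rounding: n = round(δ·p), s = max(1, round(ρ·n)); the stored δ, ρ
    are recomputed from the integers.  Infeasible points are skipped with a
    logged warning.  Each point gets an independent seed substream.
    """
    p = A_full.p_markers
    points: list[PhasePoint] = []
    for i, (delta, rho) in enumerate(grid):
        n = int(round(delta * p))
        s = max(1, int(round(rho * n)))
        if n < 2 or n > A_full.n_subjects or s > p:
            logger.warning(
                "skipping infeasible grid point (delta=%g, rho=%g): n=%d, s=%d",
                delta, rho, n, s,
            )
            continue
        point_seed = int(substream(seed, 1000 + i).integers(0, 2**31 - 1))
        points.append(
            run_experiment(
                A_full, n=n, s=s, h2=h2, ensemble=ensemble,
                reps=reps, seed=point_seed, config=config,
            )
        )
    return PhasePlaneResult(points=points, h2=h2, p_markers=p, seed=seed)


# ---------------------------------------------------------------------------
# transition detection


def detect_transition(
    xs: np.ndarray,
    values: np.ndarray,
    criterion: str = "ne",
    threshold: float = 0.5,
    fraction: float = 0.05,
) -> TransitionResult:
    """Locate the phase transition along an ordered scan.

    criterion="ne", xs ascending in ρ (values rising through 0.5):
        the largest ρ whose NE is below 0.5, linearly interpolated between
        the bracketing grid points.  All below → censored at max(xs).
    criterion="ne_n", xs ascending in n (values falling through 0.5):
        the interpolated n at which NE first drops below 0.5.
    criterion="mu", xs ascending in n:
        normalize values by their maximum, then return the smallest grid x
        after the *last* downward crossing of ``fraction`` — i.e. the point
        where the normalized μP-value drops below the fraction and stays
        there (robust to the characteristic rise-then-fall of the μP-value).
    """
    xs = np.asarray(xs, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(xs) < 3:
        raise ValueError("need at least 3 scan points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("scan positions must be strictly increasing")

    if criterion in ("ne", "ne_n"):
        below = values < threshold
        if criterion == "ne":
            if below.all():
                return TransitionResult(float(xs[-1]), True, xs, values)
            if not below[0]:
                return TransitionResult(math.nan, False, xs, values)
            i = int(np.argmin(below))  # first point at/above threshold
            crit = _interp_crossing(xs[i - 1], xs[i], values[i - 1], values[i], threshold)
            return TransitionResult(crit, False, xs, values)
        # ne_n: first drop below threshold as n grows
        if not below.any():
            return TransitionResult(math.nan, False, xs, values)
        i = int(np.argmax(below))
        if i == 0:
            return TransitionResult(float(xs[0]), True, xs, values)
        crit = _interp_crossing(xs[i - 1], xs[i], values[i - 1], values[i], threshold)
        return TransitionResult(crit, False, xs, values)

    if criterion == "mu":
        vmax = np.nanmax(values)
        norm = values / vmax if vmax > 0 else values
        ok = norm < fraction
        ok[np.isnan(norm)] = False
        if not ok.any():
            return TransitionResult(math.nan, False, xs, norm)
        # last index where the criterion fails; transition is the next point
        failing = np.flatnonzero(~ok)
        if failing.size == 0:
            return TransitionResult(float(xs[0]), True, xs, norm)
        last_fail = int(failing[-1])
        if last_fail == len(xs) - 1:
            return TransitionResult(math.nan, False, xs, norm)
        return TransitionResult(float(xs[last_fail + 1]), False, xs, norm)

    raise ValueError(f"unknown criterion {criterion!r}")


def detect_plateau(
    xs: np.ndarray,
    values: np.ndarray,
    tail: int = 3,
    tol: float = 0.05,
) -> TransitionResult:
    """Smallest x from which ``values`` stay within ``tol`` of their plateau.

    The plateau level is the median of the last ``tail`` scan values (an
    estimate of the asymptote robust to replicate-median wiggles); a point
    has "reached" the plateau when its value is at least plateau − tol, and
    the detected onset is the smallest x after the last point that has not.
    NaN if even the final point misses the band.
    """
    xs = np.asarray(xs, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(xs) < max(3, tail):
        raise ValueError("need at least max(3, tail) scan points")
    level = float(np.nanmedian(values[-tail:]))
    ok = values >= level - tol
    ok[np.isnan(values)] = False
    if not ok[-1]:
        return TransitionResult(math.nan, False, xs, values)
    failing = np.flatnonzero(~ok)
    if failing.size == 0:
        return TransitionResult(float(xs[0]), True, xs, values)
    return TransitionResult(float(xs[int(failing[-1]) + 1]), False, xs, values)


def minimum_sample_size(s: int, rho_crit: float) -> int:
    """Rule-of-thumb sample size for full selection: smallest n with s/n ≤ ρ_crit.

    E.g. with the empirical noisy-case ρ_crit = 0.03, recovering s nonzeros
    needs n ≥ s/0.03 ≈ 33·s subjects (n ≥ 30·s as an order-of-magnitude rule).
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if not (0.0 < rho_crit <= 1.0):
        raise ValueError("rho_crit must lie in (0, 1]")
    return int(math.ceil(s / rho_crit))


def _interp_crossing(x0: float, x1: float, v0: float, v1: float, thr: float) -> float:
    if v1 == v0:
        return float(x1)
    t = (thr - v0) / (v1 - v0)
    return float(x0 + t * (x1 - x0))
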