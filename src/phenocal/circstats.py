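"""Circular statistics for annual phenology.

Flowering dates are mapped onto a circle where 0° is 1 January and each
calendar month spans 30°, so the year closes on itself and December and
January flowering are one month apart, not eleven.  The flowering pattern
of a sample of dates is then described by maximum likelihood over a
lattice of ten circular distributions — one uniform (continuous flowering),
three unimodal (a single annual peak) and six bimodal (two peaks) — built
from mixtures of von Mises components:

    f(θ) = λ · VM(θ; μ1, k1) + (1 − λ) · C2(θ)

where ``C2`` is either the circular uniform density or a second von Mises
component, depending on the model's constraint set.  The best model is the
one minimising AIC = 2·(free parameters) − 2·logL, and the stability of
that choice is probed by repeating the multi-start fit many times
(the consensus procedure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e, i1e

__all__ = [
    "MONTH_DAYS",
    "MODEL_SPECS",
    "CircularSample",
    "ModelSpec",
    "ModelFit",
    "SelectionResult",
    "ConsensusResult",
    "date_to_angle",
    "angle_to_month_day",
    "circular_separation",
    "circular_mean",
    "model_density",
    "neg_loglik",
    "fit_model",
    "select_model",
    "run_consensus",
    "consensus_consistent",
    "fallback_most_prevalent",
    "peaks_from_fit",
]

# Fixed month lengths define the angular scale (the scale is month-based,
# not day-of-year based): each month is 30° wide and days interpolate
# linearly inside their month.  29 February is folded onto 28 February.
MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

_TWO_PI = 2.0 * math.pi
_LOG_2PI = math.log(_TWO_PI)
_INV_2PI = 1.0 / _TWO_PI
_DEG = math.pi / 180.0

# Concentration bound.  A von Mises component with k = 50 has circular sd
# ~8 degrees, i.e. a flowering peak of roughly +/- 8 days -- about the
# sharpest peak herbarium dating precision can support.  Allowing larger k
# lets a minority mixture component collapse onto 2-3 nearly coincident
# dates (the classic unbounded-mixture-likelihood spike), which spuriously
# wins AIC over the true model.
K_MAX = 50.0


# ---------------------------------------------------------------------------
# date <-> angle mapping


def date_to_angle(month: int, day: int | None = None) -> float:
    """Map a calendar date to degrees on the annual circle.

    ``angle = 30·(month−1) + 30·(day−1)/days_in_month``; a missing day is
    taken as the 15th (month-precision records sit mid-month).

    >>> date_to_angle(1, 1)
    0.0
    >>> date_to_angle(7, 1)
    180.0
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    month = int(month)
    if day is None:
        day = 15
    day = int(day)
    dim = MONTH_DAYS[month - 1]
    if month == 2 and day == 29:
        day = 28
    if not 1 <= day <= dim:
        raise ValueError(f"day {day} invalid for month {month}")
    return 30.0 * (month - 1) + 30.0 * (day - 1) / dim


def angle_to_month_day(angle: float) -> tuple[int, int]:
    """Inverse of :func:`date_to_angle`: nearest calendar (month, day)."""
    a = float(angle) % 360.0
    month = min(int(a // 30.0) + 1, 12)
    frac = (a - 30.0 * (month - 1)) / 30.0
    dim = MONTH_DAYS[month - 1]
    # epsilon guards against 30*(d-1)/dim mapping a hair below day d
    day = min(int(frac * dim + 1e-9) + 1, dim)
    return month, day


def circular_separation(a: float, b: float) -> float:
    """Shortest angular distance between two directions, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def circular_mean(angles: Sequence[float]) -> tuple[float, float]:
    """Mean direction (degrees) and resultant length R of a sample.

    Returns ``(nan, 0.0)`` when R is numerically zero (no preferred
    direction, e.g. antipodal pairs).
    """
    theta = np.asarray(angles, dtype=float) * _DEG
    if theta.size == 0:
        raise ValueError("empty sample")
    c = np.cos(theta).mean()
    s = np.sin(theta).mean()
    r = math.hypot(c, s)
    if r < 1e-12:
        return (float("nan"), 0.0)
    return (math.degrees(math.atan2(s, c)) % 360.0, r)


# ---------------------------------------------------------------------------
# the 10-model lattice

# Full parameter vector order: (mu1 [deg], k1, mu2 [deg], k2, lam).
_P_MU1, _P_K1, _P_MU2, _P_K2, _P_LAM = range(5)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate circular model: a constrained von Mises mixture.

    ``free`` lists the estimated parameters; everything else is pinned by
    the constraint set (axial models fix μ2 = μ1 + 180°, homogeneous models
    fix k2 = k1, symmetric mixtures fix λ = 0.5).  ``second`` says what the
    second mixture component is: absent, uniform, or a von Mises peak.
    """

    id: str
    family: str  # uniform | unimodal | bimodal
    free: tuple[str, ...]
    second: str  # "none" | "uniform" | "vm"
    axial: bool = False  # mu2 = mu1 + 180
    homogeneous: bool = False  # k2 = k1
    lam_fixed: float | None = None  # None => lam is free

    @property
    def free_params(self) -> int:
        return len(self.free)

    def lam_bounds(self) -> tuple[float, float]:
        # A von-Mises+uniform mixture cannot swap its components, so its
        # weight is constrained to lambda >= 0.5 up front; two-peak mixtures
        # explore the full range and are canonicalised afterwards.
        return (0.5, 0.95) if self.second == "uniform" else (0.05, 0.95)

    def full_params(self, x: np.ndarray) -> np.ndarray:
        """Expand the free-parameter vector into (mu1, k1, mu2, k2, lam)."""
        p = np.zeros(5)
        p[_P_LAM] = 1.0 if self.lam_fixed is None and "lam" not in self.free else (
            self.lam_fixed if self.lam_fixed is not None else 0.0
        )
        vals = dict(zip(self.free, x))
        p[_P_MU1] = vals.get("mu1", 0.0)
        p[_P_K1] = vals.get("k1", 0.0)
        if "lam" in vals:
            p[_P_LAM] = vals["lam"]
        if self.second == "none":
            p[_P_LAM] = 1.0
        p[_P_MU2] = (p[_P_MU1] + 180.0) % 360.0 if self.axial else vals.get("mu2", 0.0)
        p[_P_K2] = p[_P_K1] if self.homogeneous else vals.get("k2", 0.0)
        if self.second == "uniform":
            p[_P_K2] = 0.0
        return p


# The candidate set: 1 uniform, 3 unimodal, 6 bimodal.
MODEL_SPECS: dict[str, ModelSpec] = {
    s.id: s
    for s in (
        ModelSpec("M1", "uniform", (), "none"),
        # unimodal: a pure peak, and peak-plus-uniform "background" variants
        ModelSpec("M2A", "unimodal", ("mu1", "k1"), "none"),
        ModelSpec("M2B", "unimodal", ("mu1", "k1"), "uniform", lam_fixed=0.5),
        ModelSpec("M2C", "unimodal", ("mu1", "k1", "lam"), "uniform"),
        # bimodal, axial (peaks 6 months apart)
        ModelSpec("M3A", "bimodal", ("mu1", "k1"), "vm", axial=True,
                  homogeneous=True, lam_fixed=0.5),
        ModelSpec("M3B", "bimodal", ("mu1", "k1", "lam"), "vm", axial=True,
                  homogeneous=True),
        ModelSpec("M4A", "bimodal", ("mu1", "k1", "k2"), "vm", axial=True,
                  lam_fixed=0.5),
        ModelSpec("M4B", "bimodal", ("mu1", "k1", "k2", "lam"), "vm", axial=True),
        # bimodal, peaks anywhere
        ModelSpec("M5A", "bimodal", ("mu1", "k1", "mu2", "k2"), "vm", lam_fixed=0.5),
        ModelSpec("M5B", "bimodal", ("mu1", "k1", "mu2", "k2", "lam"), "vm"),
    )
}

MODEL_IDS = tuple(MODEL_SPECS)


@dataclass
class CircularSample:
    """A set of flowering dates expressed as angles on the annual circle."""

    angles: np.ndarray
    context: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % 360.0

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass
class ModelFit:
    model: str
    mu1: float
    k1: float
    mu2: float | None
    k2: float | None
    lam: float | None
    logL: float
    AIC: float
    converged: bool
    n_starts_used: int = 0

    @property
    def family(self) -> str:
        return MODEL_SPECS[self.model].family


@dataclass
class SelectionResult:
    fits: dict[str, ModelFit]
    best_id: str

    @property
    def best(self) -> ModelFit:
        return self.fits[self.best_id]

    @property
    def delta_aic(self) -> dict[str, float]:
        lo = self.fits[self.best_id].AIC
        return {m: f.AIC - lo for m, f in self.fits.items()}


@dataclass
class ConsensusResult:
    runs: int
    win_counts: dict[str, int]
    consistent: bool
    final_model: str
    fallback_used: bool
    winning_aics: dict[str, list[float]] = field(default_factory=dict, repr=False)
    final_fit: ModelFit | None = None


# ---------------------------------------------------------------------------
# density, likelihood and gradient


def _vm_log_const(k: np.ndarray | float):
    # log(2*pi*I0(k)) computed via the exponentially scaled Bessel function,
    # stable up to very large k.
    return np.log(_TWO_PI) + np.log(i0e(k)) + k


def _density_full(theta_rad: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Mixture density per radian at angles ``theta_rad`` for full params."""
    mu1, k1, mu2, k2, lam = p
    g1 = np.exp(k1 * np.cos(theta_rad - mu1 * _DEG) - _vm_log_const(k1))
    if lam >= 1.0:
        return g1
    g2 = np.exp(k2 * np.cos(theta_rad - mu2 * _DEG) - _vm_log_const(k2))
    return lam * g1 + (1.0 - lam) * g2


def model_density(theta_deg, fit_or_params, model: str | None = None) -> np.ndarray | float:
    """Density per radian of a fitted (or explicitly parameterised) model.

    Accepts either a :class:`ModelFit` or a full ``(mu1, k1, mu2, k2, lam)``
    tuple plus a model id.
    """
    if isinstance(fit_or_params, ModelFit):
        fit = fit_or_params
        spec = MODEL_SPECS[fit.model]
        p = np.array([
            fit.mu1, fit.k1,
            fit.mu2 if fit.mu2 is not None else 0.0,
            fit.k2 if fit.k2 is not None else 0.0,
            fit.lam if fit.lam is not None else 1.0,
        ])
        if spec.id == "M1":
            p = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    else:
        p = np.asarray(fit_or_params, dtype=float)
        if p[_P_K1] < 0 or p[_P_K2] < 0:
            raise ValueError("concentration parameters must be >= 0")
        if not 0.0 <= p[_P_LAM] <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
    theta = np.asarray(theta_deg, dtype=float) * _DEG
    out = _density_full(theta, p)
    return float(out) if np.isscalar(theta_deg) else out


def neg_loglik(angles_deg: np.ndarray, spec: ModelSpec | str, x: np.ndarray) -> float:
    """Negative log-likelihood of the free-parameter vector ``x``."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    theta = np.asarray(angles_deg, dtype=float) * _DEG
    if spec.id == "M1":
        return theta.size * math.log(_TWO_PI)
    p = spec.full_params(np.asarray(x, dtype=float))
    f = _density_full(theta, p)
    return float(-np.sum(np.log(np.maximum(f, 1e-300))))


def _log_i0(k: float) -> float:
    return math.log(float(i0e(k))) + k


def _bessel_ratio(k: float) -> float:
    return float(i1e(k) / i0e(k))  # A(k) = I1/I0


def _nll_and_grad(theta: np.ndarray, spec: ModelSpec, x: np.ndarray):
    """Value and analytic gradient of the NLL w.r.t. the free parameters.

    Specialized flat code paths per mixture shape (pure von Mises,
    von-Mises-plus-uniform, two von Mises) — this sits in the innermost
    loop of the multi-start consensus procedure.
    """
    n = theta.size
    mu1 = x[0] * _DEG
    k1 = x[1]
    d1 = theta - mu1
    c1 = np.cos(d1)
    s1 = np.sin(d1)
    lc1 = _LOG_2PI + _log_i0(k1)
    a1 = _bessel_ratio(k1)

    if spec.second == "none":  # M2A
        sc1 = float(c1.sum())
        nll = n * lc1 - k1 * sc1
        return nll, np.array([-k1 * float(s1.sum()) * _DEG, n * a1 - sc1])

    g1 = np.exp(k1 * c1 - lc1)
    if spec.second == "uniform":  # M2B / M2C
        lam = spec.lam_fixed if spec.lam_fixed is not None else x[2]
        f = lam * g1 + (1.0 - lam) * _INV_2PI
        np.maximum(f, 1e-300, out=f)
        w1 = lam * g1 / f
        nll = -float(np.log(f).sum())
        gmu1 = -k1 * float((w1 * s1).sum()) * _DEG
        gk1 = -float((w1 * (c1 - a1)).sum())
        if spec.lam_fixed is not None:
            return nll, np.array([gmu1, gk1])
        glam = -float(((g1 - _INV_2PI) / f).sum())
        return nll, np.array([gmu1, gk1, glam])

    # two von Mises components
    if spec.axial:
        # mu2 = mu1 + 180 deg: c2 = -c1, s2 = -s1
        c2, s2 = -c1, -s1
        k2 = k1 if spec.homogeneous else x[2]
    else:
        mu2 = x[2] * _DEG
        d2 = theta - mu2
        c2 = np.cos(d2)
        s2 = np.sin(d2)
        k2 = x[3]
    if spec.lam_fixed is not None:
        lam = spec.lam_fixed
    else:
        lam = x[len(spec.free) - 1]
    if spec.homogeneous:
        lc2, a2 = lc1, a1
    else:
        lc2 = _LOG_2PI + _log_i0(k2)
        a2 = _bessel_ratio(k2)
    g2 = np.exp(k2 * c2 - lc2)
    f = lam * g1 + (1.0 - lam) * g2
    np.maximum(f, 1e-300, out=f)
    nll = -float(np.log(f).sum())
    w1 = lam * g1 / f
    w2 = (1.0 - lam) * g2 / f

    gmu1 = -k1 * float((w1 * s1).sum()) * _DEG
    gk1 = -float((w1 * (c1 - a1)).sum())
    if spec.axial:
        gmu1 += -k2 * float((w2 * s2).sum()) * _DEG
        if spec.homogeneous:
            gk1 += -float((w2 * (c2 - a2)).sum())
    grad = [gmu1, gk1]
    if spec.axial and not spec.homogeneous:  # M4A / M4B: k2 free
        grad.append(-float((w2 * (c2 - a2)).sum()))
    if not spec.axial:  # M5A / M5B: mu2, k2 free
        grad.append(-k2 * float((w2 * s2).sum()) * _DEG)
        grad.append(-float((w2 * (c2 - a2)).sum()))
    if spec.lam_fixed is None:  # trailing lambda
        grad.append(-float(((g1 - g2) / f).sum()))
    return nll, np.array(grad)


def _estimate_k_from_r(r: float) -> float:
    """Invert the mean-resultant-length relation A(k) = R (standard approx.)."""
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        denom = r**3 - 4 * r**2 + 3 * r  # -> 0 as r -> 1 (point mass)
        k = 1 / denom if denom > 1e-12 else K_MAX
    return float(np.clip(k, 0.0, K_MAX))


def _moment_anchors(angles_deg: np.ndarray) -> tuple[list[float], float]:
    """Candidate peak directions and a concentration scale from the data.

    Uses the first trigonometric moment and the doubled-angle (axial)
    moment, which points at the peak pair of a two-peaks-apart pattern.
    """
    m1, r1 = circular_mean(angles_deg)
    m2, r2 = circular_mean((2.0 * angles_deg) % 360.0)
    anchors: list[float] = []
    if not math.isnan(m1):
        anchors.append(m1)
    if not math.isnan(m2):
        anchors.extend([m2 / 2.0, m2 / 2.0 + 180.0])
    if not anchors:
        anchors = [0.0, 180.0]
    k_scale = max(_estimate_k_from_r(r1), _estimate_k_from_r(r2), 0.2)
    return anchors, min(k_scale, 20.0)


def _random_start(
    spec: ModelSpec,
    rng: np.random.Generator,
    anchors: list[float],
    k_scale: float,
) -> np.ndarray:
    # Starting values are jittered around the circular moment estimates of
    # the sample rather than drawn uniformly over the box: diffuse starts
    # let the optimizer wander into degenerate minority-spike optima of the
    # mixture likelihood, which would dominate AIC spuriously.
    lo, hi = spec.lam_bounds()
    mu1 = (rng.choice(anchors) + rng.normal(0.0, 25.0)) % 360.0
    draw = {
        "mu1": lambda: mu1,
        "mu2": lambda: (rng.choice(anchors + [mu1 + 180.0]) + rng.normal(0.0, 25.0)) % 360.0,
        "k1": lambda: float(np.clip(k_scale * rng.lognormal(0.0, 0.6), 0.05, 30.0)),
        "k2": lambda: float(np.clip(k_scale * rng.lognormal(0.0, 0.6), 0.05, 30.0)),
        "lam": lambda: rng.uniform(lo, hi),
    }
    return np.array([draw[name]() for name in spec.free])


def _bounds(spec: ModelSpec):
    lo, hi = spec.lam_bounds()
    table = {
        "mu1": (0.0, 360.0),
        "mu2": (0.0, 360.0),
        "k1": (0.0, K_MAX),
        "k2": (0.0, K_MAX),
        "lam": (lo, hi),
    }
    return [table[name] for name in spec.free]


def _canonicalize(spec: ModelSpec, p: np.ndarray) -> np.ndarray:
    """Report the dominant component first: λ ≥ 0.5, μ in [0, 360)."""
    mu1, k1, mu2, k2, lam = p
    if spec.second == "vm" and spec.lam_fixed is None and lam < 0.5:
        mu1, k1, mu2, k2, lam = mu2, k2, mu1, k1, 1.0 - lam
    if spec.second == "vm" and spec.lam_fixed == 0.5 and not spec.axial and k2 > k1:
        # equal-weight components: order the sharper peak first for determinism
        mu1, k1, mu2, k2 = mu2, k2, mu1, k1
    return np.array([mu1 % 360.0, k1, mu2 % 360.0, k2, lam])


def fit_model(
    sample: CircularSample | Sequence[float],
    spec: ModelSpec | str,
    n_starts: int = 5,
    seed: int = 0,
) -> ModelFit:
    """Fit one candidate model by bounded multi-start maximum likelihood.

    Each start draws random initial parameters (seeded) and runs L-BFGS-B
    with the analytic gradient; the best converged optimum is kept.  The
    uniform model has a closed-form likelihood.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    angles = sample.angles if isinstance(sample, CircularSample) else np.asarray(sample, float) % 360.0
    n = angles.size
    if spec.id == "M1":
        logl = -n * math.log(_TWO_PI)
        return ModelFit("M1", 0.0, 0.0, None, None, None, logl, -2 * logl, True, 0)
    if n < 3:
        raise ValueError("non-uniform models need at least 3 observations")

    theta = angles * _DEG
    rng = np.random.default_rng(seed)
    bounds = _bounds(spec)
    anchors, k_scale = _moment_anchors(angles)
    best_x, best_val, any_ok = None, np.inf, False
    for _ in range(max(1, n_starts)):
        x0 = _random_start(spec, rng, anchors, k_scale)
        res = minimize(
            lambda x: _nll_and_grad(theta, spec, x),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
            any_ok = any_ok or bool(res.success)
        elif res.success:
            any_ok = True

    p = _canonicalize(spec, spec.full_params(best_x))
    logl = -best_val
    two_peak = spec.second == "vm"
    mixture = spec.second != "none"
    return ModelFit(
        model=spec.id,
        mu1=float(p[_P_MU1]),
        k1=float(p[_P_K1]),
        mu2=float(p[_P_MU2]) if two_peak else None,
        k2=float(p[_P_K2]) if two_peak else None,
        lam=float(p[_P_LAM]) if mixture else None,
        logL=logl,
        AIC=2.0 * spec.free_params - 2.0 * logl,
        converged=any_ok,
        n_starts_used=max(1, n_starts),
    )


def select_model(
    sample: CircularSample | Sequence[float],
    seed: int = 0,
    n_starts: int = 5,
) -> SelectionResult:
    """Fit all ten candidates and pick the AIC minimiser."""
    angles = sample.angles if isinstance(sample, CircularSample) else np.asarray(sample, float)
    if angles.size < 5:
        raise ValueError("model selection needs at least 5 observations")
    fits: dict[str, ModelFit] = {}
    for i, mid in enumerate(MODEL_IDS):
        # distinct per-model substreams, deterministic in the caller's seed
        fits[mid] = fit_model(angles, mid, n_starts=n_starts, seed=seed * 101 + i)
    # Among models with substantial support (within 2 AIC of the minimum),
    # prefer parsimony: extra von Mises components must earn clearly more
    # than their AIC price before they displace a simpler pattern.
    aic_min = min(f.AIC for f in fits.values())
    best = min(
        (m for m in fits if fits[m].AIC - aic_min <= 2.0),
        key=lambda m: (MODEL_SPECS[m].free_params, fits[m].AIC, m),
    )
    return SelectionResult(fits=fits, best_id=best)


def run_consensus(
    sample: CircularSample | Sequence[float],
    runs: int = 100,
    threshold: int = 75,
    seed: int = 0,
    n_starts: int = 5,
) -> ConsensusResult:
    """Repeat model selection ``runs`` times with fresh random starts.

    The pattern is deemed consistent only when one model wins strictly more
    than ``threshold`` of the runs; otherwise the most-prevalent-model
    fallback rule decides.
    """
    if runs < 1 or threshold >= runs:
        raise ValueError("need runs >= 1 and threshold < runs")
    wins: dict[str, int] = {}
    winning_aics: dict[str, list[float]] = {}
    best_fits: dict[str, ModelFit] = {}
    for i in range(runs):
        sel = select_model(sample, seed=seed + i, n_starts=n_starts)
        b = sel.best
        wins[b.model] = wins.get(b.model, 0) + 1
        winning_aics.setdefault(b.model, []).append(b.AIC)
        prev = best_fits.get(b.model)
        if prev is None or b.AIC < prev.AIC:
            best_fits[b.model] = b
    top = max(wins.values())
    consistent = consensus_consistent(wins, threshold)
    if consistent:
        final = min(m for m, w in wins.items() if w == top)
        fallback = False
    else:
        final = fallback_most_prevalent(wins, winning_aics)
        fallback = True
    return ConsensusResult(
        runs=runs,
        win_counts=wins,
        consistent=consistent,
        final_model=final,
        fallback_used=fallback,
        winning_aics=winning_aics,
        final_fit=best_fits[final],
    )


def consensus_consistent(win_counts: dict[str, int], threshold: int = 75) -> bool:
    """The agreement rule: consistent only if one model wins STRICTLY more
    than ``threshold`` runs (75 of 100 wins is not enough; 76 is)."""
    return max(win_counts.values()) > threshold


def fallback_most_prevalent(
    win_counts: dict[str, int], winning_aics: dict[str, list[float]]
) -> str:
    """Pick among the two–three most prevalent winners of an inconsistent run.

    The candidate with the lowest median AIC over its winning runs is taken;
    ties break to fewer free parameters, then lexicographic model id.
    Calling this on a consistent result is a contract violation.
    """
    total = sum(win_counts.values())
    if win_counts and max(win_counts.values()) * 100 > 75 * total:
        raise ValueError("fallback must not be called on a consistent consensus")
    ranked = sorted(win_counts, key=lambda m: (-win_counts[m], m))[:3]
    return min(
        ranked,
        key=lambda m: (
            float(np.median(winning_aics[m])),
            MODEL_SPECS[m].free_params,
            m,
        ),
    )


def peaks_from_fit(fit: ModelFit) -> list[float]:
    """Peak directions implied by a fitted model: 0, 1 or 2 angles."""
    spec = MODEL_SPECS[fit.model]
    if spec.family == "uniform":
        return []
    if spec.family == "unimodal":
        return [fit.mu1 % 360.0]
    if spec.axial:
        return [fit.mu1 % 360.0, (fit.mu1 + 180.0) % 360.0]
    return [fit.mu1 % 360.0, (fit.mu2 or 0.0) % 360.0]
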