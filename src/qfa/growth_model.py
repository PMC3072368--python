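r"""Logistic growth modelling of culture density series and derived fitness.

Each spotted culture's density time course G(t) (integrated optical density,
arbitrary units) is summarised by the logistic population model

    dG/dt = r G (1 - G/K),   G(0) = G0,

whose analytical solution is

    G(t) = K G0 e^{rt} / (K + G0 (e^{rt} - 1)).

The inoculum density G0 is fixed during fitting (default 43 AU): all liquid
cultures are assumed to reach the same stationary density before dilution
and spotting, so the initial cell number per spot is common to the whole
experiment.  Growth rate r (day^-1) and carrying capacity K (AU) are
estimated per culture by bounded least squares.

Three phenotypes are derived from the fitted parameters:

* minimum doubling time ``T`` — time for the modelled population to reach
  2*G0, assuming exponential phase immediately after inoculation:
  ``T = (1/r) ln(2(K - G0)/(K - 2G0))``;
* maximum doubling rate ``MDR = 1/T`` (doublings/day);
* maximum doubling potential ``MDP = log2(K/G0)`` (doublings), the number
  of divisions from inoculum to carrying capacity viewed as a geometric
  progression.

The composite fitness ``F = MDR * MDP`` (doublings^2/day) weights the rate
of growth and the capacity to divide equally.  Cultures whose carrying
capacity never reaches twice the inoculum (K <= 2G0) never complete one
doubling; they are assigned MDR = 0 and hence F = 0 rather than an
undefined doubling time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rod_io import CultureSeries, ValidationError

logger = logging.getLogger("qfa")

#: Default fixed inoculum density, AU.
DEFAULT_G0 = 43.0
#: Upper bound on the growth rate during fitting, day^-1.
DEFAULT_R_MAX = 25.0
#: K is bounded above by this multiple of the maximum observed density.
K_MAX_FACTOR = 10.0
#: Relative objective tolerance for the least-squares optimiser.
FIT_TOLERANCE = 1e-10
#: Floor for degenerate growth-rate guesses.
R_GUESS_FLOOR = 0.1
R_GUESS_CEIL = DEFAULT_R_MAX


class InsufficientDataError(ValueError):
    """Fewer observations than the three needed to constrain (r, K)."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic model for one culture (G0 fixed)."""

    g0: float
    r: float
    K: float

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValidationError(f"G0 must be positive, got {self.g0}")
        if self.r < 0:
            raise ValidationError(f"r must be non-negative, got {self.r}")
        if self.K < self.g0:
            raise ValidationError(f"K ({self.K}) must be >= G0 ({self.g0})")


@dataclass(frozen=True)
class FitDiagnostics:
    rss: float
    n_points: int
    converged: bool
    initial_guess: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class FitnessPhenotypes:
    """Derived growth phenotypes; ``fitness`` is always ``mdr * mdp``."""

    t_double: float  # days; inf for non-doubling cultures
    mdr: float       # doublings / day
    mdp: float       # doublings
    fitness: float   # doublings^2 / day


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def logistic_density(t, params: LogisticParams):
    """Evaluate G(t) for the logistic model; accepts scalar or array ``t``."""
    t = np.asarray(t, dtype=float)
    g0, r, K = params.g0, params.r, params.K
    # Writing the solution as K / (1 + (K/G0 - 1) e^{-rt}) avoids overflow of
    # e^{rt} at large rt.
    out = K / (1.0 + (K / g0 - 1.0) * np.exp(-r * t))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Initial guesses
# ---------------------------------------------------------------------------

def guess_initial_params(
    times: np.ndarray,
    densities: np.ndarray,
    g0: float = DEFAULT_G0,
) -> tuple[float, float, float, bool]:
    """Heuristic starting values for the least-squares fit.

    K0 is the maximum observed density.  The time ``t*`` of fastest growth is
    located by linear interpolation: the midpoint of the observation interval
    with the steepest slope (earliest such interval on ties).  For the
    logistic model G'(t) peaks when G = K/2, at ``t* = ln(K/G0 - 1)/r``;
    inverting gives the rate guess ``r0 = ln(K0/G0 - 1)/t*``, clamped to a
    positive range.

    Returns ``(r0, K0, t_star, degenerate)``; ``degenerate`` is True when the
    culture never grows above G0, in which case a floor guess is returned.
    """
    times = np.asarray(times, dtype=float)
    densities = np.asarray(densities, dtype=float)
    k0 = float(np.max(densities))
    if k0 <= g0:
        return R_GUESS_FLOOR, g0 * (1.0 + 1e-6), float(times[0]), True

    dt = np.diff(times)
    slopes = np.diff(densities) / dt
    i = int(np.argmax(slopes))  # argmax takes the first maximum: earliest tie
    t_star = float(0.5 * (times[i] + times[i + 1]))
    if t_star <= 0:
        t_star = max(float(times[i + 1]), 1e-6)
    r0 = float(np.log(k0 / g0 - 1.0) / t_star) if k0 > 2 * g0 else R_GUESS_FLOOR
    r0 = float(np.clip(r0, R_GUESS_FLOOR, R_GUESS_CEIL))
    return r0, k0, t_star, False


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_logistic(
    series: CultureSeries | tuple[np.ndarray, np.ndarray],
    g0: float = DEFAULT_G0,
    r_max: float = DEFAULT_R_MAX,
) -> tuple[LogisticParams, FitDiagnostics]:
    """Least-squares fit of (r, K) to one culture's density series, G0 fixed.

    Bounds: r in [0, r_max], K in [G0, 10 x max observed density].  On
    optimiser failure a single restart from a perturbed guess is attempted;
    if that also fails, the degenerate no-growth fit (r = 0, K = G0) is
    returned with ``converged=False``.
    """
    if isinstance(series, CultureSeries):
        times, densities = series.times, series.densities
    else:
        times, densities = (np.asarray(a, dtype=float) for a in series)
    if len(times) < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {len(times)}")

    r0, k0, _, degenerate = guess_initial_params(times, densities, g0)
    if degenerate:
        params = LogisticParams(g0=g0, r=0.0, K=g0)
        rss = float(np.sum((densities - g0) ** 2))
        return params, FitDiagnostics(rss=rss, n_points=len(times),
                                      converged=False, initial_guess=(r0, k0),
                                      degenerate=True)

    k_hi = max(K_MAX_FACTOR * float(np.max(densities)), g0 * (1 + 1e-9))
    lo = np.array([0.0, g0])
    hi = np.array([r_max, k_hi])

    def residuals(theta: np.ndarray) -> np.ndarray:
        r, K = theta
        return logistic_density(times, LogisticParams(g0=g0, r=r, K=K)) - densities

    def attempt(x0: np.ndarray):
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        return least_squares(residuals, x0, bounds=(lo, hi),
                             ftol=FIT_TOLERANCE, xtol=FIT_TOLERANCE,
                             gtol=FIT_TOLERANCE, method="trf")

    x0 = np.array([r0, k0])
    try:
        sol = attempt(x0)
        ok = sol.success
    except Exception:  # pragma: no cover - scipy raises only on bad input
        ok = False
        sol = None
    if not ok:
        try:
            sol = attempt(x0 * np.array([1.5, 1.1]))
            ok = sol.success
        except Exception:  # pragma: no cover
            ok = False
    if not ok:
        logger.warning("logistic fit failed for culture; degenerate fallback")
        params = LogisticParams(g0=g0, r=0.0, K=g0)
        rss = float(np.sum((densities - g0) ** 2))
        return params, FitDiagnostics(rss=rss, n_points=len(times),
                                      converged=False, initial_guess=(r0, k0))

    r_hat, k_hat = float(sol.x[0]), float(max(sol.x[1], g0))
    params = LogisticParams(g0=g0, r=r_hat, K=k_hat)
    diags = FitDiagnostics(rss=float(2 * sol.cost), n_points=len(times),
                           converged=True, initial_guess=(r0, k0))
    return params, diags


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def doubling_time(params: LogisticParams) -> float:
    """Minimum time T (days) for the modelled population to reach 2*G0.

    Closed form: T = (1/r) ln(2(K - G0)/(K - 2G0)).  Returns ``inf`` for
    cultures that never double (K <= 2G0 or r = 0).
    """
    g0, r, K = params.g0, params.r, params.K
    if r <= 0 or K <= 2 * g0:
        return float("inf")
    return float(np.log(2.0 * (K - g0) / (K - 2.0 * g0)) / r)


def max_doubling_rate(params: LogisticParams) -> float:
    """MDR = 1/T (doublings/day); 0 for non-doubling cultures."""
    T = doubling_time(params)
    return 0.0 if np.isinf(T) else 1.0 / T


def max_doubling_potential(params: LogisticParams) -> float:
    """MDP = log2(K/G0): doublings from inoculum to carrying capacity."""
    return float(np.log2(params.K / params.g0))


def fitness(params: LogisticParams) -> FitnessPhenotypes:
    """All derived phenotypes for one culture; F = MDR * MDP exactly."""
    T = doubling_time(params)
    mdr = 0.0 if np.isinf(T) else 1.0 / T
    mdp = max_doubling_potential(params)
    return FitnessPhenotypes(t_double=T, mdr=mdr, mdp=mdp, fitness=mdr * mdp)


# ---------------------------------------------------------------------------
# Batch fitting
# ---------------------------------------------------------------------------

def fit_screen(
    series_list: Iterable[CultureSeries],
    g0: float = DEFAULT_G0,
    r_max: float = DEFAULT_R_MAX,
) -> pd.DataFrame:
    """Fit every culture of a screen and tabulate parameters and phenotypes.

    Per-culture failures never abort the batch: non-growing or non-converged
    cultures appear as flagged rows with F = 0.  Output rows are sorted by
    (orf, query, temperature, library, replicate) so the table is
    deterministic regardless of input order.
    """
    rows = []
    for s in series_list:
        a = s.annotation
        try:
            params, diags = fit_logistic(s, g0=g0, r_max=r_max)
            phen = fitness(params)
            flag = ""
            if diags.degenerate:
                flag = "no_growth"
            elif not diags.converged:
                flag = "fit_failed"
        except InsufficientDataError:
            params = LogisticParams(g0=g0, r=0.0, K=g0)
            diags = FitDiagnostics(rss=float("nan"), n_points=len(s),
                                   converged=False, initial_guess=(0.0, g0))
            phen = fitness(params)
            flag = "insufficient_data"
        rows.append({
            "orf": a.orf, "gene": a.gene, "query": a.query,
            "temperature": a.temperature, "library": a.library,
            "replicate": a.replicate, "barcode": a.barcode,
            "row": a.row, "col": a.col,
            "g0": params.g0, "r": params.r, "K": params.K,
            "rss": diags.rss, "n_points": diags.n_points,
            "converged": diags.converged,
            "t_double": phen.t_double, "mdr": phen.mdr, "mdp": phen.mdp,
            "fitness": phen.fitness, "flag": flag,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["orf", "query", "temperature", "library", "replicate"],
            kind="mergesort",
        ).reset_index(drop=True)
    return table
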