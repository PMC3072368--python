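"""Synthetic fitness screens with known truth, for testing the pipeline.

Two levels of simulation are provided, mirroring the two entry points of the
real pipeline:

* :func:`simulate_fitness_table` generates replicate fitness tables for a
  control (ura3-like) and a query screen directly on the fitness scale, with
  planted interaction strengths, for fast statistics-only tests;
* :func:`simulate_screen_curves` goes all the way down to density time
  series: per-culture logistic parameters are derived from the target
  fitness via :func:`fitness_to_logistic`, sampled at the photograph times
  with multiplicative log-normal noise, and emitted in the ROD export
  dialect so that the complete read -> fit -> score loop can be exercised.

Interactions are planted on the normalised-fitness scale: a planted gamma
is exactly the interaction strength gamma_2 the pipeline should recover.
Because the pipeline normalises each screen to mean fitness 1, planting
shifts would leak into the grand mean; the generator therefore rescales the
non-interacting genes by a common factor so both screens keep mean 1 and
the planted values survive normalisation exactly.  The rescaling gives each
null gene an interaction of order (sum of planted gammas)/n_genes, which is
recorded in the returned truth table.

What the generator deliberately omits: spatial plate effects (edge rows,
lighting gradients — corrected upstream by the image analysis), correlation
between neighbouring spots, batch effects between library versions, and
agar-dependent lag phases.  Passing tests therefore demonstrate the
statistical machinery, not robustness to those artifacts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_model import DEFAULT_G0, LogisticParams, logistic_density
from .rod_io import N_COLS, N_ROWS, CultureSeries, StrainAnnotation

#: Default photograph schedule, days since inoculation.
DEFAULT_TIMEPOINTS = tuple(np.linspace(0.25, 7.0, 15).round(4))


@dataclass
class SimulationConfig:
    """Generative settings for one two-screen comparison.

    Replicates follow the real screens' layout: ``replicates_per_library``
    crosses from each of ``n_libraries`` library versions (default 4 + 4 =
    8 replicates per gene).  Gene-level control fitness is log-normal on the
    F scale (``mean_fitness`` doublings^2/day with coefficient of variation
    set by ``fitness_log_sigma``); the query screen's background multiplier
    ``query_multiplier`` is the ratio M of query to control background
    fitness.  Noise: ``fitness_sigma`` is the additive Gaussian sd of a
    replicate's fitness relative to the screen mean (~15% replicate CV, the
    scale seen in arrayed-colony fitness data); ``density_sigma`` is the sd
    of multiplicative log-normal noise on densities in curve-level runs.
    """

    n_genes: int = 384
    replicates_per_library: int = 4
    n_libraries: int = 2
    g0: float = DEFAULT_G0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    query_multiplier: float = 0.5
    mean_fitness: float = 40.0
    fitness_log_sigma: float = 0.35
    planted_interactions: dict[str, float] = field(default_factory=dict)
    interaction_scale: str = "normalized"  # or "multiplicative"
    fitness_sigma: float = 0.15
    density_sigma: float = 0.05
    mdp_mean: float = 9.0
    mdp_sd: float = 0.5
    query_label: str = "simquery"
    control_label: str = "ura3D"
    temperature: float = 27.0
    seed: int = 0

    @property
    def n_replicates(self) -> int:
        return self.replicates_per_library * self.n_libraries

    @property
    def libraries(self) -> list[str]:
        return [f"SGAv{i + 2}" for i in range(self.n_libraries)]


def orf_name(i: int) -> str:
    return f"YSIM{i + 1:04d}W"


# ---------------------------------------------------------------------------
# Gene-level truth
# ---------------------------------------------------------------------------

def _gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene true normalised fitness means for both screens."""
    n = config.n_genes
    orfs = [orf_name(i) for i in range(n)]
    log_mu = np.log(config.mean_fitness) - 0.5 * config.fitness_log_sigma ** 2
    f = rng.lognormal(mean=log_mu, sigma=config.fitness_log_sigma, size=n)
    c = f / f.mean()  # true normalised control means; mean exactly 1

    gamma_req = np.array([config.planted_interactions.get(o, 0.0) for o in orfs])
    planted = gamma_req != 0.0
    # An enhancer can remove at most the fitness its gene has: a planted
    # gamma is representable only when c_g + gamma_g stays positive.  Where
    # the draw is too unfit, swap its fitness value with the largest
    # remaining unplanted draw (keeps the mean-1 construction intact).
    floor = 0.05
    spare = [i for i in np.argsort(-c) if not planted[i]]
    for i in np.flatnonzero(planted):
        if c[i] + gamma_req[i] < floor:
            while spare:
                j = spare.pop(0)
                if c[j] + gamma_req[i] >= floor:
                    c[i], c[j] = c[j], c[i]
                    break
            else:
                raise ValueError(
                    f"no gene fit enough to carry planted gamma {gamma_req[i]}")
    if config.interaction_scale == "multiplicative":
        t = c * (1.0 + gamma_req)
        t = t / t.mean()
    elif config.interaction_scale == "normalized":
        t = c + gamma_req
        if planted.any() and (~planted).any():
            # Rescale null genes so the query screen keeps grand mean 1 and
            # the planted values survive the pipeline's normalisation exactly.
            beta = (n - t[planted].sum()) / c[~planted].sum()
            t[~planted] = c[~planted] * beta
        elif planted.all():
            t = t / t.mean()
    else:
        raise ValueError(f"unknown interaction_scale {config.interaction_scale!r}")
    if np.any(t < 0):
        raise ValueError("planted interactions drive query fitness negative")

    return pd.DataFrame({
        "orf": orfs,
        "gene": [f"SIM{i + 1}" for i in range(n)],
        "control_mean_norm": c,
        "query_mean_norm": t,
        "gamma_planted": gamma_req,
        "gamma_true": t - c,
        "control_fitness": config.mean_fitness * c,
        "query_fitness": config.query_multiplier * config.mean_fitness * t,
    })


# ---------------------------------------------------------------------------
# Fitness-table simulation
# ---------------------------------------------------------------------------

def _replicate_table(truth: pd.DataFrame, config: SimulationConfig,
                     rng: np.random.Generator, screen: str) -> pd.DataFrame:
    scale = config.mean_fitness
    col = "control_fitness"
    query = config.control_label
    if screen == "query":
        scale *= config.query_multiplier
        col = "query_fitness"
        query = config.query_label
    rows = []
    nrep = config.n_replicates
    noise = rng.normal(0.0, config.fitness_sigma * scale,
                       size=(len(truth), nrep)) if config.fitness_sigma > 0 else \
        np.zeros((len(truth), nrep))
    for gi, g in enumerate(truth.itertuples()):
        k = 0
        for lib in config.libraries:
            for rep in range(1, config.replicates_per_library + 1):
                rows.append({
                    "orf": g.orf, "gene": g.gene, "query": query,
                    "temperature": config.temperature, "library": lib,
                    "replicate": rep,
                    "fitness": max(getattr(g, col) + noise[gi, k], 0.0),
                })
                k += 1
    return pd.DataFrame(rows)


def simulate_fitness_table(
    config: SimulationConfig, seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicate-level fitness tables for control and query screens.

    Returns ``(control, query, truth)``; identical seeds give identical
    tables.  ``truth`` records, per gene, the true normalised means of both
    screens, the requested planted gamma and the exact effective gamma
    (``gamma_true``) after the generator's mean-preserving rescaling.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = _gene_truth(config, rng)
    control = _replicate_table(truth, config, rng, "control")
    query = _replicate_table(truth, config, rng, "query")
    return control, query, truth


# ---------------------------------------------------------------------------
# Fitness -> logistic parameters
# ---------------------------------------------------------------------------

def fitness_to_logistic(mdr: float, mdp: float, g0: float = DEFAULT_G0) -> LogisticParams:
    """Logistic parameters whose derived phenotypes are (MDR, MDP) exactly.

    Inverts the phenotype definitions: K = G0 * 2^MDP and, from T = 1/MDR,
    r = MDR * ln(2(K - G0)/(K - 2G0)).  Requires MDP > 1 (so K > 2G0, i.e.
    the culture completes at least one doubling) and MDR > 0.
    """
    if mdp <= 1:
        raise ValueError(f"MDP must exceed 1 for a doubling-time representation, got {mdp}")
    if mdr <= 0:
        raise ValueError(f"MDR must be positive, got {mdr}")
    K = g0 * 2.0 ** mdp
    r = mdr * np.log(2.0 * (K - g0) / (K - 2.0 * g0))
    return LogisticParams(g0=g0, r=float(r), K=float(K))


# ---------------------------------------------------------------------------
# Curve-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedScreen:
    """One screen's raw materials in pipeline-ingestible form."""

    label: str
    observations: pd.DataFrame           # ROD-dialect density rows
    annotations: list[StrainAnnotation]
    inoculation_times: dict[str, _dt.datetime]
    params: pd.DataFrame                 # per-culture true (r, K)


_EPOCH = _dt.datetime(2009, 1, 1, 8, 0, 0)


def _screen_curves(truth: pd.DataFrame, config: SimulationConfig,
                   rng: np.random.Generator, screen: str) -> SimulatedScreen:
    per_plate = N_ROWS * N_COLS
    if config.n_genes > per_plate:
        raise ValueError(f"curve-level simulation supports up to {per_plate} genes per plate")
    scale = config.mean_fitness
    col = "control_mean_norm"
    query = config.control_label
    if screen == "query":
        scale *= config.query_multiplier
        col = "query_mean_norm"
        query = config.query_label

    mdp = np.clip(rng.normal(config.mdp_mean, config.mdp_sd, size=config.n_genes),
                  2.0, 13.0)
    times = np.asarray(config.timepoints, dtype=float)

    obs_rows, annotations, inoc, par_rows = [], [], {}, []
    plate_i = 0
    for lib in config.libraries:
        for rep in range(1, config.replicates_per_library + 1):
            plate_i += 1
            barcode = f"SIM{query}{plate_i:03d}"
            inoc_time = _EPOCH + _dt.timedelta(days=plate_i)  # staggered robot runs
            inoc[barcode] = inoc_time
            lognoise = rng.normal(0.0, config.density_sigma,
                                  size=(config.n_genes, len(times))) \
                if config.density_sigma > 0 else np.zeros((config.n_genes, len(times)))
            for gi, g in enumerate(truth.itertuples()):
                f_target = scale * getattr(g, col)
                row, colpos = divmod(gi, N_COLS)
                ann = StrainAnnotation(
                    orf=g.orf, gene=g.gene, query=query,
                    temperature=config.temperature, library=lib, replicate=rep,
                    barcode=barcode, row=row + 1, col=colpos + 1,
                )
                annotations.append(ann)
                if f_target <= 0:
                    densities = np.full_like(times, config.g0)
                    r_true, k_true = 0.0, config.g0
                else:
                    params = fitness_to_logistic(f_target / mdp[gi], mdp[gi], config.g0)
                    densities = logistic_density(times, params) * np.exp(lognoise[gi])
                    r_true, k_true = params.r, params.K
                par_rows.append({"orf": g.orf, "query": query, "library": lib,
                                 "replicate": rep, "r": r_true, "K": k_true,
                                 "mdp": mdp[gi]})
                for t, d in zip(times, densities):
                    obs_rows.append({
                        "barcode": barcode, "row": row + 1, "col": colpos + 1,
                        "timestamp": inoc_time + _dt.timedelta(days=float(t)),
                        "density": float(d),
                    })
    observations = pd.DataFrame(obs_rows)
    observations["timestamp"] = pd.to_datetime(observations["timestamp"])
    return SimulatedScreen(label=query, observations=observations,
                           annotations=annotations, inoculation_times=inoc,
                           params=pd.DataFrame(par_rows))


def simulate_screen_curves(
    config: SimulationConfig, seed: int | None = None,
) -> tuple[SimulatedScreen, SimulatedScreen, pd.DataFrame]:
    """Density time series for a control and a query screen.

    Each gene's per-screen target fitness is decomposed into (MDR, MDP) with
    a gene-specific doubling potential, converted to logistic parameters,
    sampled at the photograph schedule and multiplied by log-normal noise
    ``exp(N(0, density_sigma^2))``.  One plate (barcode) per (library,
    replicate); staggered inoculation timestamps exercise the time-origin
    bookkeeping.  Returns ``(control, query, truth)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = _gene_truth(config, rng)
    control = _screen_curves(truth, config, rng, "control")
    query = _screen_curves(truth, config, rng, "query")
    return control, query, truth


def series_from_screen(screen: SimulatedScreen) -> list[CultureSeries]:
    """Convenience: assemble simulated observations into culture series."""
    from .rod_io import assemble_series
    return assemble_series(screen.observations, screen.annotations,
                           screen.inoculation_times)
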