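r"""Genetic interaction strength (GIS) between a query and a control screen.

A query screen measures fitness F of double mutants ``xyz yfgD`` (query
mutation combined with every library deletion); a control screen measures
``ura3D yfgD`` with the neutral ura3 deletion approximating wild type.
Under multiplicative genetic independence

    F_{xyz yfgD} = M * F_{ura3D yfgD},   M = F_xyz / F_ura3D,

a constant independent of the particular deletion.  After normalising each
screen so that its mean fitness across all deletions equals 1, independence
predicts equal normalised fitness in both screens, and for each deletion a
two-group linear model is fitted to its normalised replicate fitnesses

    F_hat_ij = mu + gamma_i + eps_ij,   gamma_1 = 0 (control), eps iid normal,

where i = 1 (control) / 2 (query) and j runs over replicates (typically
8 = 4 from each of two library versions).  The fitted gamma_2 is the
genetic interaction strength: positive = suppressor, negative = enhancer of
the query mutation's fitness defect.  Per-deletion p-values from the model's
t statistic are Benjamini-Hochberg corrected within each screen comparison
to q-values; the paper-style calls are q < 0.05, with |GIS| >= 0.5 marking
"strong" interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("qfa")

#: Default significance and effect-size thresholds for interaction calls.
Q_THRESHOLD = 0.05
STRONG_THRESHOLD = 0.5

#: Revertant filter defaults (cdc13-1 screens): replicates whose modelled
#: density at 36 C exceeds this after 6 days are treated as revertants.
REVERTANT_DENSITY_AU = 25000.0
REVERTANT_DAY = 6.0
REVERTANT_MAX_FLAGGED = 3

#: Marker-linkage exclusion radius, kilobases.
LINKAGE_KB = 20.0

#: Canonical columns of a GIS table.
GIS_COLUMNS = ["orf", "gene", "n_control", "n_query", "mu", "gis", "se",
               "p", "q", "classification", "strong"]


class NormalizationError(ValueError):
    """The screen's mean fitness is zero; normalisation is undefined."""


@dataclass(frozen=True)
class InteractionSummary:
    """Table-1-style percentages of interacting deletions for one screen."""

    screen: str
    n_assayed: int
    pct_suppressors_any: float
    pct_suppressors_strong: float
    pct_enhancers_any: float
    pct_enhancers_strong: float


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def strip_revertant_repeats(
    fitness_table: pd.DataFrame,
    check_table: pd.DataFrame,
    density_threshold: float = REVERTANT_DENSITY_AU,
    day: float = REVERTANT_DAY,
    max_flagged: int = REVERTANT_MAX_FLAGGED,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove likely revertant/SGA-failure replicates from a cdc13-1 screen.

    cdc13-1 strains cannot grow at 36 C, so a replicate whose fitted model
    predicts density above ``density_threshold`` AU after ``day`` days in the
    36 C screen (``check_table``) is either a revertant or an SGA failure.
    Flagged replicates of a gene are stripped from ``fitness_table`` only
    when at most ``max_flagged`` replicates of that gene are flagged; if more
    are flagged the growth is treated as genuine suppression and all
    replicates are retained.  Replicates with no matching 36 C fit are
    retained and logged.

    Matching is by (orf, library, replicate).  Returns (filtered table,
    report of removed rows).
    """
    from .growth_model import LogisticParams, logistic_density

    key = ["orf", "library", "replicate"]
    check = check_table.drop_duplicates(subset=key).set_index(key)

    # Modelled density at `day` for each 36C fit, vectorised.
    g0 = check["g0"].to_numpy(float)
    r = check["r"].to_numpy(float)
    K = np.maximum(check["K"].to_numpy(float), g0)
    with np.errstate(over="ignore"):
        modeled = K / (1.0 + (K / g0 - 1.0) * np.exp(-r * day))
    check = check.assign(_modeled=modeled)

    idx = pd.MultiIndex.from_frame(fitness_table[key])
    matched = idx.isin(check.index)
    modeled_for_row = np.full(len(fitness_table), np.nan)
    modeled_for_row[matched] = check["_modeled"].reindex(idx[matched]).to_numpy()
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        logger.info("revertant filter: %d replicates without a 36C fit retained",
                    n_unmatched)

    flagged = pd.Series(modeled_for_row > density_threshold,
                        index=fitness_table.index)
    per_gene = flagged.groupby(fitness_table["orf"]).transform("sum")
    remove = flagged & (per_gene <= max_flagged)

    report = fitness_table[remove].copy()
    report["reason"] = "revertant_36C"
    return fitness_table[~remove].reset_index(drop=True), report


def apply_exclusions(
    fitness_table: pd.DataFrame,
    exclude_orfs: set[str] | None = None,
    gene_coordinates: pd.DataFrame | None = None,
    marker_loci: pd.DataFrame | None = None,
    linkage_kb: float = LINKAGE_KB,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop technically problematic deletions before interaction scoring.

    ``exclude_orfs`` lists ORFs to remove outright (auxotrophy-pathway genes,
    known SGA-selection genes, experiment-specific missing strains).  When
    ``gene_coordinates`` (orf, chrom, midpoint_kb) and ``marker_loci``
    (chrom, position_kb) are given, ORFs whose deletion-locus midpoint lies
    within ``linkage_kb`` of any marker on the same chromosome are also
    removed (they co-segregate with the marker during the cross, so their
    apparent fitness is an artifact).  A listed ORF missing from the
    coordinate table is retained with a warning.

    Returns (filtered table, per-reason report).
    """
    exclude_orfs = set(exclude_orfs or ())
    reasons: dict[str, str] = {o: "listed" for o in exclude_orfs}

    if marker_loci is not None and len(marker_loci):
        if gene_coordinates is None:
            logger.warning("marker loci given without gene coordinates; "
                           "linkage exclusion skipped")
        else:
            coords = gene_coordinates.set_index("orf")
            present = fitness_table["orf"].unique()
            missing = [o for o in present if o not in coords.index]
            if missing:
                logger.warning("no coordinates for %d ORFs; retained", len(missing))
            for orf in present:
                if orf not in coords.index:
                    continue
                chrom = coords.at[orf, "chrom"]
                mid = coords.at[orf, "midpoint_kb"]
                near = marker_loci[marker_loci["chrom"] == chrom]
                if len(near) and (abs(near["position_kb"] - mid) <= linkage_kb).any():
                    reasons.setdefault(orf, "marker_linkage")

    drop = fitness_table["orf"].isin(reasons)
    report = pd.DataFrame({
        "orf": sorted(reasons),
        "reason": [reasons[o] for o in sorted(reasons)],
    })
    counts = report["reason"].value_counts().to_dict()
    logger.info("exclusions: %s", counts or "none")
    return fitness_table[~drop].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_fitness(fitness_table: pd.DataFrame,
                      column: str = "fitness") -> pd.DataFrame:
    """Divide every culture's fitness by the screen's grand mean.

    After normalisation the mean of ``column`` over all retained cultures is
    exactly 1, putting the query and control screens on a common scale.
    Idempotent.  Raises :class:`NormalizationError` on a degenerate screen
    whose mean fitness is 0.
    """
    if fitness_table.empty:
        raise NormalizationError("empty fitness table")
    grand_mean = float(fitness_table[column].mean())
    if grand_mean == 0:
        raise NormalizationError("grand mean fitness is zero")
    out = fitness_table.copy()
    out[column] = out[column] / grand_mean
    return out


# ---------------------------------------------------------------------------
# Per-gene interaction model
# ---------------------------------------------------------------------------

def estimate_gis(control_values, query_values) -> tuple[float, float, float, float]:
    """Fit the two-group interaction model to one deletion's replicates.

    Returns ``(mu, gamma2, se, p)`` where ``mu`` is the control-group mean
    normalised fitness, ``gamma2 = mean(query) - mean(control)`` is the
    interaction strength, and ``se``/``p`` come from the pooled-variance t
    statistic on ``n_control + n_query - 2`` degrees of freedom (the OLS
    solution of the one-factor model with the control effect fixed at 0).

    Groups with fewer than 2 replicates give ``p = se = NaN`` (the record is
    kept but excluded from FDR correction).  Zero pooled variance gives the
    conservative sentinel ``p = 1``: artifactually identical replicates must
    not create discoveries.
    """
    c = np.asarray(control_values, dtype=float)
    q = np.asarray(query_values, dtype=float)
    mu = float(c.mean()) if len(c) else float("nan")
    gamma2 = float(q.mean() - c.mean()) if len(c) and len(q) else float("nan")
    n1, n2 = len(c), len(q)
    if n1 < 2 or n2 < 2:
        return mu, gamma2, float("nan"), float("nan")
    df = n1 + n2 - 2
    pooled_var = (c.var(ddof=1) * (n1 - 1) + q.var(ddof=1) * (n2 - 1)) / df
    if pooled_var == 0:
        return mu, gamma2, 0.0, 1.0
    se = float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))
    t = gamma2 / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return mu, gamma2, se, p


def gis_table(control: pd.DataFrame, query: pd.DataFrame,
              column: str = "fitness") -> pd.DataFrame:
    """Per-gene interaction estimates for a whole screen comparison.

    ``control`` and ``query`` are normalised fitness tables (one row per
    replicate culture).  Statistics are computed vectorised over genes and
    equal :func:`estimate_gis` applied per gene.  Genes present in only one
    screen are dropped (no comparison possible).
    """
    def moments(df: pd.DataFrame) -> pd.DataFrame:
        g = df.groupby("orf")[column]
        out = g.agg(n="size", mean="mean", var=lambda x: x.var(ddof=1))
        out["gene"] = df.groupby("orf")["gene"].first()
        return out

    mc, mq = moments(control), moments(query)
    shared = mc.index.intersection(mq.index)
    mc, mq = mc.loc[shared], mq.loc[shared]

    n1 = mc["n"].to_numpy(float)
    n2 = mq["n"].to_numpy(float)
    gamma2 = mq["mean"].to_numpy() - mc["mean"].to_numpy()
    dof = n1 + n2 - 2
    defined = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (mc["var"].to_numpy() * (n1 - 1) + mq["var"].to_numpy() * (n2 - 1)) / dof
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = gamma2 / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero_var = defined & (pooled == 0)
    se[zero_var] = 0.0
    p[zero_var] = 1.0
    se[~defined] = np.nan
    p[~defined] = np.nan

    table = pd.DataFrame({
        "orf": shared,
        "gene": mc["gene"].to_numpy(),
        "n_control": n1.astype(int),
        "n_query": n2.astype(int),
        "mu": mc["mean"].to_numpy(),
        "gis": gamma2,
        "se": se,
        "p": p,
    }).sort_values("orf", kind="mergesort").reset_index(drop=True)
    table["q"] = fdr_adjust(table["p"].to_numpy())
    return classify_interactions(table)


# ---------------------------------------------------------------------------
# Multiple testing and classification
# ---------------------------------------------------------------------------

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN sentinels pass through.

    One correction is applied per screen comparison (matching the per-screen
    interaction tables), not globally across screens.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_interactions(records: pd.DataFrame,
                          q_threshold: float = Q_THRESHOLD,
                          strong_threshold: float = STRONG_THRESHOLD) -> pd.DataFrame:
    """Label each gene suppressor / enhancer / none, and flag strong effects.

    Suppressor: q < ``q_threshold`` and GIS > 0.  Enhancer: q < threshold and
    GIS < 0.  ``strong``: |GIS| >= ``strong_threshold``.  The stringent
    interactor lists are significant AND strong.
    """
    out = records.copy()
    sig = out["q"] < q_threshold
    out["classification"] = "none"
    out.loc[sig & (out["gis"] > 0), "classification"] = "suppressor"
    out.loc[sig & (out["gis"] < 0), "classification"] = "enhancer"
    out["strong"] = out["gis"].abs() >= strong_threshold
    return out


def summarize_interactions(records: pd.DataFrame, n_assayed: int | None = None,
                           screen: str = "") -> InteractionSummary:
    """Percentages of assayed deletions called suppressors/enhancers.

    The denominator is the number of deletions assayed after all exclusions
    (``n_assayed``, default: number of records); percentages are reported to
    two decimals.
    """
    if n_assayed is None:
        n_assayed = len(records)
    if n_assayed == 0:
        raise ValueError("n_assayed must be positive")
    sup = records["classification"] == "suppressor"
    enh = records["classification"] == "enhancer"
    pct = lambda mask: round(100.0 * int(mask.sum()) / n_assayed, 2)
    return InteractionSummary(
        screen=screen,
        n_assayed=int(n_assayed),
        pct_suppressors_any=pct(sup),
        pct_suppressors_strong=pct(sup & records["strong"]),
        pct_enhancers_any=pct(enh),
        pct_enhancers_strong=pct(enh & records["strong"]),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def fit_comparison_regression(control_means, query_means) -> tuple[float, float]:
    """OLS line of per-gene mean query fitness on control fitness.

    Used for the fitness-plot "expected fitness" line; its vertical
    displacement is a diagnostic variant of the interaction score (the
    canonical score is the linear-model gamma2).
    """
    x = np.asarray(control_means, dtype=float)
    y = np.asarray(query_means, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 genes for a regression")
    if np.var(x) == 0:
        raise ValueError("zero variance in control fitness")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def assign_region(
    gis_a: float, gis_b: float,
    sig_a: bool, sig_b: bool,
    strong_threshold: float = STRONG_THRESHOLD,
) -> int | None:
    """Place a gene in the 3x3 grid of a two-screen interaction comparison.

    Axis A (e.g. vs cdc13-1) is plotted vertically, axis B (e.g. vs yku70D)
    horizontally.  An axis counts as suppressing/enhancing only when the gene
    is significant on that axis (q below threshold) with |GIS| >=
    ``strong_threshold``; otherwise it is neutral.  Regions are numbered 1-9
    reading the grid rows top to bottom (A suppressor, neutral, enhancer) and
    columns left to right (B enhancer, neutral, suppressor): region 1 =
    suppress A & enhance B, region 3 = suppress both, region 7 = enhance
    both, region 9 = enhance A & suppress B.  A gene neutral on both axes is
    in region 5 if significant on either axis, else in the interior
    (``None``): the central region holds genes that interact significantly
    but below the strong-effect cutoff.
    """
    def status(g: float, sig: bool) -> int:
        if sig and abs(g) >= strong_threshold:
            return 1 if g > 0 else -1
        return 0

    a, b = status(gis_a, sig_a), status(gis_b, sig_b)
    if a == 0 and b == 0:
        return 5 if (sig_a or sig_b) else None
    row = {1: 0, 0: 1, -1: 2}[a]            # top: A suppressor
    col = {-1: 0, 0: 1, 1: 2}[b]            # left: B enhancer
    return 3 * row + col + 1


def region_table(records_a: pd.DataFrame, records_b: pd.DataFrame,
                 q_threshold: float = Q_THRESHOLD,
                 strong_threshold: float = STRONG_THRESHOLD) -> pd.DataFrame:
    """Region assignment for every gene shared by two GIS tables."""
    a = records_a.set_index("orf")
    b = records_b.set_index("orf")
    shared = a.index.intersection(b.index)
    rows = []
    for orf in shared:
        region = assign_region(
            a.at[orf, "gis"], b.at[orf, "gis"],
            bool(a.at[orf, "q"] < q_threshold),
            bool(b.at[orf, "q"] < q_threshold),
            strong_threshold=strong_threshold,
        )
        rows.append({"orf": orf, "gene": a.at[orf, "gene"],
                     "gis_a": a.at[orf, "gis"], "gis_b": b.at[orf, "gis"],
                     "region": 0 if region is None else region})
    return pd.DataFrame(rows)
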