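# Methods

## The measurement model

Quantitative fitness analysis (QFA) measures the fitness of arrayed
microbial cultures: dilute liquid cultures are spotted in a 384-position
grid (16 x 24) on solid agar, plates are photographed repeatedly, and image
analysis reduces each photograph to one integrated optical density (IOD,
"Trimmed Area", arbitrary units, AU) per spot. This package consumes those
tab-delimited density exports; image segmentation is upstream and out of
scope.

Each culture's density time course G(t) is summarised by the logistic
population model

    dG/dt = r G (1 − G/K),  G(0) = G0,
    G(t) = K G0 e^{rt} / (K + G0 (e^{rt} − 1)),

implemented in the overflow-safe form K / (1 + (K/G0 − 1) e^{−rt}).
**G0 is fixed** (default 43 AU, configurable per experiment and never
re-fitted): all inocula are assumed to come from liquid cultures that
reached a common stationary density before dilution, so the initial cell
number per spot is a property of the experiment, not of the strain. Fixing
G0 removes a parameter that the early, sparsely sampled part of the curve
cannot constrain.

(r, K) are estimated per culture by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective), bounds
r ∈ [0, 25] d⁻¹ and K ∈ [G0, 10 × max observed density], tolerances 1e−10
on objective, step and gradient, with one restart from a perturbed guess on
failure and a degenerate fallback (r = 0, K = G0, `converged=False`) so a
batch never aborts. Initial guesses: K0 = max observed density; the time t*
of fastest growth is the midpoint of the steepest observation interval
(linear interpolation between photographs; earliest interval on ties), and
since the logistic inflection G = K/2 occurs at t* = ln(K/G0 − 1)/r, the
rate guess is r0 = ln(K0/G0 − 1)/t*, clamped to [0.1, 25] d⁻¹. Cultures
that never grow above G0 get a flagged degenerate guess.

## Fitness phenotypes

From the fitted parameters three phenotypes are derived:

* minimum doubling time **T = (1/r) ln(2(K − G0)/(K − 2G0))** — the time to
  reach density 2 G0, assuming exponential phase right after inoculation;
* maximum doubling rate **MDR = 1/T** (doublings/day);
* maximum doubling potential **MDP = log₂(K/G0)** (doublings), the number
  of divisions from inoculum to carrying capacity viewed as a geometric
  progression;
* composite fitness **F = MDR × MDP** (doublings²/day), weighting growth
  rate and division capacity equally.

A culture with K ≤ 2 G0 never completes one doubling: T is infinite and
MDR, hence F, is set to 0 with a flag. This sentinel (rather than a
negative or undefined logarithm) keeps dead and barely-growing cultures in
the downstream statistics with a well-defined fitness of zero. The closed
forms are validated in the test suite against independent numerical
oracles: direct ODE integration for G(t) and root-finding on G(T) = 2 G0
for T. F is invariant to a joint rescaling of density units applied to
observations and G0.

## Genetic interaction strength

A query screen (e.g. *cdc13-1 yfgΔ* double mutants) is compared with a
control screen (*ura3Δ yfgΔ*, neutral background). Under multiplicative
genetic independence F_query,g = M · F_control,g with
M = F_query-background / F_control-background independent of the deletion
g. Each screen is therefore normalised to mean fitness 1 across all
retained cultures (idempotent; degenerate all-zero screens are an error),
after which independence predicts equal normalised fitness, and for each
deletion the two-group linear model

    F̂_ij = μ + γ_i + ε_ij,  γ_1 = 0,  ε_ij ~ N(0, σ²) iid,

is fitted to the normalised replicate fitnesses (i = 1 control, i = 2
query; typically 8 replicates per group, 4 from each of two library
versions). The OLS solution is γ₂ = mean(query) − mean(control) with the
pooled-variance t statistic on n₁ + n₂ − 2 degrees of freedom; this
closed form is the implementation, and the test suite checks it against an
independently coded t test at 1e−10. γ₂ is the genetic interaction
strength (GIS): positive = suppressor, negative = enhancer of the query's
fitness defect.

Numerical edge rules: a group with fewer than 2 replicates gives an
undefined p (NaN; the record is kept but excluded from FDR); zero pooled
variance gives p = 1, so artifactually identical replicates can never
create discoveries. P-values are Benjamini–Hochberg corrected to q-values
separately within each (query screen, temperature) comparison — the family
is the per-screen gene list, matching the per-screen interactor tables.
Calls: significant at q < 0.05, "strong" at |GIS| ≥ 0.5; the stringent
interactor lists require both. The regression of per-gene query fitness on
control fitness (the "expected fitness" line of the fitness plot, whose
vertical displacement is an alternative GIS reading) is provided as a plot
diagnostic only; the linear-model γ₂ is canonical, since the two views
coincide only when the regression slope equals M.

Quality filters applied before scoring:

* **Revertant stripping** (cdc13-1 screens): cdc13-1 cells cannot grow at
  36 °C, so a replicate whose fitted model predicts density > 25 000 AU
  after 6 days in the 36 °C screen is a likely revertant or SGA failure
  and is stripped — but only when at most 3 replicates of that gene are
  flagged; more widespread growth is treated as genuine suppression and
  everything is retained. The threshold is strict (> 25 000).
* **Exclusions**: listed ORFs (auxotrophy-pathway genes, SGA-selection
  genes, experiment-specific missing strains) and ORFs whose deletion-locus
  midpoint lies within 20 kb of an SGA marker on the same chromosome
  (linked loci co-segregate with the marker, so their apparent fitness is
  artifactual). The per-reason counts are reported so the summary
  denominator (n_assayed) is auditable.

## Two-screen comparison regions

Comparing GIS against two queries (vertical axis A, horizontal axis B)
partitions genes into a 3 × 3 grid. An axis counts as suppressing or
enhancing only when the gene is significant on that axis with |GIS| ≥ 0.5;
otherwise it is neutral. Regions are numbered 1–9 row-wise from top-left
(suppress A & enhance B) to bottom-right (enhance A & suppress B); genes
neutral on both axes sit in the central region 5 if significant on either
axis and otherwise in the interior. The published plot deliberately blurs
region borders, so counts near boundaries shift with the rule; the crisp
rule here (thresholds configurable) exists to make the partition total and
reproducible.

## The synthetic-data generator

`simulate` emulates the two inputs the pipeline accepts.

*Fitness level.* Gene background fitness is log-normal on the F scale
(mean 40 doublings²/day, log-sd 0.35 — a wide but realistic spread for a
deletion collection), normalised to per-gene control means c_g with grand
mean exactly 1. The query background multiplier defaults to M = 0.5 (the
query mutation halves fitness, as for a telomere-capping mutant near its
restrictive temperature). Interactions are planted **on the normalised
scale**: the query's per-gene mean is c_g + γ_g, so a planted γ is exactly
the γ₂ the pipeline should report. Because planting shifts the query
screen's grand mean, the generator rescales the unplanted genes by a
common factor so both screens keep mean 1 and the planted values survive
the pipeline's normalisation exactly; the resulting O(Σγ/n) nudge to null
genes is recorded in the returned truth table (`gamma_true`). An enhancer
can remove at most the fitness its gene has, so a planted γ that would
drive c_g + γ below a small floor is re-assigned by swapping fitness draws
with the largest unplanted gene — strong enhancers are only representable
on reasonably fit genes, as in real screens. A multiplicative
parameterisation (query mean = c_g (1 + γ_g)) is available for realism.
Replicate noise is additive Gaussian with sd 0.15 of the screen mean
(~15% replicate CV, the scale of arrayed-colony fitness variability), and
the layout is the real screens' 4 + 4 two-library structure.

*Curve level.* Each gene's per-screen target F is split into MDR and MDP
using a gene-specific doubling potential ~N(9, 0.5²) clipped to [2, 13]
(carrying capacities of order 10³–10⁴ × G0), inverted to logistic
parameters via K = G0·2^MDP, r = MDR·ln(2(K − G0)/(K − 2G0)) (an exact
inverse of the phenotype definitions, round-trip tested), sampled at 15
photograph times spanning 0.25–7 days, and multiplied by log-normal noise
exp(N(0, 0.05²)) — photography and colony-morphology noise is
scale-proportional. One plate per (library, replicate) with staggered
inoculation timestamps exercises the time-origin bookkeeping. Everything
is reproducible from a single seed.

What the generator does **not** model: spatial plate effects (edge rows,
lighting gradients — corrected upstream by the image analysis), spot-to-
spot correlation, library batch effects, lag-phase variation, and
revertants. Passing tests therefore validate the statistical machinery and
the plumbing, not robustness to those artifacts.

## Numerical and design notes

* Elapsed time is measured from a per-barcode inoculation timestamp; when
  absent the origin falls back to the first photograph time minus a
  configurable offset (default 0). Duplicate timestamps collapse by mean
  density; series assembly is invariant to input row order.
* Column mappings for the density exports are config-driven (YAML
  dialects) because export schemas vary between database versions;
  malformed rows are skipped and counted by default, with a strict mode
  that aborts.
* Slow growers that do not saturate within the photograph window leave K
  (hence MDP and F) slightly under-determined even without noise; in the
  end-to-end synthetic loop this contributes GIS errors of order 0.005 for
  the least fit genes — far below the 0.5 effect threshold. Extending the
  photograph window removes it.
* At exactly zero replicate noise the zero-variance sentinel (p = 1) makes
  every gene non-significant by construction; significance-based checks
  are meaningful only with noise, while effect-size recovery is exact.
* Temperature pairing between query and control screens defaults to
  nearest-temperature (cdc13-1 20↔20, 27↔27, 36↔37; yku70Δ 23↔20, 30↔27,
  37↔37, 37.5↔37) and is config-overridable.
* Problem sizes used by the test suite and the acceptance script — 4 000
  genes at 8 + 8 replicates for calibration/recovery, 25 seeds, a 96-gene
  curve-level screen for the end-to-end loop — were chosen as the smallest
  sizes at which the measured quantities are stable; the genome-scale
  reproduction of the published summary table additionally needs the
  original parameter tables (an external download) and is wired into the
  test suite for when they are present.

## Known limitations

Only the logistic model is offered (no Gompertz/Baranyi, no lag-time
phenotype, no Bayesian fitting). The published summary-table percentages
can only be reproduced from the original genome-wide parameter tables,
which are not redistributable here; the exact exclusion lists behind the
published denominator of 4 120 assayed deletions are likewise external, so
that denominator is a configuration input. Region counts near the ±0.5
boundary depend on the crisp region rule and will not exactly match a
hand-curated, deliberately blurred published partition.
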