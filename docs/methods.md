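# Methods

This note records the statistical models, defaults, and design choices
behind `growthqtl`, and what the synthetic-data validation does and does
not establish.

## Synthetic-data generator

The generator emulates a multi-environment UAS height study on
biparental RIL populations.  Its defaults are the study conditions every
other stage is validated against:

| quantity | default | unit | rationale |
|---|---|---|---|
| populations | 102 / 237 / 178 lines | — | the three mapping-population sizes |
| chromosomes | 10 × 130 cM, 27 markers each | — | maize-like genome, ~5 cM marker spacing after binning |
| physical scale | 1.5 Mb/cM | bp | genome-wide maize average |
| residual heterozygosity | 3% | — | ≈ (1/2)^5 for F6 material |
| environments | irrigated, non_irrigated | — | two irrigation regimens |
| env shift (non-irrigated) | x0 +2 d, L −4 cm | — | water stress delays inflection, shortens plants |
| replicates | 2 per environment (RCBD) | — | trial design |
| flight schedule | 35, 43, 57, 62, 65, 69, 100, 117 | DAS | the eight usable flight dates |
| flight noise | 0.03 | m | plot-level P95 measurement error |
| rep / range / row effect sd | 0.01 / 0.015 / 0.015 | m | modest block and spatial structure |
| parameter means (L, x0, b) | 1.10 m, 58 DAS, 7 | — | reported population-level values |
| polygenic sd (L, x0, b) | 0.06 m, 2.5 d, 0.8 | — | within-population spread with visible transgressive segregation |

**RIL genotypes** are drawn from a Markov chain along each chromosome
with switch probability R = 2r/(1+2r) between adjacent markers — the
fixation probability of a recombinant chromatid under repeated selfing —
where r inverts the Kosambi spacing.  This matches the F6+ expectation
directly instead of simulating generations of meiosis; an explicit
selfed-meiosis oracle in the test suite confirms the agreement (the
package's conditional genotype probabilities match brute-force meiosis
frequencies to < 0.01).  Crossover interference beyond Kosambi's
implicit level is not modeled.

**Trait architecture.**  QTL act additively on the Weibull parameters
(entry score −1/0/+1 taken at the marker nearest the QTL position), with
independent polygenic normal deviations per parameter.  An optional
direct height effect inside a DAS window injects transient
("opportunistic") loci for temporal-recovery testing.  Phenotypes are
`Y = f_entry(DAS) + Rep + Range + Row + eps` per plot and flight.

What the generator does *not* emulate: weather and soil processes, G×E
beyond a fixed environment shift of the parameter means, spatially
autocorrelated (AR1-style) field trends, heterotic/hybrid architectures,
or flight-to-flight differences in measurement quality.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every field artifact.

## Canopy metrics

Ground classification is a transparent two-step stand-in for production
ground-filtering algorithms: per-cell (default 1 m) minima seed a
least-squares plane, which is refit keeping points within `z_tolerance`
(default 0.10 m) above the surface; points below are always kept, so the
plane settles onto the lowest coherent surface even when some cells
contain only canopy.  The DEM is that plane; the CHM is z minus the DEM.
This suffices for the flat-to-gently-sloping fields the percentile
contract needs; terraced or strongly undulating terrain would need a
gridded/TIN DEM.  Plot extraction uses axis-aligned rectangles (0.76 m ×
3.81 m grid by default), boundary-inclusive on min edges.  Percentiles
interpolate linearly between order statistics; an empty plot yields NaN,
never zero.

## Mixed model

Per flight × environment × population, all terms of
`Y = mu + G + Rep + Range + Row + eps` are random.  Variance components
maximize the restricted likelihood, with σ²ε profiled out analytically
and a Nelder–Mead simplex over the log variance ratios (tolerances 1e-10
on the ratios; ratios pinned to zero below e⁻²⁹ and flagged as boundary
estimates rather than allowed negative).  On balanced one-way designs
the estimates match the closed-form ANOVA estimators to < 1e-6, and on
crossed designs they match statsmodels' MixedLM variance-component fit —
both kept as independent oracles in the tests.  When the residual
variance vanishes (noise-free data), the likelihood maximum sits on the
σ²ε → 0 boundary where the ratio decomposition is ill-conditioned; the
implementation then reports the no-shrinkage (OLS) limit: residual from
the saturated fixed-effects fit, each component the variance of its
estimated level effects.

BLUPs solve the mixed-model equations at the estimates; genotype BLUP
deviations sum to zero by construction.  Heritability is entry-mean
based, H² = σ²G/(σ²G + σ²ε/r).  Fisher's LSD letter groups use the
t-quantile threshold with means sorted descending and maximal
non-different runs lettered greedily (deterministic).

## Growth model

Fitting uses bounded least squares with initialization L₀ = max height,
x0₀ = first time exceeding L₀/2, b₀ = 5, and bounds L ∈ (0, 3·max],
x0 ∈ (0, 200], b ∈ (0.5, 30].  Constant series are flagged non-fits.
Family selection (Weibull vs logistic, Gompertz, probit) minimizes AICc
with ties broken by a fixed family order.

The reported AGR is the analytic derivative of the sigmoid, checked
against central finite differences at 1e-8 relative.  Its exact argmax
is x0·((b−1)/b)^(1/b) (≈ 2% below x0 at b = 7); summaries report both
this exact value and the AGR at x = x0, since field practice quotes the
inflection-point convention.

The goodness-of-fit screen is a one-sided likelihood-ratio statistic for
residual-variance inflation over a reference noise variance (default
(0.03 m)², the flight-noise scale): X² = df·(ρ − 1 − ln ρ) with
ρ = s²/v₀, dropped when X² strictly exceeds the chi-square critical
value at α = 0.05, df = 1.  The reference variance is a parameter; the
statistic is deliberately swappable.

Daily imputation evaluates the fitted curve on integer DAS 1–85 (85
values exactly), only for converged, screen-passing fits.

## Linkage map

QC order: missing-data filter (strict 10% cuts, lines screened on the
full matrix and then markers on surviving lines) → heterozygous calls
set missing → double-recombinant cleaning → redundant-marker binning →
Kosambi map on physical order.

Cleaning segments each line's homozygous calls into runs and absorbs any
run whose *region between crosspoints* (midpoints to the neighboring
runs) covers less than 0.1% of the chromosome's physical span, crediting
the calls to the absorbing allele.  The region rule only bites when
marker density is high relative to the threshold — exactly the regime
where an isolated opposite call is implausible — so sparse maps pass
through untouched.  At study-like density (markers every ~0.025 cM) and
1% random call errors, ≥ 95% of errors are corrected with a
false-breakpoint rate < 0.05 per line; a `min_run_markers` knob is
available for stricter smoothing.  An exhaustive minimal-flip
segmentation oracle bounds the greedy absorption in tests.

Binning groups markers with identical calls on shared non-missing lines
(greedy in physical order; representative = fewest missing, tie to the
smaller bp).  Adjacent-pair recombinant fractions are capped at 0.4999
(capped intervals flagged), inverted to meiotic r via r = R/(2−2R), and
accumulated as Kosambi distances.  Map r is treated under the selfed-RIL
expectation end-to-end for internal consistency with the generator, even
though genotyping-era material was F3 — a documented simplification.
With 200 RILs the estimated length of a 100 cM chromosome carries ~5 cM
sampling noise, so accuracy checks use means over replicate simulations.

## QTL scan

Conditional genotype probabilities on the 1 cM grid (plus marker
positions) condition on the nearest non-missing flanking calls through
RIL transition probabilities; lines missing both flanks get (0.5, 0.5).
The scan core regresses the phenotype on the expected additive score
P(BB) − P(AA) (Haley–Knott) rather than an EM normal mixture — for
two-class RIL populations at this marker density the LOD difference is
negligible and the regression form is exactly equal to single-marker
least squares at fully informative markers (asserted at 1e-8).
LOD = (n/2)·log10(RSS₀/RSS₁); positive additive effects always mean the
parent-B allele increases the trait.

ICIM background control: forward–backward stepwise regression on
mean-imputed marker scores with entry threshold PIN = 0.001 and removal
threshold POUT = 2·PIN (the removal constant and mean imputation are
package defaults; only PIN is prescribed).  The phenotype scanned in
each interval subtracts the fitted contributions of all selected markers
except the interval's flanks.  PVE is reported against the unadjusted
phenotypic variance.

Calling uses LOD > 2.0 and PVE ≥ 3% — deliberately liberal thresholds
for tracking temporal shifts, not marker-assisted-selection confidence.
Peak separation: a dip below the LOD threshold always separates calls;
within one above-threshold segment a second local maximum is distinct
only if ≥ 20 cM away *and* the profile drops ≥ 1 LOD below the smaller
maximum between them (otherwise it is a shoulder of the same peak).
Support intervals are 1-LOD drops; names follow `q{chrom}_{peak cM}`.

## Temporal QTL

Daily calls cluster by single-linkage on peak position within 10 cM on
the same chromosome (window exposed in config; clusters are monotone
non-increasing in the window).  Consensus position is the LOD-weighted
mean of member peaks; onset/offset are the first/last member day, which
bridges short detection gaps; trajectories are reported for all 85 days
including sub-threshold ones.  A sign switch is flagged only when the
additive effect has opposite signs on two successive days that are both
above the LOD threshold.  Candidate-gene distance is measured from the
center of the support interval to the nearest gene span (0 inside), with
< 1 Mbp and 1–5 Mbp bin counts.

Because daily phenotypes are deterministic functions of one fitted curve
per entry, any chance marker–phenotype correlation above the liberal
threshold persists across days and appears as its own temporal cluster;
recovery tests therefore assert the properties of the cluster at the
injected position.

## Problem sizes used in validation

Test and acceptance runs use desk-scale versions of the study design,
chosen to make the statistical assertions sharp rather than to replicate
field scale: fit-quality metrics use the full 3 × 2 population layout
(1,034 entries); REML recovery uses 200 trials of 200 entries × 2 reps;
detection power uses 200 scans at n = 237 (PVE 20%); temporal recovery
uses 100 runs of an 85-day scan at n = 237; cleaning uses 200 lines ×
4,001 markers; pipeline determinism uses a 50-entry, 2-chromosome
configuration run twice.  The full default configuration (three
populations, two environments, 85 days, 1 cM grid) runs end-to-end in
about five minutes on one CPU and is exercised by the same code paths.

## Known limitations

* Single-environment models only; no cross-environment or multi-trait
  REML, no AR1 spatial correlation.
* Additive RIL scans only (no dominance or epistasis), fixed LOD
  threshold rather than permutation-based genome-wide control.
* The ground model is planar; the GOF statistic tests variance inflation
  against a user-supplied noise scale, not lack-of-fit against
  replicate-level error.
* Flowering time is a proxy (x0 + offset + noise) used only by the
  correlation report, not a mechanistic model.
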