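# Methods

## The calling model

The package operationalizes a transcript-level test for two MET alterations
on a targeted digital counting panel.

**Evaluability.** RNA from FFPE tissue varies enormously in quality; the
geometric mean of the raw housekeeping counts (ACTB, PSMC4, MRPL19) is used
as an input/quality gauge and samples below 100 are not evaluable. The rule
is applied to *raw* counts, before any normalization, and is strict on the
fail side ("lower than 100"): a geomean of exactly 100 passes. A zero count
on any housekeeping probe annihilates the geomean (the sample fails), which
is the desired behaviour for a dead lane.

**Two-step normalization.** Counts are scaled per sample, first by
`pos_factor = mean_cohort(geomean of positive-control counts) / geomean_s`,
then — on the step-1-scaled values — by the analogous housekeeping factor.
The cohort reference is the arithmetic mean of per-sample geomeans over
QC-passing samples only, so failing lanes cannot perturb it. This is the
standard convention for this platform: positive-control scaling corrects
hybridization/lane efficiency, housekeeping scaling corrects RNA input.
The downstream statistics are insensitive to the reference constant; what
matters is that both steps are per-sample scalar multiplications, which
leaves every within-sample probe ratio — in particular the Δex14/wt ratio —
exactly unchanged. A QC-passing sample with a zero positive-control geomean
is reported as a corrupt lane rather than silently scaled.

**Scores.** `logMET = log2` of the normalized wild-type-MET value;
`LR = log2` of (normalized junction value / normalized wild-type value).
Base 2 is an arbitrary default: mean + k·SD classification is invariant to
the base (a positive linear rescaling of the log), which a property test
verifies; the base is recorded in the run manifest. A QC-passing sample
with a raw wild-type count of zero is treated as data corruption and
reported by id — MET-wt is abundantly expressed, and a silent pseudo-count
would distort the cohort SD.

**Detectability.** A sample with *no* raw junction counts is directly
skipping-negative and does not enter the log-ratio cohort (`raw_zero`
mode, the default; the number of samples that did enter is reported as
`n` on the cutoff so the choice is auditable). A `background` mode —
detected iff the raw junction count exceeds the sample's negative-control
mean + 2·SD — is available but off by default, since background
thresholding of endogenous probes is a stricter convention than the
literal zero-count rule.

**Cohort-adaptive cutoffs.** All thresholds are mean + k·SD with the
sample SD (n−1). Skipping positivity is *strictly above* mean + 2·SD of
the defined log-ratios (including any true positives — the cohort is taken
as analyzed, not pre-cleaned). Expression tiers use *inclusive* boundaries:
very-high ⟺ logMET ≥ mean + 2·SD, moderately elevated ⟺ mean + 1·SD ≤
logMET < mean + 2·SD. Strict-vs-inclusive is a fixed, documented convention
(config-exposed) rather than a silent ambiguity. Cutoffs are re-estimated
on every analyzed cohort; this self-referential design is faithful to the
assay's intended screening use but is unstable for tiny batches — on any
continuous score distribution roughly 2% of samples sit above their own
cohort's mean + 2·SD, so a handful of samples should never be screened
against self-estimated cutoffs. A frozen-cutoff mode accepting an external
`CutoffSet` is provided for prospective use.

## Distribution diagnostics

The two score distributions behave differently in real cohorts: log-MET is
unimodal with a high tail, the log-ratio is bimodal (background mode vs
skipping mode). The package quantifies this with

* a KS normality test with parameters estimated from the data (Lilliefors
  correction; table p-values are clipped to [0.001, 0.2] by the reference
  implementation in statsmodels), and
* a deterministic two-component equal-variance Gaussian mixture, fitted by
  EM (tolerance 1e-8, ≤200 iterations) from a Lloyd 2-means initialization
  seeded at the data extremes. A median-split initialization was tried
  first and abandoned: with a 3 % minority mode both initial centres land
  inside the majority mode and EM converges to a local optimum that splits
  it. The extremes-seeded 2-means start places one centre per mode whenever
  two exist and is equally deterministic.

The bimodal verdict requires all three of: log-likelihood gain over a
single Gaussian above a margin (default 5); component separation above 2
pooled SDs; and a genuine valley in the fitted mixture density (valley /
lower peak < 0.5). The third condition is what distinguishes a heavy upper
tail (log-MET: a 3.5 % component at +4 SD yields large likelihood gain and
separation, yet the fitted density stays monotone, valley ratio ≈ 1) from a
separated second mode (log-ratio: valley ratio ≈ 0). The equal-variance
posterior boundary `(μ₁+μ₂)/2 + σ²·ln(w₁/w₂)/(μ₂−μ₁)` is reported as the
misclassification boundary.

Group comparisons of log-MET across driver strata use two-sided
Mann–Whitney U tests against the driver-negative reference, unadjusted by
default (matching the assay-validation literature's convention), with
statsmodels multiple-testing correction available by config; groups under
3 samples are skipped with a warning.

## Concordance statistics

Agreement between two binary assays is summarized from the 2×2 table with
samples unknown on either side excluded pairwise (which is why each
comparison has its own N). Percent agreement carries a Wilson score
interval — chosen because it reproduces the intervals printed in the
assay-validation literature exactly at 1 dp (28/29 → 82.8–99.4;
101/112 → 83.3–94.4) and behaves correctly at the boundaries (upper bound
exactly 1 when all pairs agree); Clopper–Pearson is available by config.
Cohen's κ = (p_o − p_e)/(1 − p_e) with the usual marginal-product p_e, and
the qualitative bands slight/fair/moderate/substantial/almost-perfect at
0.20/0.40/0.60/0.80. Sensitivity a/(a+c) and specificity d/(b+d) treat the
reference assay as truth; the orientation is recorded and can be swapped.
κ variance estimation and weighted/multi-rater κ are out of scope.

## The synthetic cohort generator

No public count-level dataset exists for this assay class, so the package
ships a generator whose defaults emulate a 474-sample FFPE NSCLC screening
cohort: 52 QC-failing lanes and, among the 422 evaluable samples, 13
skipping-positive, 15 very-high and 36 moderately-elevated samples.

Per sample: a lane scalar `exp(N(0, 0.3))`; a latent MET level z — N(0,1)
truncated at +2.3 SD for the bulk, N(1.5, 0.25) for the moderately elevated
stratum, N(4.0, 0.25) for the very-high stratum (shifts in bulk-SD units);
total MET mean `2000·2^(σ·z)` with σ set in closed form so the cohort log-SD
is ≈1. Skipping-positive samples (drawn from the bulk stratum, matching the
observed moderate-but-not-high expression and mutual exclusivity with
over-expression) conserve total MET output and reallocate a fraction
(default 0.5) to the junction isoform. Skipping-negative samples see a
junction background of `4 + 0.003·(MET mean)` — a nonspecific-binding floor
plus cross-hybridization that tracks the abundant wild-type transcript;
because it tracks the target, the negative log-ratio mode is tight
(SD ≈ 0.6 log2 around ≈ −7.6) and the realized log-ratio distribution is
cleanly bimodal, as real cohorts are. QC-failing samples have housekeeping
and endogenous means depleted 33-fold (degraded RNA); positive-control
spike-ins are unaffected by RNA quality. Every count is negative-binomial
via a gamma–Poisson mixture with size r = 100, i.e. variance μ(1 + μ/100),
about 10 % extra CV at high counts — typical technical overdispersion for
digital counting; r → ∞ recovers Poisson. All randomness flows from one
seed through a single generator with a fixed draw order (statuses, lane
factors, z, counts probe-block by probe-block), so identical configs are
bit-identical.

Two generator choices deserve emphasis:

* **Bulk truncation.** The adaptive mean + 2·SD cutoff lands ≈2.2 bulk-SDs
  above the bulk mean under this composition, so an unbounded Gaussian bulk
  would place ~1 sample per cohort above any such cutoff *by construction*,
  making "true tier" ill-defined for those samples. Truncating the bulk at
  +2.3 SD keeps the labels identifiable while preserving the unimodal,
  high-tailed shape. This was fixed by analysis at design time, not tuned
  against test outcomes.
* **The moderately-elevated stratum is not exactly recoverable.** Its mean
  (+1.5 bulk-SDs) sits essentially on the mean + 1·SD cutoff, so about half
  of its members classify as normal while bulk samples above +1·SD classify
  as moderate; the *called* moderate count therefore fluctuates around the
  true 36 (observed ≈35–49 across seeds). This mirrors the real situation —
  the moderate tier is a soft band, not a separated population — and no
  exactness is claimed or tested for it. Skipping and very-high recovery,
  by contrast, are exact across seeds under the defaults.

The spike-in simulator mixes cell models (wild-type; a MET-amplified line
with 90 % exon-14-skipped transcripts; a MET-amplified wild-type line) as
convex combinations of probe means — synthetic stand-ins for cultured-cell
profiles, not measured data. It supports monotone sensitivity curves
(mean log-ratio vs spiked fraction); wet-lab limits of detection (section
areas, cell percentages) are physical properties outside what count-level
simulation can reproduce.

**What passing tests on synthetic cohorts do not show:** the generator has
no FFPE degradation chemistry, no stromal/immune MET expression, no
batch/cartridge structure (normalization is pooled across the cohort; a
per-run variant would be a config away), and its group separations are by
construction recoverable. Synthetic recovery validates the *procedure* —
QC, normalization, cutoff estimation, calling, bookkeeping — not the
clinical performance of the assay.

## Problem sizes and determinism

Default simulations are 474 samples × 15 probes; a full pipeline run takes
well under a second, the whole test suite a few seconds, and the
reproduction script about a second. The pipeline is a pure function of
(inputs, config): rerunning a manifest reproduces outputs byte-identically,
and all cutoffs actually used are logged and embedded in the manifest.
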