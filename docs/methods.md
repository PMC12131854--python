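# Methods

This note documents the statistical models behind `aquamark`, the
assumptions of the synthetic cohort generator, and the numerical and
design choices made where the methodology was genuinely open.

## Study design and cohorts

The pipeline models a three-group ocular-fluid study: nonproliferative
diabetic retinopathy (NPDR, the control stage), proliferative disease
(PDR), and neovascular glaucoma (NVG). Two contrasts carry the biology:
PDR vs NPDR and NVG vs PDR. Discovery uses two pooled profiling
platforms (LFQ and TMT); validation uses per-patient targeted MRM with
technical duplicates. The a-priori per-group size follows

    n = (z_alpha + z_beta)^2 * 2 / d^2

with z_alpha = 1.96 (two-sided α = 0.05), z_beta = 1.28 (90 % power);
at the profiling-derived standardized effect d = 0.759 this gives 37
per group (73 total), which is also the default cohort layout of the
generator (37/38/9 — the NVG group is capped by disease rarity).
`ceil` is applied after rounding to 9 decimals so exact-integer designs
are not inflated by floating-point noise.

## Synthetic cohort generator

The generator produces every input the downstream stages consume, plus
ground truth for recovery scoring. What it emulates, and the defaults:

- **Clinical table.** Group sizes 37/38/9; ages truncated-normal on
  [30, 90] years with per-group means/SDs (66.1 ± 8.3, 54.9 ± 8.9,
  53.3 ± 12.1); sex and hypertension prevalences follow the validation
  cohort; macular edema and panretinal photocoagulation (PRP)
  prevalences rise with stage (PRP: 0.10/0.70/0.90) since PRP is the
  standard treatment for proliferative disease; cataract grades skew
  higher in NPDR (patients enrolled at cataract surgery). Covariates
  are drawn independently within group.
- **Profiling matrices.** Log2 intensity = protein baseline
  (N(20, 2)) + cumulative group effect for true markers + platform
  location shift (+ a per-protein platform offset, SD 0.3) + Gaussian
  noise (SD 0.3) scaled by the platform factor. LFQ is one pooled
  column per group; TMT has two replicate channels per group (the
  6-plex two-channels-per-group labeling layout) and no missing values.
  LFQ missingness is left-censoring-like: detection probability is
  logistic in the true log2 abundance (midpoint 17, slope 1), because
  intensity-dependent identification is the dominant missingness
  mechanism on that platform.
- **MRM peak areas.** Log2 area = peptide baseline (N(17, 1)) +
  fixed per-transition offset (SD 1) + group effect + per-sample
  biological deviation (SD 0.5 log2) + per-sample loading factor
  (normal on log2, SD 0.25 — i.e. log-normal on the raw scale, so
  spike-in normalization is its exact inverse) + duplicate noise.
  The duplicate noise SD is cv_target/ln 2 with cv_target = 0.10;
  the within-duplicate CV of the real instrument is not published, so
  0.10 is a free parameter chosen as a typical triple-quadrupole
  duplicate CV, not an estimate of the study. The four
  β-galactosidase spike-ins sit at a constant log2 level (19 ≈ 5·10⁵
  counts) plus the loading factor and 30 % of the analyte duplicate
  noise (a concentrated exogenous standard is more reproducible than
  low-level analytes). "Poor" samples can be designated, in which a
  configurable fraction of target transitions falls below the
  detection floor.

What the generator does **not** emulate: chromatography (retention
time, peak shape, interference), fractionation, protein inference,
correlated missingness between related proteins, and any real
biological covariance structure between markers. Passing recovery
tests therefore demonstrates that the statistical machinery is
correct under the stated generative model — not that the pipeline's
thresholds are optimal for real instrument data.

## Transition design

Digestion is strict tryptic with zero missed cleavages; cleavage after
K/R is suppressed before proline by default (the common trypsin
convention; configurable). Eligibility: length 6–30, no Cys/Met (to
avoid variable alkylation/oxidation states), unique to one protein of
the supplied FASTA (uniqueness is database-relative, not
proteome-wide), and ≥ 2 surviving peptides per protein. Monoisotopic
m/z uses the standard residue table (proton 1.007276 Da, water
18.010565 Da): precursor (Σresidues + H₂O + z·proton)/z, b-ion
(Σprefix + z·proton)/z, y-ion (Σsuffix + H₂O + z·proton)/z.

Product candidates are the singly charged y/b ions of the 2+ precursor;
only products with m/z strictly above the precursor m/z are kept — a
co-isolated 1+ contaminant cannot produce fragments above its own
precursor m/z, so this region is clean. Exactly three transitions are
selected per peptide. Because empirical fragment-intensity evidence
(spectral libraries) is deliberately out of scope, ranking is
deterministic: fragment index descending (longer fragments carry more
sequence specificity), y before b at equal index. Peptides with fewer
than three qualifying products are dropped.

## Differential expression and integration

LFQ calls use fold change only (|log2FC| ≥ 1): the pooled design has
no replication, so no p value is defined. When one group has missing
values, its observed intensities are compared against the mean of the
fully observed group; proteins entirely missing in one group are
"group-specific", with log2FC capped at ±10 so downstream ordering
stays defined. TMT calls require p < 0.05 (pooled-variance Student t
on the two channels per group — the balanced design matches the
equal-variance assumption; Welch is a config switch) and
|log2FC| ≥ 0.58. Candidates are the intersection of the per-platform
unions over the two contrasts (configurable to union), ordered by
descending max |log2FC|.

Batch adjustment implements the standard parametric empirical-Bayes
location/scale model: per-protein standardization after removing the
grand mean and the protected covariate fit (disease group, so biology
is not absorbed into batch terms), method-of-moments priors (normal on
the batch location γ, inverse-gamma on the batch scale δ), iterative
conditional-expectation shrinkage (tolerance 1e-6, max 500
iterations), and back-transformation. Proteins not observed in every
batch are excluded (the model needs complete rows); zero-variance
proteins are dropped with a log message. The pooled residual variance
uses n − rank(design) degrees of freedom, which makes the
**unshrunken** (direct) adjustment exactly idempotent. The shrunken
adjustment is *not* idempotent — shrinkage deliberately leaves a
residual noise component in the batch means, and a second pass shrinks
it again; the test suite asserts the second pass is a contraction
rather than a no-op.

## MRM QC cascade

Fixed order: normalize → detect → sample filter → CV filter →
quantify; every stage only removes rows, so re-filtering filtered data
is a no-op.

- **Spike-in normalization:** per (sample, replicate) factor =
  geometric mean of the spike-in transition areas ÷ cohort median of
  those geometric means. Geometric (not arithmetic) because areas are
  log-normal and one hot transition should not dominate. Within-sample
  area ratios are unchanged by construction.
- **Detection:** area strictly above 10³ counts, assessed on the raw
  (pre-normalization) areas by default since the floor is an
  instrument-scale constant (configurable to post-normalization).
- **Sample filter:** samples detecting fewer than 50 % of the target
  transitions (spike-ins excluded from numerator and denominator) are
  removed; exactly 50 % is retained.
- **CV filter:** per transition and sample, CV = SD/mean (n−1
  denominator) over the two replicates; the transition's summary CV is
  the **median over samples** where it is detected (the aggregation
  level is a design choice; per-sample CVs are retained for audit).
  Transitions at or above 20 % are removed cohort-wide; transitions
  detected in fewer than 3 samples are removed as insufficiently
  observed.
- **Roll-up:** a peptide is quantified in a sample when ≥ 3 of its
  surviving transitions are detected in both replicates; the quantity
  is the replicate mean of the summed normalized transition areas
  (the sum stays proportional to abundance under the fixed 3-transition
  design). The "≥ 3" reading reconciles a three-transitions-per-peptide
  design with a more-than-three identification rule; a strict ">"
  toggle is provided.

## Validation statistics

Wilcoxon rank-sum is exact (dynamic-program enumeration of the
rank-sum null) when the combined sample size is ≤ 12 and tie-free,
otherwise the normal approximation with tie and continuity
corrections. AUC uses the Mann–Whitney identity
(#case>control + ½·ties)/(n₁n₂), auto-oriented to ≥ 0.5 with a flip
flag. Multiplicity is Benjamini–Hochberg by default (Bonferroni via
config) — the adjustment method for the original analysis is unnamed,
and BH is the standard choice for biomarker panels. Note BH is
monotone (adjusted ≥ raw) but **not** idempotent in general; only
monotonicity is asserted. Fold change is the ratio of group means
reported as log2 (geometric-mean variant via config). Tiers:
candidate = AUC > 0.7 (strict) with profiling-concordant direction;
strong additionally AUC > 0.9; significance (adjusted p < 0.05) is an
independent flag. ROC/Wilcoxon operate at peptide level; a protein
roll-up takes the best peptide and is flagged as such.

## Clinical statistics

Frequency comparisons use Pearson chi-square **without** continuity
correction, and sparse tables use exact tests (Fisher 2×2;
Freeman–Halton for 2×K by full enumeration of fixed-margin tables,
summing multivariate-hypergeometric probabilities ≤ the observed
table's) — this pairing reproduces the published patient-table p
values (0.584 hypertension, 0.826 sex, 0.395 combined ophthalmic
disease, 1.0 for the cohort comparison). The profile-vs-validation age
p (0.700) is not reproducible from summary statistics by either pooled
or Welch t tests and is not used as an anchor. Odds ratios use ad/bc
with the Haldane–Anscombe +0.5 correction on zero cells and Woolf
log-scale 95 % intervals, reported as log2. Covariate regressions are
OLS of log2 peptide quantity on the covariate with disease-group
indicators and age included as adjusters ("normalization" by group and
age is implemented as adjustment covariates; z-scoring is a config
switch); collinear designs are flagged and the estimate withheld; p
values are BH-adjusted across peptides. Stratified re-checks recompute
the Wilcoxon contrasts within strata (e.g. the median-age split at 60,
or cataract grades) and report whether direction and significance
persist; strata under 3 patients per arm are "not evaluable".

## Stage-wise enrichment

Each stage contributes a single (pooled) expression profile. The
single-sample ES is the integrated difference between the weighted hit
ECDF (weights |expression|^α, α = 0.25 — the established single-sample
default; 0 and 1 exposed) and the uniform miss ECDF along the
descending-rank list. Because the stage profiles have no replicates, a
**gene-permutation** null is used: for each distinct set size,
size-matched random sets are scored and shared across sets of that
size. NES = ES / mean |null ES| (sign preserved); the empirical p is
the null exceedance fraction of the max-over-stages |NES|, floored at
1/(B+1) and BH-adjusted into an FDR. The stage-wise statistic is the
NES difference — each stage's NES minus the cross-stage mean — which
sums to zero over stages by construction. With the default 1000
permutations and ≲ 20 sets, a planted one-stage shift of 2 SD on a
20-gene set clears FDR < 0.05; smaller permutation counts raise the p
floor and can make significance unreachable.

## Problem sizes and determinism

Simulation-based tests use sizes chosen for tight Monte-Carlo error at
desk scale: 20 000 replicates for the power computation, 200 simulated
cohorts for the MRM recovery suite, 150–400 proteins and 50 samples
per batch for adjustment recovery. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers (the
generator derives independent streams from the design seed), so every
table, matrix, and permutation null is bit-reproducible.

## Known limitations

- LFQ profiling is pooled (one profile per group), so LFQ calls carry
  no error rate; they are fold-change heuristics, as in the original
  design.
- The NVG arm (n = 9) makes NVG-contrast AUCs and p values coarse;
  exact Wilcoxon p values at n = 9 vs 38 cannot be smaller than
  permutation granularity allows.
- The Freeman–Halton implementation enumerates tables and is limited
  to small margins (it refuses rather than approximates).
- ssGSEA FDR under a gene-permutation null measures departure from
  random gene-set membership, not between-sample variability.
- The transition ranking is a deterministic stand-in for
  intensity-based ranking; on real data, library evidence should
  replace it.
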