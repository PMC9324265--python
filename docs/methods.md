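# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes live in a samples × variants matrix of effect-allele dosages
(0, 1, 2; NaN for a missing call). Dosage always counts the variant's
declared *effect* allele; switching to the opposite allele is an explicit
involution (`orientation.dosage_flip`, g → 2−g with alleles swapped), never
an I/O side effect. VCF input maps ALT → effect allele and rejects
multi-allelic records outright: the intended use is small, strictly
biallelic SNP panels, and silently splitting records would corrupt panel
bookkeeping. Coordinates are 1-based (GRCh37 in the packaged panel),
matching VCF's native convention.

## Quality control

Per-variant call rate is the fraction of non-missing calls. Hardy–Weinberg
equilibrium is tested with the 1-df χ² goodness-of-fit statistic comparing
observed genotype counts with (np̂², 2np̂q̂, nq̂²); a monomorphic variant
fits its degenerate expectation exactly and returns (χ²=0, p=1). The test
runs in **controls only** by default — genuine disease association distorts
case genotype proportions, so pooling would reject associated variants.
Defaults `call_rate_min = 0.95` and `hwe_p_min = 10⁻³` are ordinary values
for candidate-panel QC and are configurable; the emulated study reports
only an average call rate (98%), which the generator's 2% missingness
reproduces in expectation. The χ² test (not the exact test) is used because
the screened panels are small and frequencies are far from the boundary;
an exact-test variant would be a reasonable extension.

## Per-variant association

Each variant is tested by maximum-likelihood logistic regression of status
on dosage under the log-additive model, optionally adjusted for age, sex
(male indicator) and ethnicity (indicators against the most frequent
control category). Fitting is Newton–Raphson (statsmodels) with at most 50
iterations and tolerance 10⁻⁸; separation or non-convergence is surfaced
through a flag rather than silently returned. CIs and p-values are Wald
(z = 1.96 fixed for 95%), matching the OR-with-CI presentation standard in
candidate-gene tables; likelihood-ratio intervals are out of scope.
Complete-case deletion is applied per model, and per-group effect-allele
frequencies are computed on exactly the samples used in each fit.
Monomorphic variants are reported (OR 1, p 1, flagged) rather than dropped.
The closed-form allelic OR — 2×2 allele-count cross-product with Woolf CI —
is provided separately; under HWE it agrees with the unadjusted logistic
estimate to within sampling noise, and the test suite enforces agreement
within 2% at n ≥ 1000.

## Risk orientation

Score construction requires all effects pointing toward risk. A variant
with fitted OR < 1 is flipped: alleles swapped, OR inverted, **CI inverted
with it** ((lo, hi) → (1/hi, 1/lo)), and frequencies complemented. The
per-variant weight is ln(oriented OR) ≥ 0. An OR of exactly 1 is left
unflipped with weight 0 (tie-break convention). Published tables produced
by inverting ORs without inverting CIs can show CIs that fail to bracket
the OR; this implementation never emits such rows. Whether weights should
be OR or ln(OR) is a genuine ambiguity in the emulated study's description;
ln(OR) is the standard additive-scale choice and is the default, with
OR-scale weights available (`weight_scale="or"`) for sensitivity analysis.

## LD pruning

LD is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (the composite-LD estimator; no phase needed),
computed on cases and controls pooled by default. Pruning is greedy:
variants are scanned in ascending association-p order (ties by chromosome,
then position) and kept iff r² ≤ threshold against every kept variant;
exclusion is strict (r² must *exceed* 0.2), each dropped variant records
its excluding partner, and the kept set is maximal for the priority. The
keep-the-smaller-p rule is a convention — the emulated study states only
that 7 of 28 SNPs were excluded at r² > 0.2 — and is logged as such.

## Scoring and score-level inference

PGSᵢ = Σⱼ wⱼ gᵢⱼ on risk-oriented dosages. Missing genotypes are imputed
with the variant's mean risk-allele dosage (per-sample imputation counts
recorded); a strict mode drops incomplete samples instead. Scores are
standardised against the pooled mean and SD (cases + controls): the
score-level effect is then an **OR per 1 SD of PGS**, the scale-free unit
that makes weighted and unweighted models comparable. The score-level
logistic regression is run both unadjusted and with the same covariates as
the per-variant models. Two invariances pin the conventions down: allele
relabelling shifts raw scores by a constant and leaves standardised scores,
OR per SD and AUC unchanged; a weighted model with all weights equal is a
rescaling of the unweighted model.

## ROC analysis

AUC is the Mann–Whitney estimator (ties ½), identical to the trapezoidal
area under the empirical ROC curve; the test suite checks both identities
to 10⁻¹². The CI uses the DeLong structural-components variance
(var(V₁₀)/n + var(V₀₁)/m from placement values), truncated to [0, 1]; with
perfect separation the variance degenerates and the interval collapses to
a point, flagged. The operating point maximises Youden's J = sens + spec −
1, ties broken toward higher sensitivity then lower cutoff, with the rule
"score ≥ cutoff ⇒ predicted case".

## Synthetic study generator

Defaults encode the emulated study's printed structure: 464 cases / 1042
controls; 21 index SNPs with the published per-group effect-allele
frequencies; sex (60.8% / 49.8% male), age (means 56.0 / 53.6 years) and
ethnicity (Bashkir/Tatar/Russian) composition per group; 2% missing calls
(MCAR); and 7 proxy variants attached to the first 7 panel SNPs at
haplotype copy probability c = 0.775, giving dosage r² ≈ c² ≈ 0.6 and
reproducing the 28 → 21 pruning arithmetic. Which SNPs carry proxies is an
arbitrary fixture choice. The published age is given with its standard
error; the generator needs a population SD, set to 10 years (age is only a
covariate, so this choice is inert for the genetic analysis).

Two modes: *conditional* draws dosages per group as Binomial(2, group EAF)
— HWE within group, independence across index SNPs; *logistic* draws
controls at the population frequency (rare-disease approximation) and
cases from P(g|case) ∝ ORᵍ·Binom(2, p), the exact retrospective
log-additive distribution. Covariates are generated independently of
genotypes, so adjusted and unadjusted effects coincide in expectation.

What the generator does **not** emulate: real LD structure beyond the
planted pairs, population stratification between the ethnicity labels,
genotyping error beyond MCAR missingness, and covariate–genotype
confounding. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data features.

Where the published per-variant table is internally inconsistent (ORs
inverted without their CIs; frequency columns rounded to 2 decimals;
covariate-adjusted ORs alongside raw frequencies), the generator treats
the **per-group frequency columns as ground truth** and lets effect
direction and magnitude follow from them — frequencies fully determine the
unadjusted association, and the orientation stage re-derives risk
direction. A consequence worth knowing: the printed frequency columns
imply a somewhat stronger aggregate score signal than the study's reported
score-level AUC/OR, so simulations parameterised by those columns
over-reproduce the headline discrimination (the acceptance script reports
whatever the simulation actually yields).

## In-sample evaluation and winner's curse

Weights are derived and evaluated in the same sample, mirroring a study
with no external training GWAS. This inflates apparent discrimination:
in-sample risk orientation alone biases even an unweighted score's AUC
above 0.5 under the global null. The null-calibration test therefore uses
a data-independent unit-weight model, which is exactly calibrated (OR per
SD centred on 1, AUC on 0.5).

## Problem sizes and determinism

Replicate-based checks use the study's own dimensions (1506 samples,
21–28 variants); replicate summaries use 50 seeded replicates, and the
null HWE calibration uses 2000 variants. Every random draw flows from a
single `numpy.random.Generator` seeded from the configuration; derived
per-replicate seeds stay below 2³¹. Identical (config, seed) pairs give
byte-identical datasets and pipeline output bundles.
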