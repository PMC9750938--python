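# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of `burdenmr`. It states no empirical result
that the test suite or `scripts/acceptance.py` do not themselves compute.

## Genotype and variant QC (`genoqc`)

Multi-allelic records are split into biallelic ones; each ref/alt pair is
reduced to its minimal, leftmost representation by the standard
trim-and-shift recurrence (truncate shared trailing bases, extending left
through the reference when an allele would empty; then truncate shared
leading bases). The test suite checks this against a brute-force
enumerator of all equivalent representations on small haplotypes.

Genotype filters: SNV calls are set missing when DP < 7 **and** GQ < 20;
indels when DP < 10 **and** GQ < 20. The conjunction is the literal
reading of the rule this pipeline follows; because the disjunctive reading
is also common practice, the gate is configurable (`gate: and|or`,
default `and`). Heterozygous SNVs are tested for a 50% alt-read
contribution with an exact binomial test at p = 0.5 on the AD sum; calls
with p ≤ 1e-3 are set missing. The two-sided p-value uses the
minimum-likelihood convention (sum of all outcome probabilities no larger
than the observed one). For the symmetric p = 0.5 binomial this equals
`2·P(X ≤ min(k, n−k))`, capped at 1 and exactly 1 when 2k = n, which is
what the vectorized implementation computes; two-sided binomial
conventions differ between tools, so this is pinned by exact
rational-arithmetic tests for all n ≤ 200. Het indels are untested (the
rule is stated for SNVs only). After genotype filtering, per-variant
missingness is recomputed and variants with missingness strictly > 50%
are dropped; AC/AN/MAF are recomputed post-filter (whether the original
pipeline recomputed frequency pre- or post-filter is unstated; post is
the default here and the pre-filter counts remain available).

## Annotation and masks (`annotate`)

One transcript per variant: protein-coding > MANE-select > canonical,
with remaining ties broken by lowest transcript id — a convention chosen
to make the reduction order-independent; the upstream tool's tie-break is
not documented. One consequence per variant: the most severe term under a
fixed severity ranking shipped as package data
(`data/consequence_severity.tsv`); unknown terms raise rather than rank.
Stop-gained, frameshift and splice acceptor/donor variants form the PTV
class. Masks cross five functional classes (HC PTV; missense REVEL ≥ 0.5;
missense REVEL ≥ 0.7; synonymous; damaging = missense CADD ≥ 25 or HC
PTV) with two frequency strata (MAF < 0.001; AC = 1). Score thresholds
are inclusive. Variants lacking a score the mask needs are non-members
and are tallied in a diagnostics counter rather than erroring. Any
non-missing alt genotype makes a sample a carrier, which also covers the
hemizygous-male convention on chrX (dosage handling there is otherwise
unspecified upstream).

## Burden association (`burden`)

The three-step generalised-linear-model scheme:

1. **Null model** — OLS of the trait on covariates only, with binary
   traits treated as continuous at this stage.
2. **Preliminary scan** — simple OLS of the null residuals on the 0/1
   carrier indicator, vectorized across genes in closed form; p from the
   t distribution with n−2 df. This p is the reported one when the gate
   is not passed.
3. **Full model** — for genes with preliminary p < 1e-4 (configurable), a
   GLM of the raw trait on carrier + covariates with family binomial or
   gaussian. Binary fits report OR = exp(β) with exp(β ± 1.96·SE) limits.
   Perfect separation and non-convergence are caught and returned as
   `status="flagged"` records, never crashes; zero-carrier genes are
   skipped records; a contrast-free carrier vector raises.

Significance requires p < 6.9e-7 (the exome-wide threshold used as the
default; its derivation in terms of effective tests is not stated
anywhere authoritative, so it is configurable) **and** ≥ 30 carriers.
Multiplicity across masks is handled by this single global threshold, not
FDR. Sample-exclusion lists supported by the screen make "drop these
carriers and re-test" analyses expressible. Mixed-model machinery
(GRM-based association) is deliberately out of scope; the GLM path is the
validation route and relatedness correction is not attempted.

Diagnostics: λ = median(χ²₁ quantile of 1−p)/0.4549; the heterogeneity of
two effect estimates is Z = (β₁−β₂)/√(SE₁²+SE₂²) with a two-sided normal
p. Protein-domain partition testing collapses a gene's qualifying
variants inside and outside a residue interval separately and compares
the two full fits with this Z.

**Calibration caveat (measured, see the acceptance suite):** with a
binary trait at prevalence 0.077 and carrier counts in the tens to low
hundreds, the preliminary-stage t-test is mildly anti-conservative in its
median — λ ≈ 1.015 on average at n = 20,000 with per-gene carrier
frequencies between 0.002 and 0.02 — because the carrier-case count is a
small discrete binomial. Rejection rates at α = 0.05 and KS uniformity
are unaffected; the inflation disappears for Gaussian traits and for
larger carrier counts.

## Mendelian randomization (`mr`)

Harmonization aligns outcome to exposure alleles (sign-flip and EAF
complement on label swap, strand flips resolved by complementation),
drops irreconcilable allele sets with a reason, drops palindromic SNPs
with exposure EAF in [0.42, 0.58] (a conventional ambiguity window; the
width is configurable), and finally orients every record so β_x ≥ 0.
Pre-resolved LD proxies can be supplied as a SNP-id map; LD panels and
proxy search are out of scope.

Estimators: IVW with multiplicative random effects (fixed-effect SE
inflated by √(Q/df) only when Q/df > 1 — no underdispersion credit; a
single instrument reduces exactly to its Wald ratio); MR-Egger by WLS
with weights 1/se_y², t-inference on n−2 df and the same overdispersion
floor; weighted median with inverse-variance ratio weights and a
penalised variant multiplying weights by min(1, 20·q_j) where q_j is the
χ²₁ tail p of the instrument's deviation from the IVW estimate (penalty
constant 20 follows the originating method; configurable); bootstrap SEs
for the medians are parametric with 1,000 draws and a fixed seed. Radial
filtering iteratively removes instruments whose Q contribution has
χ²₁ tail p below α/n per round (α = 0.05 default) until stable; it is
idempotent. Steiger filtering compares r² = 2·EAF·(1−EAF)·β² between
outcome and exposure on standardized traits, keeps ties, and passes
through instruments missing EAF/N with a warning tally; the raw r²
comparison (not the directionality-test p) is used — with many near-null
outcome effects it also trims noisy valid instruments and truncates
|β_y|, deflating a subsequent IVW, so the analysis drivers report it as a
sensitivity count rather than a pre-filter. MVMR is WLS of β_y on the
exposure-effect columns without intercept, weights 1/se_y²; rank
deficiency errors with the collinear column names. Additive estimates can
be rescaled per SD of the exposure (default factor 5.5 units/SD).

## Colocalization (`coloc`)

Wakefield log-ABFs with prior effect SD W = 0.15 (quantitative) or 0.2
(case-control), configurable. Hypothesis sums accumulate in log space
(log-sum-exp); H3's "distinct causal SNPs" term is computed as
log(e^{S1+S2} − e^{S12}) with a guard that returns −∞ when rounding makes
the difference non-positive. Priors default to p1 = p2 = 1e-4,
p12 = 1e-5. Posteriors are normalized over H0–H4; per-SNP shared-causal
posteriors are emitted. Multi-signal conditioning and fine-mapping are
out of scope — with several independent causal signals at one locus the
single-causal model can favour H3 even when one signal is shared.

## The synthetic world (`simcohort`)

Defaults state the world at reduced scale: 20,000 samples (the cohort
emulated has 418,436), 500 genes, trait prevalence 7.7%, covariates age,
age², sex, ten standard-normal principal-component surrogates and a
3-level sequencing-batch factor (50k/200k/450k-style proportions).
Rare-variant MAFs follow a power-law spectrum (exponent 1, i.e. 1/f)
truncated at 0.1%, with 50% of sites forced to be singletons. Read
evidence: negative-binomial depth (mean 30, size 10), clipped-normal GQ
(mean 75, SD 20), binomial(DP, 0.5) alt reads for true hets with a 2%
unbalanced-het error mode (alt fraction 0.12) and a 0.5% low-quality
error mode (DP ~ Poisson(4), GQ < 25) so the QC filters have true
positives; the real platform's DP/GQ error process is not public, so this
noise model is a stand-in.

The liability model is logistic (not probit) because carrier effects are
specified and reported as odds ratios; the intercept is solved by Brent's
method so the marginal prevalence matches the target. Causal genes are
specified as (gene, mask class, log-odds); each receives 20 injected
qualifying variants of its class at equal MAFs summing to a target
cumulative carrier frequency, default 0.02. That default is a power
statement, fixed before any screen was run: ~400 carriers at n = 20,000
are needed for an OR of 2.5 to clear p < 6.9e-7, mirroring how the
emulated study's detected genes (carrier counts 31–394 at n ≈ 418k)
scale down.

MR instruments: |β_x| ~ |N(0.02, 0.01)| + 0.01 with random sign before
orientation, SEs 0.003/0.01 (exposure n = 428,525; outcome n = 893,130),
β_y = θ·β_x + pleiotropy + noise with θ = 0.1/SD by default and 784
instruments. Reverse-causal instruments are built outcome-first
(γ ~ ±N(0.15, 0.02) on the outcome, induced exposure effect 0.3·γ), so
their outcome r² strictly dominates. Coloc tracks place one causal SNP
(z = 8 by default) among independent null SNPs; no LD is simulated.

What a green test does **not** establish: robustness to linkage
disequilibrium, relatedness, population stratification, haplotype
structure, imputation error, winner's-curse in instrument selection, or
case-control ascertainment — none of these are simulated.

## Reproducibility and I/O

Every generator is a pure function of its config and seed; identical
seeds give identical tables (asserted byte-level through the pipeline).
Coordinates are 1-based inclusive throughout (VCF convention). TSVs are
UTF-8, tab-delimited, `.` for missing. The VCF subset written is v4.2
with INFO AC/AN and FORMAT GT:DP:GQ:AD, read back through cyvcf2; carrier
matrices round-trip through a long-form TSV (genes with zero carriers are
not representable there and are re-omitted on read). The pipeline
manifest records versions, seed, thresholds and per-stage variant counts,
and the counts are conserved (in = kept + dropped) by construction and by
test. CLI exit codes: 0 success, 2 configuration, 3 data, 4 numerical.
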