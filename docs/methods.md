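# Methods

This note records the models, conventions and design choices behind
`snpdist`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Genotype model

A call is an **unordered** pair of alleles.  Array and exome-chip genotypes
are unphased, so order-insensitive equality is the only defensible
comparison; VCF phase separators (`|` vs `/`) are deliberately ignored on
read.  Half-calls (`0/.`) are treated as entirely missing, because the
distance's per-site indicator δ is defined on whole genotypes.  Internally
every call is a sorted pair of small integers indexing the variant's allele
table, with (−1, −1) for missing; this single representation feeds every
downstream kernel.

PLINK 1 `.bed` decoding follows the published 2-bit code (00 hom-A1,
01 missing, 10 het, 11 hom-A2), in both variant-major and sample-major
layouts; `.fam` phenotypes 2/1 map to case/control and −9/0 (or anything
else) to `unknown`, which the pipeline excludes with a logged count.

## Distances

* **Hamming** — the count of both-called positions where the unordered
  pairs differ.  δ is strictly 0/1: sharing one of two alleles is still a
  difference (allele-level sharing is the IBS metric's job).
* **Normalised Hamming** — count / compared positions; identical to H/n on
  complete data.
* **IBS allele-sharing distance** — 1 − (IBS2 + ½·IBS1)/compared, the
  conventional stratification metric.

**Missing-data rule.** Pairwise-complete deletion: a site missing in either
individual contributes to neither numerator nor denominator.  This is
unbiased per pair, reduces exactly to the complete-data definitions, and
each `DistanceMatrix` carries the per-pair compared-site counts so the
information loss is always visible.

**Vectorisation.** The matrix builder one-hot encodes per-site genotype
categories (and, for IBS, per-allele dosage classes) and accumulates
match/compared counts for all pairs with BLAS products.  For IBS the
identity IBS = 2 − ½ Σₐ |dᵢ(a) − dⱼ(a)| (dosage d of allele a) turns the
per-site classification into six matrix products.  Tests verify exact
agreement with the naive per-pair double loop, which is kept as the
reference semantics.

## QC and MAF classification

Defaults: call rate ≥ 0.95; biallelic sites only; exact Hardy–Weinberg
P ≥ 10⁻⁶ computed in controls only (computing HWE in cases would discard
genuine association signal; the all-samples option exists).  The exact HWE
test conditions on the observed allele counts and enumerates all
heterozygote counts of matching parity; tables with up to 20,000 alleles use
exact integer arithmetic (so probability ties are resolved exactly), larger
ones a log-gamma formulation.  The χ² approximation is avoided entirely
because the variant sets of interest are rare, where it is invalid.

MAF is computed on non-missing alleles with cases and controls pooled, and
class boundaries follow the standard definitions: rare < 0.5% ≤
low-frequency < 5% ≤ common.  The three classes partition the QC-passing
variants — an invariant surfaced end-to-end in the pipeline report.
Monomorphic variants are retained (MAF 0 → rare) because they contribute
zero to every distance; dropping them is available as an option.

## Classical MDS

Torgerson scaling: B = −½ J D⁽²⁾ J, eigendecomposition, coordinates
= eigenvectors × √λ.  Conventions chosen for strict reproducibility:

* eigenvalues sorted descending, index as tie-break;
* each coordinate column sign-fixed so its largest-magnitude entry is
  positive (first index wins ties);
* eigenvalues below 10⁻¹² of the spectrum's largest magnitude count as zero;
* negative eigenvalues (genotype Hamming matrices need not be Euclidean) are
  excluded from coordinates but retained in the reported spectrum, with
  `negative_eigenvalue_mass` = Σ|λ₋| / Σ|λ| logged.  No additive-constant
  correction is applied.

If fewer positive eigenvalues than requested dimensions exist, the
achievable dimension is returned with a warning rather than padding.

## Hotelling's T²

Classical two-sample form with the pooled (n₁+n₂−2)-denominator covariance
and the exact F reference distribution; the exact P is always computed, and
only the human-readable report applies the conventional "< 2.2e−16" floor.
If the pooled covariance's condition number exceeds 10¹², the test refuses
and advises reducing the tested dimension instead of silently
pseudo-inverting.  The default tested dimension is 2 (the MDS plane).  With
four classes tested per run the report adds a Bonferroni-adjusted column
next to — never instead of — the raw P-values.

## Synthetic cohorts

The generator emulates an exome-chip case–control study: a panel of
2,000 common + 2,000 low-frequency + 5,000 rare variants, 200 cases and
200 controls, per-call missingness 0.005 (the sub-1% regime typical of
modern arrays), genotypes drawn in Hardy–Weinberg proportions within each
group, and no linkage disequilibrium.

The disease signal is **symmetric allele-frequency divergence** between the
case and control pools, following the Balding–Nichols model: an affected
variant has ancestral frequency q inside its class band, and each group
realises a frequency from Beta(mean q, variance fst·q(1−q)).  Two modelling
choices deserve emphasis:

* **Both groups are displaced, not just cases.**  A one-sided frequency
  increase in cases inflates case heterozygosity, making within-case
  distances exceed case–control distances; classical scaling can only
  represent that geometry on *negative* eigenvalues, which are discarded
  from coordinates, so the contrast would be invisible by construction.
  Symmetric displacement keeps the two groups exchangeable and puts the
  contrast in the positive spectrum — the geometry an actually diverged
  pair of population samples produces.
* **Class bands constrain the pooled frequency.**  The classifier stratifies
  variants by cohort-pooled MAF, so a variant "designed rare" is defined as
  one whose pooled population frequency lies in the rare band: divergent
  frequency pairs are redrawn until (p_case + p_ctrl)/2 is in band.
  Without this, the strongest-divergence variants systematically migrate
  into the low-frequency class and the planted signal leaks out of the
  stratum it was planted in.

Defaults fst = 0.02 and affected_fraction = 1.0 for the rare class (0
elsewhere) were fixed once by a design power analysis: at the default cohort
size this places the planted rare-class divergence comfortably in the
detectable regime (rare-class P typically ≤ 10⁻¹²) while common and
low-frequency classes stay null, giving the frequency-localised signature
the pipeline is meant to expose.  The rare band's floor of 5×10⁻⁴ keeps
expected minor-allele counts ≥ 1 so empirical classification is stable.

**What the generator does not model** — and what passing tests therefore do
not establish about real data: linkage disequilibrium, relatedness,
admixture or other population substructure beyond the planted two-pool
divergence, genotyping error and batch effects, differential missingness,
and any phenotype model richer than a pure frequency shift (no odds-ratio
liability model, no covariates).  A real cohort in which cases carry a net
one-directional excess of rare alleles would, per the geometry above, *not*
separate in the leading MDS plane; detecting that pattern needs the negative
spectrum or burden-style statistics, which are out of scope here.

## Pipeline conventions

Samples are analysed on the genotype ∩ phenotype intersection; mismatches
and unknown phenotypes are logged, never silently dropped.  A requested
class with zero variants is skipped with a warning while other classes
proceed; a class whose T² cannot be computed (e.g. fewer than two members in
a group) reports the error in place of the statistic rather than failing the
run.  Re-running with identical inputs and configuration produces
byte-identical result tables.  The stratification screen
(`run_stratification_check`) forces the IBS metric and flags samples lying
more than 6 scaled MADs (1.4826×MAD, a robust σ estimate) from the
coordinate-wise median in either of the first two MDS axes; flagging is
reporting-only unless exclusion is explicitly requested.

## Problem sizes used in validation

The planted-divergence acceptance check runs 50 replicate cohorts at the
default 400-sample × 9,000-variant scale (≈1.5 s per replicate); the
type-I-error calibration uses 2,000 bivariate-normal replicates at
n₁ = n₂ = 100; the HWE oracle comparison enumerates every genotype table
with ≤ 200 alleles (≈180,000 tables).  These sizes were chosen so the whole
suite, including acceptance checks, completes in a few minutes on one core.
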