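# Methods

This note documents the statistical models implemented in famburden, the
assumptions they make, the defaults and why, and the numerical choices
that affect results.

## The two-stage design

The package targets the standard two-stage design for a presumably
monogenic, autosomal-dominant trait that is also common in the general
population (essential tremor: prevalence ≈ 2–4% in adults, up to 14%
over 65). Stage one prioritizes variants in a multiplex family by
frequency, consequence and segregation; stage two asks whether rare
deleterious variants in the prioritized gene are enriched in a large
case-control cohort.

## Family prioritization cascade

Filters are applied in a fixed order (five frequency filters, one
consequence filter, the two segregation clauses), each recording its
survivor count so runs can be diffed step by step.

**MAF threshold 0.02, strict.** Because the trait is common, a causal
allele need not be vanishingly rare; 0.02 balances sensitivity against
the background of common variation. The comparison is strict
(`MAF < 0.02` retains; exactly 0.02 removes). A variant *absent* from a
population database is retained (`missing_maf_policy="keep"`): absence
from a catalogue of observed variation is evidence of rarity, and
dropping unobserved variants would discard exactly the alleles the
design is looking for.

**Consequence classes.** The default retained set is {missense,
stop_gained, stop_lost, frameshift, splice_site}; synonymous variants are
excluded and later reused as the cohort negative control.

**Segregation with phenocopy tolerance.** Under a dominant model a
carrier has dosage ≥ 1. A variant survives iff at least
`min_affected_carriers` (default 9 of 10) affected members carry it and
at most `max_control_carriers` (default 0) unaffected members do. The
default is deliberately not 10/10: for a common trait one affected
member may be a phenocopy — in the motivating family, the affected
non-carrier had a thyroidectomy, a recognised non-genetic cause of
tremor. Setting `min_affected_carriers = n_affected` and
`max_control_carriers = 0` recovers strict co-segregation. A missing
genotype is neutral: it contributes to neither the affected-carrier nor
the control-carrier count, so an ungenotyped member neither supports nor
kills a candidate.

**Consensus deleteriousness.** Nine predictor calls (DANN, GERP, FATHMM,
LRT, MetaLR, MetaSVM, MutationAssessor, MutationTaster, PROVEAN) are
combined by strict majority of pathogenic over benign among non-missing
calls. A tie or an all-missing profile yields `unknown`, which is *not*
treated as deleterious downstream — with no stated tie rule in the
field's practice, the conservative call is the defensible one. The
verdict is used by the cohort analysis (deleterious-variant selection),
not as a cascade step in the family analysis.

## Kinship verification

Pedigree structure is checked against genotypes with the between-family
KING-robust estimator

    phi = (N_het,het − 2·N_opp) / (N_het(i) + N_het(j))

over jointly non-missing sites (`N_opp` counts opposite homozygotes).
This form needs no allele-frequency input, is robust to population
structure, and is what `vcftools --relatedness2` computes. Monomorphic
and hom-concordant sites contribute nothing and are skipped implicitly;
pairs with no shared heterozygous site raise an explicit
undefined-kinship error rather than returning 0/0. Degrees use the
standard powers-of-two bands: phi > 2^-3/2 duplicate/MZ, then first
(2^-5/2, 2^-3/2], second (2^-7/2, 2^-5/2], third (2^-9/2, 2^-7/2], else
unrelated. A declared parent-offspring pair that classifies outside
{first, duplicate/MZ} is reported as a pedigree contradiction and makes
the family pipeline exit nonzero.

## Cohort association

**Carrier table and Fisher test.** A sample is a carrier if it has
dosage ≥ 1 at ≥ 1 variant of the selected set; samples missing at *all*
set variants are excluded from the counts and listed in the report. The
two-sided Fisher exact p sums, in log space, the probabilities of all
tables with the observed margins whose hypergeometric probability does
not exceed the observed one (relative tie tolerance 1e-7 for
floating-point equality of probabilities). Degenerate margins return
p = 1 with a warning.

**Deleterious set.** Variants passing all five MAF filters at 0.02, with
a protein-altering consequence and a deleterious consensus verdict
(`deleterious_only=False` drops the verdict requirement).

**Null model.** Logistic regression of case status on an intercept, age
(standardized before fitting to aid IRLS convergence) and sex (0/1),
fitted by IRLS to relative tolerance 1e-8, at most 100 iterations.
Samples with missing covariates are dropped with a logged count.
Complete separation and constant phenotypes raise explicit errors.

**SKAT.** With weighted dosages `Z = G·diag(w)`,
`w_j = Beta(1, 25) density at the sample MAF of variant j` (the
canonical linear weighted kernel defaults, upweighting rarer variants),
the score vector is `S = Z'(y − μ̂)` and `Q_SKAT = S'S`. Under the null,
Q is distributed as a mixture of 1-df chi-squares with weights equal to
the eigenvalues of `Z'P₀Z`, where `P₀ = V − VX(X'VX)⁻¹X'V` is the null
covariance projection (V = diag(μ̂(1−μ̂))).

**SKAT-O.** `Q_ρ = (1−ρ)·Q_SKAT + ρ·Q_burden` with
`Q_burden = (1'S)²`, over the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Per-ρ p-values use the
eigenvalues of `R_ρ^{1/2} (Z'P₀Z) R_ρ^{1/2}` with
`R_ρ = (1−ρ)I + ρ·11'` (the ρ = 1 kernel is rank one and handled
exactly — it reduces to the 1-df weighted burden test). The grid is
combined by the minimum-p statistic: the null distribution of
min_ρ p_ρ is evaluated by decomposing each Q_ρ into a shared 1-df
burden component and an orthogonal mixture remainder, and integrating
the joint survival over the burden component. Inside that decomposition
ρ is capped at 0.999 (the construction divides by 1−ρ); the omnibus
p-value is additionally floored at the per-ρ minimum and capped at the
Bonferroni bound `min_ρ p_ρ · |grid|`. A single-variant set reduces to
the 1-df score test for every ρ.

**Chi-square mixture tails.** P(Q > q) is computed by numerical
inversion of the characteristic function (Imhof's formula). The
oscillatory integral is evaluated on a shared grid as sine/cosine
transforms of two fixed eigenvalue functions (≈ 12 points per
oscillation period, envelope truncated at 1e-10), which lets one grid
serve every quantile needed by the omnibus integration; cases where the
frequency–range product would need more than ~60k grid points switch to
QUADPACK's oscillatory-weight (QAWO) rule. Tails below 1e-5 use the
Lugannani–Rice saddlepoint approximation (accurate far into the tail,
where quadrature loses relative precision); Liu's kurtosis-matched
moment approximation is the last-resort fallback and also supplies the
quantiles needed by the omnibus step. The grid path agrees with
adaptive quadrature to ~1e-9 and with Monte-Carlo tail frequencies at
4×10⁵ draws; the omnibus integral uses 196-node Gauss–Legendre after
the substitution x = s², which removes the 1-df density singularity.

**Case subsampling.** Drawing `resample_size` (default 630) cases
without replacement from the case pool makes the carrier count per
replicate a hypergeometric variable; the summary reports min, max, mean
and the full histogram over replicates (default 1000). Sampling *with*
replacement (binomial counts) is available as a config flag. The
without-replacement default reproduces the expected extreme-order
statistics for a 159/820 pool subsampled to 630 (minima near 108,
maxima near 137 over 1000 replicates).

**Synonymous control.** The same MAF filtering and carrier Fisher test
restricted to synonymous variants. Because synonymous alleles should be
phenotype-neutral, this provides a locally matched negative control; a
cohort with no planted synonymous differential yields approximately
uniform p-values.

**Seeds.** Every random component draws its seed from a single root via
`numpy.random.SeedSequence.spawn`, so one integer reproduces the full
analysis; derived seeds stay below 2³¹.

## Synthetic data generators

**Family.** The pedigree template is the motivating 16-member family
(ids, tiers, ages and the candidate genotype column follow its published
clinical table); the *connecting structure* — two generation-I founders
and four married-in spouses — is a plausible synthetic reconstruction,
since the full pedigree is not public. Background sites (default 5000)
draw frequencies from a 70/30 mixture of common (U(0.05, 0.5)) and rare
(U(0.0005, 0.02)) spectra, founders are Hardy–Weinberg draws, and
children receive one uniformly chosen allele per parent (gene-dropping),
so Mendelian consistency holds by construction and kinship expectations
(0.25/0.125/0.0625) emerge from transmission rather than being planted.

By default (`phenotype_mode="observed"`) the causal variant's carrier
states and the affection statuses reproduce the family template exactly
— nine affected carriers, one affected non-carrier phenocopy, six
unaffected non-carriers — because those *are* the study conditions the
cascade is specified against. `phenotype_mode="stochastic"` instead
gene-drops the causal variant from founder I-1 and assigns affection
with penetrance 0.9 (high but incomplete, as in dominant tremor
pedigrees) and phenocopy rate 0.05 (the trait is common); under that
mode the 9-of-10 pattern holds only with the probability the penetrance
model implies (≈ 0.9⁹ ≈ 0.39 for all nine carriers affected), which is
what a power study of the segregation filter should see.

**Cohort.** Carrier status for the deleterious class is simulated at
the person level — exact-count mode plants exactly round(n·p) carriers
per group (defaults 159/820 cases, 55/630 controls) — and then
materialized as a single heterozygous genotype at one deleterious site
chosen proportionally to site frequency. This calibration choice
matches the analysis' acceptance surface (the carrier table) exactly.
Synonymous sites get person-level carrier status independent of the
deleterious signal with equal group rates by default (a null control;
a planted case rate is available for power checks), and benign sites
are Hardy–Weinberg draws independent of phenotype. Ages are
N(65, 10) clipped to [30, 95], sex is Bernoulli(0.5); the family
generator reuses the template ages (39–100).

**What the generators do not model.** No linkage disequilibrium between
sites (no in-scope analysis uses LD, but SKAT power studies on this data
understate the effect of correlated variants); no genotype missingness
in the cohort; no sequencing/coverage error; single-gene cohorts only.
Passing tests therefore validate the statistical machinery and its
calibration, not robustness to real-data artifacts.

## Numerical and edge-case policy

- Coordinates are 1-based throughout (VCF convention); no interval
  arithmetic exists in the pipeline.
- Multi-allelic records are split per ALT; GT alleles not matching the
  split ALT count as reference for that variant, conserving the
  per-sample total alternate count at a site. Indels are reduced to
  minimal representation by trimming the shared suffix then prefix; full
  left-alignment against a reference sequence is out of scope (no FASTA
  input), a documented limitation for real indel data.
- Missing genotypes are never imputed in I/O. In the association tests,
  missing dosages are treated as reference with a logged count (the
  simulated cohorts contain none).
- Kernel eigenvalues below mean(positive)/1e5 are discarded as numerical
  zeros; an all-monomorphic variant set raises a degenerate-statistic
  error rather than returning a meaningless p.
- Test-suite and acceptance problem sizes (2000 null replicates at
  n = 500 for calibration, 100,000 permutations on 300-sample fixtures
  for the SKAT-O oracle, 10,000 sites for kinship recovery) were chosen
  to make Monte-Carlo error small relative to the tolerances being
  asserted.

## Known limitations

- Only the dominant carrier model is implemented (no recessive or
  compound-heterozygote segregation).
- The family cascade does not compute region blacklisting; upstream
  annotation is expected to have handled low-complexity regions.
- The Fisher summed-tail rule is one of several two-sided conventions;
  alternatives (doubled one-tail) can give less extreme p-values on the
  same table.
- No population-stratification correction (single-ancestry cohorts
  assumed) and no multi-gene scanning or cross-gene multiple-testing
  correction.
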