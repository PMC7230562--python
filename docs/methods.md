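# Methods

This note documents the models, procedures and numerical choices behind
`melvar`, and what the synthetic data used in its test suite does and does
not establish about behaviour on real cohorts.

## Study design and data model

The package targets a small familial-melanoma discovery design: a handful of
exome-sequenced multiple-primary-melanoma (MPM) cases that include one
sibling pair, additional MPM cases screened only for candidate variants,
index patients of familial-melanoma families, and healthy population
controls. Variants are normalized to bi-allelic records keyed by
`(chrom, pos, ref, alt)`; multi-allelic VCF records are split per alternate
allele with per-sample allele counts recomputed against each alternate.

Three conventions are load-bearing:

* **Undefined genotypes are a distinct state.** A `./.` call is not
  homozygous reference. The quality gate requires every exome case to have a
  defined, quality-passing genotype; group denominators in the screening
  table count only samples typed for that variant, which is how mixed
  control denominators (100/200/300) arise.
* **Unknown population frequencies are never zero.** Rare, previously
  unobserved variants typically have no database frequency; coercing absence
  to 0 would silently exempt common variants with missing annotation from
  the frequency filter, and coercing to "common" would discard novel
  variants. The filter only acts on frequencies actually present.
* **X-chromosome genotypes are taken as recorded** (diploid counts, no
  sex-aware hemizygote model). Carrier counting is unaffected; the
  dominant-consistency rule treats a `1/1` record in a control as
  homozygous regardless of chromosome.

## The selection cascade

Steps run in a fixed order: quality gate → cohort sharing → annotation
selection → common-variant exclusion → synonymous exclusion →
poly-variant-gene exclusion → final recurrence + pathogenicity selection.
Each step is monotone (output ⊆ input) and idempotent; the first two
exclusions commute with each other, but the gene-level exclusion does not
commute with anything that changes per-gene variant counts — its count is
taken among the survivors of the preceding steps, which is the interpretation
that places the rule inside the funnel rather than genome-wide. Outputs are
always sorted by variant key; nothing in the cascade is randomized.

Choices where the underlying procedure is stated loosely:

* **Frequency threshold inclusivity.** The default excludes variants with
  allele frequency ≥ 1% (inclusive), with `af_inclusive=False` available.
  The inclusive reading matches the screening table's own treatment of a
  variant at exactly 1% as a non-rare polymorphism.
* **Two recurrence thresholds.** Sharing is tested early among exome cases
  (sibling-pair rule, or ≥ 2 non-sibling carriers); final recurrence is
  tested late across all patients (exome + screened) at "more than two",
  i.e. ≥ 3 by default. Both are configurable because they are genuinely
  different rules applied at different stages.
* **"Pathogenic according to at least one database."** A damaging verdict
  from any of the seven predictors (SIFT, PolyPhen-2, MetaSVM, MetaLR,
  PROVEAN, MutationTaster, FATHMM) or a pathogenic/likely-pathogenic ClinVar
  record each count as one vote; the stringent annotation arm consults only
  the first four predictors plus ClinVar presence and the Ensembl
  high-quality flag. Tool vocabularies are collapsed to
  damaging/tolerated/unknown by a fixed mapping table in `melvar.vcfio`
  because no common cutoff convention exists across tools.
* **Synonymous variants.** The default drops them; `keep_synonymous=True`
  restores designs in which a recurrent synonymous variant (e.g. one with a
  suspected splice effect) is deliberately retained. The flag exists because
  retention of a synonymous candidate alongside a synonymous-exclusion rule
  is a real pattern in published screens and the package should be able to
  reproduce either reading.

## Screening

Carrier frequency is `100·k/n` rounded half-up to one decimal — the
convention that reproduces every published-style cell we encode in tests,
including `(2/300) → 0.7%` and `(22/26) → 84.6%`. Rarity is classified from
the control carrier frequency with boundaries belonging to the middle class:
rare < 1% ≤ polymorphism ≤ 5% < common. The boundary assignment is forced by
the data convention the tests pin (variants at exactly 1.0% and 5.0% counted
as polymorphisms). The dominant-consistency rule excludes any candidate with
an `allele_count = 2` genotype in at least one healthy control; with no
control genotypes at all the rule is vacuous and logs a warning rather than
guessing.

## Aggregation tests

All three tests are score tests under an intercept-only binomial null: with
case fraction `μ̂ = ȳ`, residuals `r = y − μ̂` and variance `v = μ̂(1−μ̂)`,
per-variant scores are `S = Gᵀr`. No covariates enter the null model — the
design is a pure case/control comparison. Weights default to the Beta(1, 25)
density at the folded minor-allele fraction estimated from the genotype
matrix itself (`w ≈ 25(1−maf)²⁴`), strongly up-weighting the rarest
variants; monomorphic columns are a caller error, not silently dropped.

* **Burden**: `U = wᵀS`, `Var(U) = v·bᵀ(I−J/n)b` with `b = Gw`;
  `p = P(χ²₁ > U²/Var(U))`, two-sided by construction. For a single 0/1
  variant with unit weight this is algebraically identical to the Pearson
  chi-square on the 2×2 carrier-by-status table (a test pins this).
* **SKAT**: `Q = Σ (w_j S_j)²`; the null is `Σ λ_k χ²₁` with `λ` the
  eigenvalues of `v·WGᵀ(I−J/n)GW`. Eigenvalues below `1e−10·λ_max` are
  truncated as numerically zero.
* **SKAT-O**: `Q_ρ = (1−ρ)Q_skat + ρQ_burden` over the grid
  `ρ ∈ {0, 0.1², …, 0.5², 0.5, 1}`; each `Q_ρ`'s p-value uses the
  eigenvalues of `R_ρ^{1/2} M R_ρ^{1/2}` with
  `R_ρ = (1−ρ)I + ρ11ᵀ`. The minimum p over the grid is calibrated by
  decomposing the weighted genotypes onto the common burden direction,
  integrating the conditional non-exceedance probability against the
  1-df chi-square density of that direction (variance-rescaled by
  `√((VarQ − VarRemain)/VarQ)` to absorb the mixed term). A single-point
  grid returns the corresponding component p unchanged, which yields the
  endpoint identities (ρ=1 → burden, ρ=0 → SKAT) exactly. The final p is
  clamped to `[T, k·T]` (best component, Bonferroni) as a numerical guard.

### Quadratic-form tails

`P(Σλ_kχ²₁ > q)` is computed by characteristic-function inversion of the
Imhof integral. Two evaluation paths share one accuracy target (1e−6
absolute): a vectorized fixed-grid Simpson rule whose truncation point grows
until the envelope tail estimate is negligible and whose step is refined
until a half-resolution comparison meets the target (this path also
evaluates whole grids of statistics against one eigenvalue set in a single
pass, which is what makes SKAT-O affordable in simulation loops); and an
adaptive QUADPACK path that splits the integrand into Fourier sine/cosine
parts with frequency `q/2` for the slowly decaying small-`m` case. A single
eigenvalue is a scaled `χ²₁` and is evaluated in closed form. When the
inversion fails to converge, or the probability lies at or below the
inversion accuracy (deep tail), the Liu four-moment match to a noncentral
chi-square takes over; the method actually used is reported in results.

### Permutation oracle and small-sample behaviour

`permutation_pvalue` permutes case/control labels with a seeded generator and
returns `(1 + #{perm ≥ obs})/(1 + B)`; `permutation_reference` is a
vectorized version producing burden, SKAT and min-p-omnibus reference values
in one pass. The omnibus reference converts permuted `Q_ρ` into
within-permutation upper-tail ranks, takes the minimum across the grid and
compares against the observed minimum — an assumption-free analogue of the
SKAT-O combination.

No small-sample moment adjustment is applied to the asymptotic p-values; the
permutation scheme is the authoritative small-n answer. Empirically (and
pinned in tests): with balanced weights the asymptotic and permutation
p-values agree within Monte-Carlo error throughout the rejection region
(p ≲ 0.05), while in the body of the distribution, or when one extreme
Beta weight makes the statistic effectively univariate on a rare skewed
column, they can differ by a few hundredths at n ≈ 200. Decisions at
conventional significance levels are unaffected; exact mid-range p-values
on very small cohorts should be quoted from the permutation method.

### Reconstruction from carrier counts

`reconstruct_from_counts` rebuilds an individual-level genotype matrix from a
per-group carrier-count table under a stated policy: carriers are
heterozygous, carriers of different variants are disjoint individuals within
a group, and groups are padded to their largest denominator with untyped
sample-variant pairs marked missing (mean-imputed inside the tests;
`scale_to_min` rescales counts to the smallest denominator instead). For the
seven-variant aggregation set the case carriers sum exactly to the 26 MPM
patients, so the disjoint reconstruction is exact there: each case row
carries exactly one variant. Every assumption applied is returned in a log.
Overlapping-carrier layouts are not implemented; when disjoint placement is
infeasible the function refuses rather than inventing an overlap pattern.

## Synthetic cohorts

The generator's defaults mirror the target design: 8 exome cases with one
sibling pair, 18 screened cases, 37 indexes, 100 controls, 500 background
variants (30% rare with minor-allele fractions uniform on [0.001, 0.009] and
frequently absent from the frequency databases; 70% common with fractions
from Beta(0.5, 3) truncated to [0.01, 0.5] and truthful annotation), plus
eight planted candidates split between the two sharing patterns and a decoy
panel pinned to every cascade step. Predictor noise gives each tool an
independent 10% chance of a spurious damaging call on background variants,
which exercises the "at least one database" rule.

Background variants are constructed so they cannot satisfy the cascade:
common ones carry their true above-threshold frequency (removed by the
frequency exclusion), and rare ones are drawn with at most one exome-case
carrier (they fail both sharing criteria). This makes planted-variant
recovery exact by design — precision = recall = 1 across seeds — and that is
precisely what the closed-loop tests verify: that the cascade implements its
stated rules faithfully, not that it would achieve perfect precision on real
data, where rare background variants *can* be shared by relatives and
unrelated cases alike. Likewise the generator draws background genotypes
independently per variant (no linkage disequilibrium) and annotations
independently per tool, so the tests say nothing about correlated-annotation
or correlated-genotype failure modes.

The case/control simulators used for calibration draw genotypes
`Binomial(2, maf)`; the alternative model assigns disease by a logistic
model `logit P(y=1|g) = α + Σ log(OR_j) g_j` with `α` set from a 10%
baseline prevalence, accumulating cases and controls by retrospective
(ascertainment) sampling.

## Problem sizes used in the checks

The test suite and acceptance script choose sizes that a laptop reproduces
comfortably while keeping Monte-Carlo error well below the decision margins:
type-I error from 5,000 null cohorts (script: 2,000) of 26 cases / 100
controls at the allele frequencies implied by the published control carrier
counts, with the empirical rate required to fall in [0.035, 0.065] at
α = 0.05; power orderings from 1,000 (script: 500) replicates of 100/100 at
maf 0.05 with odds ratios 2.0 (same-sign) or 3.0/⅓ (mixed-sign); permutation
oracles at 10⁴–10⁵ permutations; planted-recovery over 20 seeds (script: 10).

## Known limitations

* Annotations are inputs; the package never recomputes predictor verdicts,
  splice effects or population frequencies.
* The funnel counts of any particular real cohort depend on its annotation
  dialect and cannot be asserted by the synthetic tests.
* The aggregation tests assume unrelated samples under the null; the sibling
  pair violates exchangeability slightly if both siblings enter the case
  block. The reconstruction-based analyses treat all 26 cases as
  exchangeable carriers, which matches the summary-table information
  available but not pedigree reality.
* SKAT-O's omnibus integration is an approximation tuned for the
  significant regime; far from significance it is conservative (the
  permutation omnibus is exact there, and is what the tests compare
  against in that regime).
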