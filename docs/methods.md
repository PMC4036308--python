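# Methods

`lactpath` implements a pathway-based association workflow for quantitative
traits in pedigreed livestock populations, with dairy-cattle milk
production traits as the motivating design. This note records the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
want written down.

## Gene windows and pathway SNP sets

Gene coordinates are 1-based and inclusive at both ends, and a gene's
window is `[max(1, start − w), stop + w]` with `w = 100,000 bp` by default
— wide enough, under the moderate-to-high LD of dairy cattle, for nearby
regulatory variation to be tagged by SNPs assigned to the gene. A
pathway's SNP set is the *union* of its member-gene windows: genes in a
pathway frequently overlap (STAT5A/STAT5B share most of their span), and a
SNP must contribute at most once to any set-level statistic. Per-gene SNP
counts reported for descriptive tables may double-count shared SNPs; every
test statistic uses the deduplicated union. Windows are truncated at
position 1 but not at an assumed chromosome end, since chromosome lengths
are not part of the inputs.

The package ships, as reference fixtures, transcriptions of three curated
lactation gene sets — mammary development (64 genes), prolactin signalling
(27) and involution (40) — whose exactly three common genes are STAT5A,
STAT5B and SOCS3. Parsing skips summary rows (blank coordinates or an
`N = …` symbol), so the fixtures can mirror the printed tables verbatim.

## Record preparation and weights

Phenotypes are trait deviations: a cow record is the mean deviation over
her `l` lactations (herd-year-season and permanent-environment corrections
are assumed already applied upstream); a bull record is the mean deviation
of his `n` daughters. Records are standardised to mean 0, SD 1 *within
breed* (sample SD), and heteroscedasticity across record types is carried
by residual weights

    bulls:  w = (1 − h²) / (1 + (4 − h²)/n)
    cows:   w = (1 − h²) / (1 + r²(l − 1)/l)

entering the mixed model as `Var(e_i) = σe²/w_i`. Both weights live in
`(0, 1 − h²]`: the bull weight rises with daughter count (a progeny mean
carries more information), the cow weight falls with lactation count
(repeat lactations share the permanent-environment effect, so they add
little). Defaults for the five milk traits are h² = 0.33 (milk, fat kg,
protein kg) and h² = 0.5 (fat %, protein %), repeatability r² = 0.56 for
all. For the high-heritability percentage traits, bull weighting can be
switched off per trait (`weight_bulls=False`), reproducing the practice of
fitting bulls unweighted when the weighted model will not converge. The
typeset source of these weight expressions is ambiguous about grouping;
the adopted readings above are the standard de-regressed-proof forms and
are asserted as this package's convention, not as the only possible one.
A trait declared with h² = 0 (a non-genetic null trait in simulation
studies) gets unit weights, since the formulas are information heuristics
for heritable records.

## The mixed model and REML

The single-SNP association model is

    y = Xβ + W b + Z u + e,  u ~ N(0, A σa²),  e ~ N(0, D σe²),  D = diag(1/w)

with fixed effects mean, breed and sex, `W` the 0/1/2 dosage of the
counted allele and `A` the pedigree numerator relationship matrix (tabular
method, exact for inbred pedigrees). The variance-partitioning model
replaces `Zu` by `Zg`, `g ~ N(0, G σg²)`, with `G` the VanRaden method-1
GRM (`G = ZZ′ / 2Σp(1−p)`, allele frequencies estimated from the supplied
genotypes unless base-population frequencies are given; monomorphic SNPs
dropped with a logged count).

All REML fits share one engine: whitening by `sqrt(w)` reduces the
residual covariance to the identity; one symmetric eigendecomposition of
the whitened kinship turns the restricted likelihood into a cheap 1-D
function of the variance ratio λ = σg²/σe², maximised by a 25-point grid
on log λ ∈ [−12, 12] followed by bounded scalar refinement (`xatol` 1e−7).
This yields the exact REML optimum for a single random effect — there is
no iteration schedule to tune and no EM fallback to need. The
eigendecomposition does not involve `X`, so per-SNP refits reuse it.
Because the solver never inverts the kinship, a PSD-singular `G` is
handled exactly; the classic 4000-random-SNP augmentation is nevertheless
retained as the study design being modelled (and is what
`run_partitioning` performs), since it is part of the procedure whose
behaviour the package reproduces.

Non-identifiable configurations (e.g. `A = I` with equal weights, where
only σa² + σe² is determined) produce a flat profile; the fitter detects a
likelihood range below 1e−6 across the grid, warns, and reports the total
variance rather than inventing an interior optimum.

**Association modes.** `exact` mode refits REML per SNP with the SNP as a
fixed covariate, mirroring per-SNP variance-component refitting in a
standard mixed-model package. `fast` mode (the default) is a vectorised
approximation of the same refit: the per-SNP restricted likelihood is
profiled on a log-λ grid centred on the null-model optimum (local spacing
0.75, plus coarse global anchors), and the per-SNP optimum and Wald
quantities are obtained by quadratic interpolation between grid points.
This was preferred over GLS frozen at the null components (EMMAX-style)
because freezing λ measurably distorts p-values when some SNPs have
non-trivial effects; the grid scan tracks the exact refit to within
|Δlog₁₀p| of a few hundredths at a few hundred animals and tighter as n
grows, while remaining a full-matrix scan. Two-sided p-values use the
standard normal reference for the Wald ratio (large-sample convention).
Monomorphic SNPs (zero dosage variance) and SNPs collinear with the fixed
effects (projected squared norm below 1e−10 of their scale) are flagged,
never silently dropped.

## Enrichment: PropSig and the permutation null

For a pathway with per-SNP p-values `p_1..p_m`, `PropSig = #{p ≤ α}/m`
with α = 0.05 by default; the boundary `p = α` counts as significant. The
experiment-wise null is built by drawing random gene sets of the same
*gene count* from the annotation universe (matching neither SNP count,
chromosome, nor spacing — `gene_pair_distances` quantifies the spacing
mismatch but no correction is applied), forming each set's windowed SNP
union and recomputing PropSig from the same association results. With
`n_perm` permutations the critical value is the `ceil(α·n_perm)`-th
largest null value — the 500th highest at 10,000 permutations — and a
pathway is significant only if its observed PropSig *strictly exceeds*
that value. The empirical p-value uses the add-one estimator
`(1 + #{null ≥ obs})/(n_perm + 1)`. Random draws whose SNP union is empty
are redrawn and counted (dropping them would bias the null toward zero).
Chromosome-exclusion re-analysis removes the excluded chromosome from the
universe, from every pathway set, and from the permutation draws in the
same invocation.

Alternative per-SNP thresholds (10⁻³, 10⁻⁵) are supported through `alpha`
but carry no packaged reference values.

## Variance partitioning

`run_partitioning` fits the single-GRM model for the pathway SNP set plus
`n_random = 4000` genome-wide augmentation SNPs, then for `n_replicates =
5` baseline sets of the same pre-augmentation size drawn uniformly from
within 100 kb of any gene, each reusing the *same* augmentation SNPs. The
reported quantity is `delta = 100·(prop_g(pathway) − mean prop_g(baseline))`
in percentage points, with `se` the SD across the replicate differences —
deliberately not divided by √n, the conservative reading of
replicate-derived uncertainty. `prop_g = σg²/(σg² + σe²)` excludes fixed
effects from the denominator (standard REML convention). Only the marginal
contribution of the pathway SNPs over the augmentation SNPs is assessed;
there is no two-GRM joint partition. Fixed effects are mean, breed and sex
in both the association and the variance models.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes,
not cattle genomes:

* **Genome.** 10 chromosomes × 30 Mb, 5,000 uniformly placed SNPs, 1,500
  genes with lognormal lengths (median 20 kb) placed by a two-scale gap
  mixture (30% short gaps of mean 30 kb) to create positional clustering.
  One 40-gene candidate pathway is drawn from the universe, i.e. 2.7% of
  genes — small enough that random control sets rarely touch it, which is
  the operative property of a genome-wide annotation (where a curated
  pathway is a fraction of a percent of all genes). A preset with the
  pathway at ~8% of the universe was rejected: it makes the permutation
  null itself enriched and misrepresents the design being emulated.
* **LD.** Founder haplotypes are mosaics over 250-kb blocks of a 16-deep
  per-breed ancestral haplotype pool; LD is strong within blocks and
  absent across them. This deliberately simple block model reproduces the
  clustered-SNP redundancy that motivates GRM augmentation. `ld_block_bp=0`
  gives fully unlinked SNPs for oracle scenarios.
* **Population.** Two breeds (65% / 35%) as separate founder pools with
  Fst-like frequency divergence (default 0.05); 200 founders, 3 discrete
  generations of within-breed random mating to 2,000 animals; meiosis with
  Poisson crossovers at 1 cM/Mb. Offspring dosages are genuinely
  transmitted, so Mendelian consistency and the pedigree–genomic
  relationship agreement are emergent.
* **Phenotypes.** Causal SNPs (default 50) get normal effects rescaled so
  the true breeding values have variance exactly h²; a configurable
  fraction of causal SNPs is placed inside the target pathway's windows.
  Cows get `value = u + pe + mean of l lactation residuals` with
  `Var(pe) = r² − h²`, `Var(resid) = 1 − r²`, `l ~ 1 + Poisson(1.2)`
  capped at 8. Bulls get the mean deviation of `n ~ 1 + Poisson(39)`
  daughters, each daughter built as `u_d = 0.5·u_sire + 0.5·u_dam +
  Mendelian sampling` plus one lactation's residual — so the bull-weight
  formula's variance assumptions are emergent rather than imposed, and a
  bull record regresses on its sire's breeding value with slope one half,
  as daughter averages do. Breed enters as a fixed shift that within-breed
  standardisation then removes, exactly as in the emulated workflow.

What the generator does **not** emulate: imputation error between chip
densities, selection and genetic trend across generations, coalescent-
accurate LD decay, herd-year-season structure (records arrive already
corrected), and X-linked or non-additive genetics. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to those real-data features.

## Problem sizes used by the test and acceptance runs

The statistical suites run at 1,000 animals × 5,000 SNPs (enrichment
calibration over 200 null datasets with 500 permutations each; power over
50 enriched replicates with 20 causal loci at SNP-h² 0.2), 500 animals ×
200 SNPs for scan-fidelity comparisons, 1,000 unrelated animals with
unlinked SNPs and 400 augmentation SNPs for partitioning scenarios, and
10,000 permutations for the threshold-rank check. These sizes were chosen
so a full run completes on a single CPU core in well under half an hour
while leaving the Monte-Carlo error small relative to the tolerances
asserted.

## Known limitations

* The A-matrix is dense tabular, intended for desk-scale pedigrees
  (≤ ~5,000 animals); no sparse Henderson inverse or single-step H matrix.
* One record per animal per trait enters the mixed model; repeated records
  are pre-averaged with the weight carrying the information content.
* The fast scan's λ grid is centred on the null-model optimum; a SNP whose
  optimal variance ratio lies far outside ±3 log units of it (plus the
  coarse anchors) would be evaluated at a slightly suboptimal λ. The exact
  mode is the arbiter in such cases.
* `prop_g` compares variance captured by *sets including* the shared
  augmentation SNPs; with few animals and many augmentation SNPs the
  baseline is noisy, which the replicate SD is meant to express.
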