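# lactpath

Pathway-based GWAS enrichment and SNP-set variance partitioning for milk
production traits in dairy cattle — and, more generally, for any
quantitative trait measured on a pedigreed, genotyped population with a
curated set of candidate gene pathways.

Conventional GWAS of milk traits must survive genome-wide multiple
testing, so variants of small effect in biologically obvious places —
mammary development, prolactin signalling, post-lactation involution —
stay invisible. `lactpath` implements the complementary strategy: restrict
attention to the SNPs inside (or within 100 kb of) the genes of a
candidate pathway, test each SNP with a weighted linear mixed model, and
ask two set-level questions:

1. **Enrichment.** Is the proportion of pathway SNPs significant at
   per-SNP level α (*PropSig*) larger than for random gene sets of the
   same size? The null distribution comes from `n_perm` random draws from
   the annotation universe; at 10,000 permutations the experiment-wise
   0.05 critical value is the 500th-largest null PropSig, and a pathway is
   declared significant only if it strictly exceeds it.
2. **Variance.** Does a genomic relationship matrix (GRM) built from the
   pathway SNPs (plus 4,000 random SNPs to keep it well conditioned)
   capture more phenotypic variance than an equal number of random
   near-gene SNPs? The answer is reported as `delta ± se` in percentage
   points over five baseline replicates.

The per-SNP model is `y = Xβ + Wb + Zu + e` with a pedigree polygenic
effect `u ~ N(0, A σa²)`; phenotypes are within-breed standardised trait
deviations, weighted by `(1−h²)/(1+(4−h²)/n)` for bulls with `n` daughters
and `(1−h²)/(1+r²(l−1)/l)` for cows with `l` lactations. Variance
components are estimated by exact spectral REML; the per-SNP scan has an
`exact` mode (REML refit per SNP) and a vectorised `fast` mode that tracks
it to within a few hundredths of a log₁₀ p-value unit. See
`docs/methods.md` for the full model description and design rationale.

Because no public dataset accompanies this design, the package includes a
first-class synthetic-data generator (`lactpath.simulate`) producing
pedigrees, LD-structured two-breed genotypes, clustered gene annotations
and bull/cow phenotype records, plus ground truth for every simulated
quantity. The three curated lactation gene tables (64 mammary-development,
27 prolactin-signalling, 40 involution genes) ship as packaged fixtures.

## Worked example

Simulate a 1,000-animal study in which all 20 causal variants for protein
percentage lie inside the windows of a 40-gene pathway, then run the full
analysis:

```sh
cat > config.yaml <<EOF
seed: 42
n_animals: 1000
n_founders: 150
n_snps: 5000
traits:
  - {name: protein_pct, h2: 0.5, r2: 0.56, weight_bulls: false}
n_causal: 20
enrichment_fraction: 1.0
target_pathway: pathway_1
EOF

lactpath simulate --config config.yaml --out ds
lactpath gwas     --dataset ds --trait protein_pct --out assoc.tsv
lactpath enrich   --dataset ds --assoc assoc.tsv --n-perm 10000 --seed 7 --out enrich.tsv
lactpath varcomp  --dataset ds --trait protein_pct --pathway pathway_1 \
                  --n-random 400 --n-replicates 5 --seed 7 --out vc.tsv
```

which prints (abridged):

```
wrote 7 files to ds (1000 animals, 5000 SNPs, 1500 genes)
5000 SNPs tested (4865 ok) -> assoc.tsv
  pathway       trait  n_snps  n_sig  propsig  null_mean  threshold  threshold_rank  significant  empirical_p
pathway_1 protein_pct     136     19 0.139706   0.067072   0.103896             500         True       0.0013
  pathway       trait  delta_pct   se_pct  pathway_prop_g  baseline_mean_prop_g
pathway_1 protein_pct  35.225557 4.774336        0.740706               0.38845
```

Reading the numbers: 19 of the pathway's 136 SNPs are significant at
p ≤ 0.05 (PropSig 0.140), versus a mean of 0.067 over 10,000 random
40-gene sets and an experiment-wise threshold of 0.104 (the 500th-largest
null value) — the pathway is enriched with permutation p ≈ 0.001. The
pathway GRM captures 74% of phenotypic variance against 39% for random
near-gene SNP sets of equal size: 35 ± 5 percentage points of additional
variance, as expected when every causal variant sits in the pathway.

The library API mirrors the CLI: `simulate_dataset`, `run_gwas`,
`run_enrichment`, `run_varcomp`, and the lower-level building blocks
(`build_a_matrix`, `build_grm`, `SpectralREML`, `build_null_distribution`,
`run_partitioning`, …) are all importable from `lactpath`.

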