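# raretag

Statistical pipeline for asking how well common SNPs tag rare alleles in a
genotyped cohort, in two stages:

1. **Binned correlation (stage 1).** The genome is tiled with fixed
   non-overlapping bins (default 1 Mb). In each bin, random subsets of
   `n_s` rare SNPs (default 5, repeated `round(n_r / n_s)` times when the bin
   holds more) define a per-individual rare-allele load — either the total
   count of rare alleles or its 0/1 collapse. The load is correlated with the
   bin's common SNPs via the maximum single-SNP squared Pearson correlation
   and the multiple regression R² (plus its predictor-count adjustment), for
   the whole cohort, per subpopulation, and per synonymous/nonsynonymous
   stratum. A permutation null (each common SNP independently shuffled across
   individuals within its bin) is compared against the observed distribution
   with Kolmogorov–Smirnov and Welch t tests.

2. **Nested tag sets (stage 2).** For each rare SNP, the common SNPs within a
   window (default 1 Mb centered) are greedily pruned into nested sets
   A ⊆ B under pairwise r² ceilings (defaults (0.80, 0.95) and (0.95, 0.99)).
   The gain of regressing the rare dosage on B over A is tested with the
   nested-model F statistic against both the analytic F tail and a
   block-permutation null that shuffles the rows of the B∖A predictors
   jointly (default 1000 replicates), preserving their internal LD.

A synthetic genotype module generates cohorts with the structure the analysis
assumes — founder-haplotype mosaics with distance-decaying LD,
Balding–Nichols subpopulation divergence, and rare variants planted either on
a common-haplotype background ("linked") or independently of all genotypes
("unlinked") — so the whole pipeline is testable without external data.

## CLI

```sh
# synthetic dataset (VCF + annotation/population/truth TSVs)
raretag simulate --config sim.json --out-dir data/ --seed 1

# stage 1 + its permutation null + KS/t comparison table
raretag stage1 --data-dir data/ --out-dir s1/ --seed 1

# stage 2 at one threshold pair
raretag stage2 --data-dir data/ --out-dir s2/ \
    --threshold-a 0.80 --threshold-b 0.95 --n-perm 1000 --seed 1

# summary tables from stage outputs
raretag report --stage1-dir s1/ --stage2-dir s2/ --out-dir report/

# everything from one JSON config (simulate -> stage1 -> stage2 -> report)
raretag all --config run.json --out-dir run/ --seed 1
```

`run.json` may override any default, e.g.:

```json
{
  "sim": {"n_individuals": 100, "n_subpopulations": 2, "n_common": 40,
          "n_rare": 20, "chromosome_length": 2000000, "seed": 0},
  "bin_size": 1000000, "n_s": 5,
  "rare_threshold": 0.01, "common_threshold": 0.05,
  "threshold_pairs": [[0.80, 0.95], [0.95, 0.99]],
  "n_perm": 1000, "window_bp": 1000000, "seed": 1
}
```

Every run writes its resolved config next to its outputs; reruns with the
same seed are byte-identical. Inputs may also be real data: a biallelic-SNP
VCF (`genotypes.vcf`), an annotation TSV (`variant_id`, `chromosome`,
`position`, `functional`), and a population TSV (`individual_id`,
`subpopulation`) in one directory. Dosages always count the minor allele;
variants in perfect LD (r² = 1) with an earlier variant are dropped at load.

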