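# dlahap

Three-locus **DLA haplotype analysis** for the dog major
histocompatibility complex: phasing of unphased `DLA-88` /
`DLA-12/88L` / `DLA-DRB1` genotypes into haplotypes, per-breed
diversity statistics, homozygous-donor transplant-coverage modeling,
and breed population-structure PCA — plus a synthetic cohort generator
so the whole pipeline is testable without access to clinical genotype
data.

It is written for immunogeneticists and veterinary researchers working
with breed-stratified DLA (or other MHC-style) genotype surveys:
people who have a table of per-dog allele calls and want haplotype
frequency tables, Ho/He/Fis/Hr diversity indices, Hardy–Weinberg tests
and donor-bank coverage curves out the other end.

## The science in brief

A dog's DLA class I/II core region carries, on each chromosome, an
ordered triple of alleles at `DLA-88`, the `DLA-12`-or-`DLA-88L` slot
(two alternative haplotype *structures*, `88-12-DRB1` vs
`88-88L-DRB1`), and `DLA-DRB1` — a *haplotype*. Genotyping yields only
unordered allele pairs per locus, so haplotypes must be reconstructed:

* **Tiered homozygote-anchored phasing** (`phase_cohort`): dogs
  homozygous at all three loci (tier `hom3`) or heterozygous at exactly
  one locus (`hom2`) have a forced phase; their haplotypes seed a
  registry. Remaining dogs are resolved only when exactly one of their
  2^(h−1) phase-consistent diplotypes is composed entirely of registry
  haplotypes (`hom1_ref`, `het_ref`); ambiguous dogs stay unresolved.
* **EM cross-check** (`em_phase`): gene-counting
  expectation–maximisation over the spanned haplotype space gives
  maximum-likelihood frequencies p̂ under random pairing and a
  posterior-mode diplotype per dog, used to confirm the tiered calls.

From the phased cohort the package computes haplotype frequency tables
(`count / 2N` with singleton flagging and the structure partition),
observed heterozygosity `Ho = 1 − n_hom/N`, expected heterozygosity
`He = 1 − Σp²` (biased and Nei's unbiased forms), the inbreeding
coefficient `Fis = 1 − Ho/Hs` with Nei's within-sample gene diversity
`Hs`, rarefied haplotype richness
`Hr(g) = Σᵢ [1 − C(2N−Nᵢ, g)/C(2N, g)]`, a Monte-Carlo
Hardy–Weinberg test (random re-pairing of the 2N observed
chromosomes), donor coverage curves (fraction of dogs carrying ≥ 1 of
the top-k haplotypes observed in homozygotes), and a covariance PCA of
the breed × haplotype frequency matrix at field-1 allele resolution.

## Worked example

The bundled study-scale simulation (24 breeds, 10–49 dogs each,
skewed per-breed haplotype pools, ~21 % `88-88L` structures,
inbreeding coefficients from −0.21 to 0.32):

```python
from dlahap import (study_like_config, simulate_cohort, phase_cohort,
                    build_haplotype_table, diversity_reports, cohort_summary,
                    coverage_curve, rank_donor_haplotypes)

cohort = simulate_cohort(study_like_config(seed=1))
result = phase_cohort(cohort.genotypes())
print(f"resolved {result.n_resolved}/{len(result.records)} dogs, tiers {result.tier_counts}")

table = build_haplotype_table(result)
for s, d in table.structure_partition().items():
    print(f"{s}: {d['n_haplotypes']} haplotypes, {d['n_copies']} copies ({d['pct_copies']}%)")

reports = diversity_reports(result, n_perm=1000, seed=1)
print(f"mean Ho over {len(reports)} breeds: {cohort_summary(reports).mean_ho}")

curve = coverage_curve(result, rank_donor_haplotypes(result))
print(f"top 9 donor haplotypes cover {curve.cum_counts[8]}/{curve.n_assigned} dogs ({curve.cum_pct[8]}%)")
```

prints

```
resolved 569/690 dogs, tiers {'hom3': 222, 'hom2': 6, 'hom1_ref': 44, 'het_ref': 297}
88-12-DRB1: 35 haplotypes, 949 copies (83.4%)
88-88L-DRB1: 6 haplotypes, 189 copies (16.6%)
mean Ho over 22 breeds: 0.604
top 9 donor haplotypes cover 351/569 dogs (61.7%)
```

— 569 of 690 dogs phased (222 directly as three-locus homozygotes, the
rest against the registry), five sixths of phased chromosomes carrying
the `88-12` structure, a cohort-mean observed heterozygosity of 0.604
across the 22 breeds meeting the 10-dog minimum, and a 9-haplotype
homozygous-donor bank that would cover 61.7 % of phased dogs for
DLA-matched transplantation.

The same pipeline runs from the shell on genotype TSVs
(`dog_id, breed, a88_1, a88_2, a12_88L_1, a12_88L_2, drb1_1, drb1_2`):

```sh
dlahap all --seed 1 --outdir out --prefix demo
# resolved 569/690 dogs; mean Ho 0.604; wrote 14 files to out
dlahap phase --genotypes my_cohort.tsv --out-prefix run
dlahap diversity --phasing run.phasing.tsv
```

Subcommands (`simulate`, `phase`, `tables`, `diversity`, `coverage`,
`pca`, `compare`, `all`) each read and write TSVs so stages compose.

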