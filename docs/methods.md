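# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `dlahap`, and what the synthetic-data tests do
and do not establish about real genotype data.

## Phasing model

A dog's genotype is three unordered allele pairs, one per locus
(`DLA-88`, the `DLA-12/88L` slot, `DLA-DRB1`). With `h` heterozygous
loci there are `2^max(h−1, 0)` phase-consistent diplotypes
(`enumerate_diplotypes`; the orientation of the first heterozygous
locus is fixed to quotient out the chromosome swap).

`phase_cohort` reconstructs haplotypes the way curators of MHC breed
surveys do by hand:

1. **Anchoring.** Dogs with `h ≤ 1` have a unique phase. Three-locus
   homozygotes are resolved at tier `hom3`, single-locus heterozygotes
   at `hom2`, and their haplotypes enter a registry annotated with the
   first tier at which each haplotype was seen.
2. **Registry filtering.** For every remaining dog the candidate
   diplotypes are screened against the registry; if exactly one
   candidate consists of two registry haplotypes the dog is resolved
   (tier `hom1_ref` for `h = 2`, `het_ref` for `h = 3`). Rounds repeat
   to a fixpoint, bounded by `max_rounds` (default 10).

Two deliberately conservative conventions: a dog whose surviving
candidates share one haplotype but differ in the other stays
unresolved (no partial credit), and ties are never broken by frequency
— frequency-based assignment is the EM phaser's job and is reported
separately. By default haplotypes inferred for multi-heterozygous dogs
do **not** extend the registry, keeping the anchor set
homozygote-derived; `resolve_and_extend=True` lets each newly resolved
dog's haplotypes join the registry, which can only increase the
resolved set. Both behaviours are exposed because survey practice is
ambiguous about whether haplotypes first seen in double-heterozygous
dogs may anchor later assignments.

Registry filtering is sound whenever every haplotype segregating in
the cohort is anchored by some low-heterozygosity dog: the true
diplotype then always survives screening, so a unique survivor must be
the truth. When rare haplotypes never appear in near-homozygous dogs a
unique-but-wrong survivor is possible in principle; the simulation
tests measure this and observe zero wrong resolutions at the standard
setting (below).

`em_phase` is classical gene-counting EM over the haplotype space
spanned by all candidates: dog likelihood `Σ m·p_i·p_j` over candidate
pairs (multiplier 2 when heterozygous), E-step posterior-weighted
chromosome counts, M-step renormalisation. The log-likelihood is
asserted non-decreasing each run; iteration stops when the gain falls
below `tol` (default 1e-8, `max_iter` 1000). Initialisation is
uniform; the likelihood is multimodal in principle but in the tested
regimes the fixpoint is insensitive to the start.

## Diversity estimators

* `Ho = 1 − n_hom/N`, exact rational, reported to 3 decimals
  (half-up).
* `He`: biased `1 − Σp̂²` by default — matching the uncorrected form
  most survey software prints — with Nei's unbiased
  `2N/(2N−1)·(1 − Σp̂²)` always available.
* `Fis = 1 − Ho/Hs` with Nei's within-sample gene diversity
  `Hs = N/(N−1)·(1 − Σp̂² − Ho/2N)` (the FSTAT-style estimator); the
  naive `1 − Ho/He` is reported alongside. Monomorphic samples yield
  NaN ("not applicable") rather than an arbitrary zero.
* `Hr(g) = Σᵢ [1 − C(2N−Nᵢ,g)/C(2N,g)]`, the expected number of
  distinct haplotypes in a subsample of `g` gene copies; the
  non-observation probabilities come from
  `scipy.stats.hypergeom.pmf(0, …)`, exact and overflow-safe. The
  default `g` is the smallest included breed's `2N`, so richness is
  comparable across breeds.
* The HWE test statistic is the χ² distance between observed diplotype
  counts and expectations `N·p̂ᵢ²` / `2N·p̂ᵢp̂ⱼ`; the null re-pairs the
  2N observed chromosomes uniformly at random (haplotype counts held
  fixed), `p = (1 + #{null ≥ obs})/(1 + n_perm)` with `n_perm`
  defaulting to 10 000 and a fixed seed. An asymptotic χ² p-value with
  `k(k−1)/2` df is reported for reference but the permutation p is
  authoritative — with dozens of rare haplotypes per breed the
  asymptotic reference is unreliable. Significance is annotated at
  p < 0.05 and p < 0.001 with no multiple-testing correction, matching
  survey convention.

Percentages are formatted half-up at the printed precision; a
truncation mode exists because some published rates are truncated
(e.g. a homozygosity rate of 198/829 printed as 23.8 %), and the
formatter takes the convention as a flag rather than guessing.

## Coverage modeling

Donor haplotypes are those observed in at least one homozygous dog,
ranked by cohort frequency (ties broken by canonical label order so
runs are deterministic). A recipient is covered at rank k iff its
diplotype contains ≥ 1 of the top-k donor haplotypes — matching in the
host-versus-graft direction only. The denominator is the set of dogs
with an assigned diplotype; a full-cohort denominator is available
because published coverage percentages are not always consistent about
which denominator they use. Breed-spread annotations count distinct
non-mongrel breeds per haplotype and report a predominant breed when
one holds > 70 % of copies.

## Population structure

Breed rows are within-breed haplotype frequencies with labels
collapsed to field-1 resolution (the first colon-separated field of
each allele name; deeper fields encode synonymous or non-binding-site
differences). PCA is covariance PCA of the column-centered matrix —
frequencies share a scale, so columns are not standardized by default
(a standardized option exists since the historically used spreadsheet
tools are not explicit about their internal transform). Components get
a deterministic sign (largest-magnitude loading positive). Mongrels
are excluded from PCA, as a mixed group is not a breed population.
Cross-cohort comparison uses Pearson r over the union of alleles seen
in either cohort with absences as zeros, so private alleles penalise
the correlation.

## Synthetic cohort generator

`simulate` draws, per breed, a pool of `n_haplotypes` distinct
haplotypes with symmetric-Dirichlet(α) frequencies; `floor(frac_88L ·
n_haplotypes)` of them carry the `88-88L` structure. Dogs are two
chromosome draws from the pool with an inbreeding mixture:

* `fis > 0`: with probability `fis` one draw is copied (identical by
  descent) — the expected haplotype-level Fis equals the configured
  value.
* `fis < 0`: homozygous draws are rejected with the probability `r`
  solving `s(1−r)/(1−rs) = s + fis(1−s)` (`s = Σp²`), so the expected
  homozygote fraction hits the target exactly. Below the scheme's
  feasibility bound `fis < −s/(1−s)` no rejection probability exists;
  such draws are clamped to the bound with a warning, while
  structurally impossible requests (|fis| > 1, negative fis on a
  monomorphic pool, pools exceeding allele-pool capacity) raise a
  config error.

One root seed spawns independent child streams (shared pool first,
then one per breed), so adding a breed to a config never perturbs the
cohorts of existing breeds, and identical config + seed gives
byte-identical output. An optional cohort-wide shared haplotype pool
makes breeds overlap in haplotype content, which is what gives the
breed PCA its structure.

`study_like_config()` fixes the generator at the scale of real
multi-breed DLA surveys: 24 breeds of 10–49 dogs, pools of 3–27
haplotypes, Dirichlet α = 0.4 (strongly skewed, a few dominant
haplotypes per breed), 21 % `88-88L` structures, Fis from −0.21 to
0.32, and a shared pool of 60 haplotypes.

What the generator does **not** emulate: linkage-disequilibrium decay
between the three loci, mutation and recombination, pedigree
structure, genotyping error, and missing calls. Passing tests
therefore demonstrate correctness of the estimators and the phasing
logic under clean random-mating-with-inbreeding sampling — not
robustness to genotyping artefacts or to cohorts where many haplotypes
never appear in a near-homozygous dog.

## Problem sizes and test design

The simulation-backed checks run at sizes where the expected sampling
error is well inside the asserted tolerances: parameter-recovery and
soundness checks use single-breed cohorts of 2000 dogs with 8
haplotypes over 20 seeds (binomial SE of a frequency over 4000
chromosomes ≈ 0.008, against a ±0.02 band; Fis mean over 20 × 2000
dogs against ±0.05); HWE calibration uses 200 null cohorts of 50 dogs
with 999 permutations (rejection-rate SE ≈ 0.015 against a ±0.03
band); convergence checks of the generator run at 10⁴ dogs with 3-SE
bands. Exhaustive oracles (brute-force diplotype assignment,
subsample enumeration for rarefaction, full re-pairing enumeration at
six chromosomes, dense SVD) are kept at sizes where enumeration is
exact and instant.

## Known limitations

* The tiered phaser's guarantees are empirical, not structural: on
  cohorts whose rare haplotypes lack homozygote anchors it can leave
  many dogs unresolved (and could in principle mis-resolve; not
  observed in testing).
* The EM phaser assumes random pairing within the cohort it is given;
  running it across pooled breeds mixes allele pools and its
  frequencies then describe the mixture, not any breed.
* Fis and He estimator variants differ subtly between the classical
  population-genetics packages; values here follow the Nei/FSTAT
  forms stated above and may differ in the third decimal from other
  software on the same data.
* Tentative (`nov##`) allele names are atomic: field-1 collapsing
  leaves them unchanged, so a tentative allele never merges with a
  numeric field-1 group even if later naming would merge them.
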