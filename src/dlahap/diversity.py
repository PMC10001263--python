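"""Haplotype frequency tables and per-breed diversity statistics.

Implements the classical descriptive toolkit of MHC breed surveys:

* haplotype frequency tables over the phased chromosomes, with
  singleton flagging and the 88-12 vs 88-88L structure partition;
* observed heterozygosity Ho = 1 - (homozygous dogs / dogs);
* expected heterozygosity He = 1 - sum(p^2), plus Nei's small-sample
  corrected (unbiased) gene diversity;
* the inbreeding coefficient Fis = 1 - Ho/Hs with Hs Nei's unbiased
  within-sample gene diversity (a simple 1 - Ho/He is also reported);
* rarefied haplotype richness Hr(g): the expected number of distinct
  haplotypes in a random subsample of g gene copies, from exact
  hypergeometric non-observation probabilities;
* a Monte-Carlo Hardy–Weinberg test that re-pairs the observed
  chromosomes at random;
* per-allele frequency and carrier-proportion summaries.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import HaplotypeLabel, STRUCTURE_12, STRUCTURE_88L
from .phasing import Diplotype, DogGenotype, PhasingResult

__all__ = [
    "HapEntry",
    "HaplotypeFrequencyTable",
    "DiversityReport",
    "CohortSummary",
    "FisEstimate",
    "HWEResult",
    "round_half_up",
    "format_percent",
    "build_haplotype_table",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "inbreeding_fis",
    "haplotype_richness",
    "hwe_test",
    "allele_summary",
    "diversity_reports",
    "cohort_summary",
]


# ---------------------------------------------------------------------
# rounding conventions


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(
    num: float, den: float, decimals: int = 1, mode: str = "half_up"
) -> float:
    """Percentage ``100 * num / den`` at a fixed precision.

    ``mode="half_up"`` rounds; ``mode="truncate"`` drops the excess
    digits (some published rates are truncated rather than rounded, so
    both conventions are available).
    """
    if den == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(repr(100.0 * num / den))
    q = Decimal(1).scaleb(-decimals)
    rounding = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}[mode]
    return float(pct.quantize(q, rounding=rounding))


# ---------------------------------------------------------------------
# haplotype frequency table


@dataclass(frozen=True)
class HapEntry:
    haplotype: HaplotypeLabel
    count: int
    frequency: float  # count / (2 * n_dogs_assigned)
    n_dogs_with: int
    n_homozygous_dogs: int
    singleton: bool

    @property
    def structure(self) -> str:
        return self.haplotype.structure


@dataclass
class HaplotypeFrequencyTable:
    """Counts and frequencies over the chromosomes of phased dogs."""

    n_dogs_assigned: int
    entries: dict[HaplotypeLabel, HapEntry]
    min_count: int = 2

    @property
    def total_copies(self) -> int:
        return 2 * self.n_dogs_assigned

    @property
    def retained(self) -> list[HapEntry]:
        """Entries meeting the count threshold (singletons excluded at 2)."""
        return [e for e in self.entries.values() if e.count >= self.min_count]

    @property
    def singletons(self) -> list[HapEntry]:
        return [e for e in self.entries.values() if e.singleton]

    def structure_partition(self) -> dict[str, dict[str, float]]:
        """Haplotype and copy counts per structure over the retained set."""
        out: dict[str, dict[str, float]] = {}
        retained = self.retained
        total = sum(e.count for e in retained)
        for structure in (STRUCTURE_12, STRUCTURE_88L):
            sub = [e for e in retained if e.structure == structure]
            copies = sum(e.count for e in sub)
            out[structure] = {
                "n_haplotypes": len(sub),
                "n_copies": copies,
                "pct_copies": format_percent(copies, total, 1) if total else math.nan,
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            self.entries.values(), key=lambda e: (-e.count, e.haplotype.sort_key)
        )
        return pd.DataFrame(
            {
                "haplotype": [e.haplotype.label() for e in rows],
                "structure": [e.structure for e in rows],
                "count": [e.count for e in rows],
                "frequency": [e.frequency for e in rows],
                "n_dogs": [e.n_dogs_with for e in rows],
                "n_homozygous": [e.n_homozygous_dogs for e in rows],
                "singleton": [e.singleton for e in rows],
            }
        )


def build_haplotype_table(
    result: PhasingResult, min_count: int = 2
) -> HaplotypeFrequencyTable:
    """Tabulate haplotype counts over the resolved dogs of a phasing run.

    Frequencies are over all ``2 x n_resolved`` chromosomes (singletons
    included in the denominator); ``min_count`` only controls which
    entries the structure partition and the "retained" view keep, with
    the default 2 excluding singletons as is conventional.
    """
    resolved = result.resolved_records
    if not resolved:
        raise ValueError("no resolved dogs: cannot build a haplotype table")
    copies: Counter = Counter()
    dogs_with: Counter = Counter()
    homo: Counter = Counter()
    for r in resolved:
        d = r.diplotype
        copies[d.hap1] += 1
        copies[d.hap2] += 1
        for h in set(d.haplotypes):
            dogs_with[h] += 1
        if d.homozygous:
            homo[d.hap1] += 1
    n = len(resolved)
    entries = {
        h: HapEntry(
            haplotype=h,
            count=c,
            frequency=c / (2 * n),
            n_dogs_with=dogs_with[h],
            n_homozygous_dogs=homo.get(h, 0),
            singleton=c == 1,
        )
        for h, c in copies.items()
    }
    return HaplotypeFrequencyTable(n_dogs_assigned=n, entries=entries, min_count=min_count)


# ---------------------------------------------------------------------
# scalar diversity statistics


def observed_heterozygosity(N: int, n_homozygous: int, decimals: int | None = 3) -> float:
    """Ho = 1 - n_homozygous / N, rounded half-up (``decimals=None`` for raw)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n_homozygous <= N:
        raise ValueError("n_homozygous must lie in [0, N]")
    ho = 1.0 - n_homozygous / N
    return ho if decimals is None else round_half_up(ho, decimals)


def expected_heterozygosity(
    frequencies, N: int | None = None, mode: str = "biased"
) -> float:
    """He from haplotype frequencies.

    ``biased``: 1 - sum(p^2).  ``unbiased``: Nei's small-sample
    correction ``2N/(2N-1) * (1 - sum(p^2))`` over ``2N`` gene copies.
    """
    p = np.asarray(list(frequencies), dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    he = 1.0 - float((p**2).sum())
    if mode == "biased":
        return he
    if mode == "unbiased":
        if N is None or N < 1:
            raise ValueError("unbiased mode requires the sample size N")
        return (2 * N) / (2 * N - 1) * he
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FisEstimate:
    """Inbreeding coefficient at the haplotype level.

    ``fis`` uses Nei's unbiased within-sample gene diversity Hs
    (the FSTAT-style estimator); ``fis_simple`` is the uncorrected
    1 - Ho/He.  Both are NaN for a monomorphic sample.
    """

    fis: float
    fis_simple: float
    ho: float
    hs: float
    he: float
    n: int


def inbreeding_fis(diplotypes: list[Diplotype]) -> FisEstimate:
    """Fis = 1 - Ho/Hs from a sample of diplotypes."""
    n = len(diplotypes)
    if n < 2:
        raise ValueError("Fis needs at least two dogs")
    counts: Counter = Counter()
    n_hom = 0
    for d in diplotypes:
        counts[d.hap1] += 1
        counts[d.hap2] += 1
        n_hom += d.homozygous
    ho = 1.0 - n_hom / n
    p = np.array(list(counts.values()), dtype=float) / (2 * n)
    he = 1.0 - float((p**2).sum())
    if len(counts) < 2:
        return FisEstimate(math.nan, math.nan, ho, 0.0, he, n)
    hs = n / (n - 1) * (he - ho / (2 * n))
    fis = 1.0 - ho / hs if hs > 0 else math.nan
    fis_simple = 1.0 - ho / he if he > 0 else math.nan
    return FisEstimate(fis, fis_simple, ho, hs, he, n)


def haplotype_richness(counts, g: int) -> float:
    """Rarefied richness: expected distinct haplotypes among g gene copies.

    ``Hr(g) = sum_i [1 - C(2N - N_i, g) / C(2N, g)]`` — one minus the
    hypergeometric probability of missing haplotype i entirely.
    """
    counts = [int(c) for c in counts]
    if any(c < 1 for c in counts):
        raise ValueError("haplotype counts must be positive")
    total = sum(counts)
    if not 1 <= g <= total:
        raise ValueError(f"subsample size g={g} must lie in [1, {total}]")
    return float(
        sum(1.0 - stats.hypergeom.pmf(0, total, c, g) for c in counts)
    )


# ---------------------------------------------------------------------
# Hardy–Weinberg testing


@dataclass(frozen=True)
class HWEResult:
    p_value: float  # Monte-Carlo re-pairing p
    p_asymptotic: float  # chi-square reference, k(k-1)/2 df
    chi2: float
    df: int
    n_perm: int


def _pair_chi2(
    chrom: np.ndarray, expected: np.ndarray, cell_of: np.ndarray
) -> float:
    i = chrom[0::2]
    j = chrom[1::2]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    obs = np.bincount(cell_of[lo, hi], minlength=expected.size).astype(float)
    return float(((obs - expected) ** 2 / expected).sum())


def _null_chi2(
    chrom: np.ndarray,
    expected: np.ndarray,
    cell_of: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Re-pairing null statistics, permutations vectorised in batches."""
    n_cells = expected.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        order = rng.random((b, chrom.size)).argsort(axis=1)
        shuffled = chrom[order]
        i, j = shuffled[:, 0::2], shuffled[:, 1::2]
        cells = cell_of[np.minimum(i, j), np.maximum(i, j)]
        flat = cells + (np.arange(b) * n_cells)[:, None]
        obs = np.bincount(flat.ravel(), minlength=b * n_cells).reshape(b, n_cells)
        out[done : done + b] = (((obs - expected) ** 2) / expected).sum(axis=1)
        done += b
    return out


def hwe_test(
    diplotypes: list[Diplotype], n_perm: int = 10000, seed: int | None = 0
) -> HWEResult:
    """Monte-Carlo exact Hardy–Weinberg test on diplotype counts.

    The statistic is the chi-square distance between observed diplotype
    counts and Hardy–Weinberg expectations from the observed haplotype
    frequencies.  The null distribution is generated by randomly
    re-pairing the 2N observed chromosomes, so haplotype counts are held
    fixed; ``p = (1 + #{null >= observed}) / (1 + n_perm)``.  A plain
    asymptotic chi-square p-value (k(k-1)/2 df) is reported alongside.
    """
    n = len(diplotypes)
    if n < 2:
        raise ValueError("HWE test needs at least two dogs")
    hap_index: dict[HaplotypeLabel, int] = {}
    chrom_list: list[int] = []
    for d in diplotypes:
        for h in d.haplotypes:
            chrom_list.append(hap_index.setdefault(h, len(hap_index)))
    k = len(hap_index)
    if k < 2:
        return HWEResult(math.nan, math.nan, math.nan, 0, n_perm)

    chrom = np.array(chrom_list)
    counts = np.bincount(chrom, minlength=k).astype(float)
    p = counts / (2 * n)

    # cells: unordered pairs (i <= j); expected counts under HW pairing
    cell_of = np.zeros((k, k), dtype=int)
    expected = []
    c = 0
    for i in range(k):
        for j in range(i, k):
            cell_of[i, j] = cell_of[j, i] = c
            expected.append(n * (p[i] ** 2 if i == j else 2 * p[i] * p[j]))
            c += 1
    expected = np.array(expected)

    observed_chi2 = _pair_chi2(chrom, expected, cell_of)
    rng = np.random.default_rng(seed)
    null = _null_chi2(chrom, expected, cell_of, n_perm, rng)
    exceed = int((null >= observed_chi2 - 1e-12).sum())
    p_mc = (1 + exceed) / (1 + n_perm)
    df = k * (k - 1) // 2
    p_asym = float(stats.chi2.sf(observed_chi2, df))
    return HWEResult(p_mc, p_asym, observed_chi2, df, n_perm)


# ---------------------------------------------------------------------
# allele-level summaries


def allele_summary(genotypes: list[DogGenotype]) -> pd.DataFrame:
    """Per-allele frequency, carrier count and carrier proportion.

    One row per (locus slot, allele); the 12/88L slot pools DLA-12 and
    DLA-88L alleles, which stay distinct through their sublocus tag.
    """
    if not genotypes:
        raise ValueError("no genotypes")
    n = len(genotypes)
    slots = ("88", "12/88L", "DRB1")
    rows = []
    for s, slot in enumerate(slots):
        copies: Counter = Counter()
        carriers: Counter = Counter()
        for g in genotypes:
            pair = g.pairs[s]
            for a in pair:
                copies[a] += 1
            for a in set(pair):
                carriers[a] += 1
        for a in sorted(copies, key=lambda x: x.sort_key):
            rows.append(
                {
                    "slot": slot,
                    "allele": a.format(),
                    "count": copies[a],
                    "frequency": copies[a] / (2 * n),
                    "n_carriers": carriers[a],
                    "carrier_proportion": carriers[a] / n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# per-breed reports


@dataclass
class DiversityReport:
    """Per-breed haplotype diversity indices."""

    breed: str
    N: int  # dogs with an assigned diplotype
    n_unassigned: int
    n_haplotypes: int
    n_homozygous: int
    ho: float
    he_biased: float
    he_unbiased: float
    fis: float
    fis_simple: float
    hr: float
    hr_g: int
    hwe_p: float
    hwe_p_asymptotic: float

    @property
    def hwe_flag(self) -> str:
        if math.isnan(self.hwe_p):
            return "NA"
        if self.hwe_p < 0.001:
            return "p<0.001"
        if self.hwe_p < 0.05:
            return "p<0.05"
        return "-"


def diversity_reports(
    result: PhasingResult,
    min_dogs: int = 10,
    g: int | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> list[DiversityReport]:
    """One :class:`DiversityReport` per breed with ``min_dogs`` assigned dogs.

    The rarefaction size ``g`` defaults to the smallest included breed's
    2N gene copies so richness is comparable across breeds.  The HWE
    Monte-Carlo seed is offset per breed for independent streams.
    """
    by_breed: dict[str, list] = {}
    unassigned: Counter = Counter()
    for r in result.records:
        if include is not None and r.breed not in include:
            continue
        if exclude is not None and r.breed in exclude:
            continue
        if r.resolved:
            by_breed.setdefault(r.breed, []).append(r.diplotype)
        else:
            unassigned[r.breed] += 1
    by_breed = {b: d for b, d in by_breed.items() if len(d) >= min_dogs}
    if not by_breed:
        raise ValueError("no breed meets the minimum sample size")
    if g is None:
        g = min(2 * len(d) for d in by_breed.values())

    reports = []
    for offset, (breed, dips) in enumerate(sorted(by_breed.items())):
        N = len(dips)
        counts: Counter = Counter()
        n_hom = 0
        for d in dips:
            counts[d.hap1] += 1
            counts[d.hap2] += 1
            n_hom += d.homozygous
        freqs = [c / (2 * N) for c in counts.values()]
        fis = inbreeding_fis(dips)
        hwe = (
            hwe_test(dips, n_perm=n_perm, seed=seed + offset)
            if len(counts) > 1
            else HWEResult(math.nan, math.nan, math.nan, 0, n_perm)
        )
        g_breed = min(g, 2 * N)
        reports.append(
            DiversityReport(
                breed=breed,
                N=N,
                n_unassigned=unassigned.get(breed, 0),
                n_haplotypes=len(counts),
                n_homozygous=n_hom,
                ho=observed_heterozygosity(N, n_hom, decimals=None),
                he_biased=expected_heterozygosity(freqs),
                he_unbiased=expected_heterozygosity(freqs, N=N, mode="unbiased"),
                fis=fis.fis,
                fis_simple=fis.fis_simple,
                hr=haplotype_richness(counts.values(), g_breed),
                hr_g=g_breed,
                hwe_p=hwe.p_value,
                hwe_p_asymptotic=hwe.p_asymptotic,
            )
        )
    return reports


@dataclass
class CohortSummary:
    mean_ho: float  # unweighted arithmetic mean over breeds, 3 decimals
    table: pd.DataFrame


def cohort_summary(reports: list[DiversityReport]) -> CohortSummary:
    """Unweighted mean Ho across breeds plus the per-breed table."""
    if not reports:
        raise ValueError("no reports")
    mean_ho = round_half_up(
        sum(round_half_up(r.ho, 3) for r in reports) / len(reports), 3
    )
    table = pd.DataFrame(
        {
            "breed": [r.breed for r in reports],
            "N": [r.N for r in reports],
            "n_unassigned": [r.n_unassigned for r in reports],
            "n_haplotypes": [r.n_haplotypes for r in reports],
            "n_homozygous": [r.n_homozygous for r in reports],
            "Ho": [round_half_up(r.ho, 3) for r in reports],
            "He": [round_half_up(r.he_biased, 3) for r in reports],
            "He_unbiased": [round_half_up(r.he_unbiased, 3) for r in reports],
            "Fis": [round_half_up(r.fis, 3) if not math.isnan(r.fis) else math.nan for r in reports],
            "Hr": [round_half_up(r.hr, 2) for r in reports],
            "hr_g": [r.hr_g for r in reports],
            "HWE_p": [r.hwe_p for r in reports],
            "HWE": [r.hwe_flag for r in reports],
        }
    )
    return CohortSummary(mean_ho=mean_ho, table=table)
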