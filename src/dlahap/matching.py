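"""Homozygous-donor haplotype banks and recipient coverage.

MHC-matched stem-cell transplantation favours donors homozygous for a
haplotype: a recipient carrying at least one copy of the donor
haplotype sees no foreign MHC in the host-versus-graft direction.  The
functions here rank the haplotypes observed in homozygous dogs by
cohort frequency, accumulate the fraction of dogs matched as the donor
bank grows (the coverage curve), and summarise per-breed coverage by
each breed's own most frequent haplotype, plus how widely each
haplotype spreads across breeds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .nomenclature import HaplotypeLabel
from .diversity import HaplotypeFrequencyTable, format_percent
from .phasing import PhasingResult

__all__ = [
    "CoverageCurve",
    "rank_donor_haplotypes",
    "coverage_curve",
    "breed_top_coverage",
    "breed_spread",
]

MONGREL_NAMES = frozenset({"mongrel", "mongrels", "mixed", "mix"})


def _is_mongrel(breed: str) -> bool:
    return breed.strip().lower() in MONGREL_NAMES


def rank_donor_haplotypes(result: PhasingResult) -> list[HaplotypeLabel]:
    """Haplotypes observed in at least one homozygous dog, ranked by
    cohort frequency (descending), ties broken by canonical label order."""
    counts = result.haplotype_counts()
    hom_haps = {
        r.diplotype.hap1
        for r in result.resolved_records
        if r.diplotype.homozygous
    }
    if not hom_haps:
        warnings.warn("no homozygous dogs: empty donor ranking", stacklevel=2)
        return []
    return sorted(hom_haps, key=lambda h: (-counts[h], h.sort_key))


@dataclass
class CoverageCurve:
    """Cumulative recipient coverage as the donor bank grows.

    ``cum_counts[k-1]`` is the number of assigned dogs carrying at least
    one of the top-k donor haplotypes; percentages are over
    ``n_assigned`` dogs.
    """

    donors: list[HaplotypeLabel]
    cum_counts: list[int]
    n_assigned: int

    @property
    def cum_pct(self) -> list[float]:
        return [format_percent(c, self.n_assigned, 1) for c in self.cum_counts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.donors) + 1),
                "haplotype": [h.label() for h in self.donors],
                "cum_count": self.cum_counts,
                "cum_pct": self.cum_pct,
            }
        )


def coverage_curve(
    result: PhasingResult, donors: list[HaplotypeLabel] | None = None
) -> CoverageCurve:
    """Coverage of assigned dogs by a ranked donor-haplotype bank.

    A dog is matched at rank k iff its diplotype contains at least one
    of the first k donor haplotypes (host-versus-graft matching; the
    reverse direction is not modeled).
    """
    resolved = result.resolved_records
    if not resolved:
        raise ValueError("no resolved dogs: coverage undefined")
    if donors is None:
        donors = rank_donor_haplotypes(result)
    observed = set(result.haplotype_counts())
    for h in donors:
        if h not in observed:
            raise ValueError(f"donor haplotype {h.label()} not observed in cohort")
    matched: set[str] = set()
    cum = []
    for h in donors:
        for r in resolved:
            if h in r.diplotype.haplotypes:
                matched.add(r.dog_id)
        cum.append(len(matched))
    return CoverageCurve(donors=list(donors), cum_counts=cum, n_assigned=len(resolved))


def breed_top_coverage(result: PhasingResult) -> pd.DataFrame:
    """Per breed: its most frequent haplotype and the share of the
    breed's assigned dogs carrying at least one copy."""
    by_breed: dict[str, list] = {}
    for r in result.resolved_records:
        by_breed.setdefault(r.breed, []).append(r.diplotype)
    if not by_breed:
        raise ValueError("no resolved dogs")
    rows = []
    for breed in sorted(by_breed):
        dips = by_breed[breed]
        counts: Counter = Counter()
        for d in dips:
            counts[d.hap1] += 1
            counts[d.hap2] += 1
        top = min(
            (h for h, c in counts.items() if c == max(counts.values())),
            key=lambda h: h.sort_key,
        )
        carriers = sum(1 for d in dips if top in d.haplotypes)
        rows.append(
            {
                "breed": breed,
                "haplotype": top.label(),
                "carriers": carriers,
                "N": len(dips),
                "pct": format_percent(carriers, len(dips), 1),
            }
        )
    return pd.DataFrame(rows).sort_values("pct", ascending=False, ignore_index=True)


def breed_spread(
    table: HaplotypeFrequencyTable,
    result: PhasingResult,
    predominance_threshold: float = 0.70,
) -> pd.DataFrame:
    """Per haplotype: breed spread and predominant breed.

    ``n_breeds`` counts distinct non-mongrel breeds in which the
    haplotype occurs.  When a single breed holds more than
    ``predominance_threshold`` of all copies (mongrels included in the
    copy totals), that breed is reported with its share (1 decimal).
    """
    copies_by_breed: dict[HaplotypeLabel, Counter] = {}
    for r in result.resolved_records:
        for h in r.diplotype.haplotypes:
            copies_by_breed.setdefault(h, Counter())[r.breed] += 1
    rows = []
    order = sorted(
        table.entries.values(), key=lambda e: (-e.count, e.haplotype.sort_key)
    )
    for e in order:
        per_breed = copies_by_breed.get(e.haplotype, Counter())
        n_breeds = sum(1 for b in per_breed if not _is_mongrel(b))
        total = sum(per_breed.values())
        predominant, share = "", float("nan")
        if total:
            b, c = max(per_breed.items(), key=lambda kv: (kv[1], kv[0]))
            if c / total > predominance_threshold:
                predominant, share = b, format_percent(c, total, 1)
        rows.append(
            {
                "haplotype": e.haplotype.label(),
                "count": e.count,
                "n_breeds": n_breeds,
                "predominant_breed": predominant,
                "predominant_share_pct": share,
            }
        )
    return pd.DataFrame(rows)
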