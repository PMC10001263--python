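"""Three-locus haplotype phasing from unphased genotypes.

Two complementary phasers are provided.

``phase_cohort``
    A tiered, homozygote-anchored procedure.  Dogs homozygous at all
    three loci, or heterozygous at exactly one locus, have a unique
    phase; their haplotypes seed a registry of known haplotypes.  Every
    remaining dog is then resolved only if exactly one of its
    phase-consistent diplotypes is composed entirely of registry
    haplotypes.  This mirrors how DLA haplotypes are assigned by hand in
    breed surveys, and deliberately leaves ambiguous dogs unresolved.

``em_phase``
    Classical gene-counting EM over the haplotype space spanned by the
    cohort's phase-consistent diplotypes, yielding maximum-likelihood
    haplotype frequencies under random pairing and a posterior-mode
    diplotype per dog.  It serves as an independent statistical
    cross-check of the tiered assignments.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .nomenclature import AlleleName, HaplotypeLabel

__all__ = [
    "DogGenotype",
    "Diplotype",
    "DogPhase",
    "PhasingResult",
    "EMResult",
    "enumerate_diplotypes",
    "phase_cohort",
    "em_phase",
]

#: Resolution tiers, in the order haplotypes are discovered:
#: hom3 = homozygous at all three loci; hom2 = heterozygous at exactly one
#: locus (unique phase); hom1_ref / het_ref = resolved against the registry
#: with two / three heterozygous loci.
TIERS = ("hom3", "hom2", "hom1_ref", "het_ref")

_SLOT_LOCI = (("88",), ("12", "88L"), ("DRB1",))
_SLOT_NAMES = ("88", "12/88L", "DRB1")


def _canonical_pair(a: AlleleName, b: AlleleName) -> tuple[AlleleName, AlleleName]:
    return (a, b) if a.sort_key <= b.sort_key else (b, a)


@dataclass(frozen=True)
class DogGenotype:
    """Unphased genotype: unordered allele pairs at the three DLA loci."""

    dog_id: str
    breed: str
    pair88: tuple[AlleleName, AlleleName]
    pair12_88L: tuple[AlleleName, AlleleName]
    pairDRB1: tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        for slot, pair, loci in zip(
            _SLOT_NAMES, self.pairs, _SLOT_LOCI, strict=True
        ):
            for a in pair:
                if a.locus not in loci:
                    raise ValueError(
                        f"dog {self.dog_id}: allele {a.format()} illegal in the "
                        f"{slot} column"
                    )
        for name, pair in zip(_SLOT_NAMES, self.pairs, strict=True):
            if pair != _canonical_pair(*pair):
                raise ValueError(
                    f"dog {self.dog_id}: {name} pair not in canonical order"
                )

    @classmethod
    def from_alleles(
        cls,
        dog_id: str,
        breed: str,
        pair88: tuple[AlleleName, AlleleName],
        pair12_88L: tuple[AlleleName, AlleleName],
        pairDRB1: tuple[AlleleName, AlleleName],
    ) -> "DogGenotype":
        """Build with pairs put into canonical sorted order."""
        return cls(
            dog_id,
            breed,
            _canonical_pair(*pair88),
            _canonical_pair(*pair12_88L),
            _canonical_pair(*pairDRB1),
        )

    @property
    def pairs(self) -> tuple[tuple[AlleleName, AlleleName], ...]:
        return (self.pair88, self.pair12_88L, self.pairDRB1)

    @property
    def het_loci(self) -> tuple[bool, bool, bool]:
        return tuple(a != b for a, b in self.pairs)  # type: ignore[return-value]

    @property
    def n_het(self) -> int:
        return sum(self.het_loci)


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotypes; stored in canonical sorted order."""

    hap1: HaplotypeLabel
    hap2: HaplotypeLabel

    def __post_init__(self) -> None:
        if self.hap2.sort_key < self.hap1.sort_key:
            h1, h2 = self.hap2, self.hap1
            object.__setattr__(self, "hap1", h1)
            object.__setattr__(self, "hap2", h2)

    @classmethod
    def of(cls, a: HaplotypeLabel, b: HaplotypeLabel) -> "Diplotype":
        return cls(*((a, b) if a.sort_key <= b.sort_key else (b, a)))

    @property
    def haplotypes(self) -> tuple[HaplotypeLabel, HaplotypeLabel]:
        return (self.hap1, self.hap2)

    @property
    def homozygous(self) -> bool:
        return self.hap1 == self.hap2

    def projection(self) -> tuple[tuple[AlleleName, AlleleName], ...]:
        """Per-locus unordered allele pairs implied by the phase."""
        return tuple(
            _canonical_pair(a, b)
            for a, b in zip(self.hap1.alleles, self.hap2.alleles, strict=True)
        )

    def consistent_with(self, g: DogGenotype) -> bool:
        return self.projection() == g.pairs

    def to_genotype(self, dog_id: str, breed: str) -> DogGenotype:
        p88, p12, pdrb1 = self.projection()
        return DogGenotype(dog_id, breed, p88, p12, pdrb1)


def enumerate_diplotypes(g: DogGenotype) -> list[Diplotype]:
    """All phase-consistent diplotypes of a genotype.

    With ``h`` heterozygous loci there are ``2**max(h - 1, 0)`` distinct
    unordered phasings: the first heterozygous locus can be fixed to one
    chromosome without loss of generality.
    """
    het = g.het_loci
    het_idx = [i for i, h in enumerate(het) if h]
    free = het_idx[1:]  # orientation of the first het locus is fixed
    out = []
    for flips in itertools.product((False, True), repeat=len(free)):
        first = [g.pairs[i][0] for i in range(3)]
        second = [g.pairs[i][1] for i in range(3)]
        for i, flip in zip(free, flips, strict=True):
            if flip:
                first[i], second[i] = second[i], first[i]
        out.append(
            Diplotype.of(HaplotypeLabel(*first), HaplotypeLabel(*second))
        )
    return out


@dataclass(frozen=True)
class DogPhase:
    """Phasing outcome for one dog."""

    dog_id: str
    breed: str
    status: str  # "resolved" | "unresolved"
    tier: str | None
    diplotype: Diplotype | None
    n_candidates: int  # registry-consistent candidates at the final round

    @property
    def resolved(self) -> bool:
        return self.status == "resolved"


@dataclass
class PhasingResult:
    """Cohort-level phasing outcome.

    ``registry`` maps each known haplotype to the tier at which it was
    first seen.  ``records`` preserves cohort input order.
    """

    records: list[DogPhase]
    registry: dict[HaplotypeLabel, str]
    n_rounds: int
    resolve_and_extend: bool = False
    genotypes: list[DogGenotype] = field(default_factory=list, repr=False)

    @property
    def resolved_records(self) -> list[DogPhase]:
        return [r for r in self.records if r.resolved]

    @property
    def unresolved_records(self) -> list[DogPhase]:
        return [r for r in self.records if not r.resolved]

    @property
    def n_resolved(self) -> int:
        return len(self.resolved_records)

    @property
    def tier_counts(self) -> dict[str, int]:
        c = Counter(r.tier for r in self.resolved_records)
        return {t: c.get(t, 0) for t in TIERS}

    def haplotype_counts(self) -> Counter:
        """Chromosome counts over resolved dogs (sums to 2 x n_resolved)."""
        c: Counter = Counter()
        for r in self.resolved_records:
            c[r.diplotype.hap1] += 1
            c[r.diplotype.hap2] += 1
        return c

    def subset(self, breeds) -> "PhasingResult":
        """Restrict records to the given breeds (registry unchanged)."""
        keep = set(breeds) if not isinstance(breeds, str) else {breeds}
        return PhasingResult(
            records=[r for r in self.records if r.breed in keep],
            registry=self.registry,
            n_rounds=self.n_rounds,
            resolve_and_extend=self.resolve_and_extend,
            genotypes=[g for g in self.genotypes if g.breed in keep],
        )

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.breed, None)
        return list(seen)


def phase_cohort(
    genotypes: list[DogGenotype],
    max_rounds: int = 10,
    resolve_and_extend: bool = False,
) -> PhasingResult:
    """Tiered homozygote-anchored phasing of a cohort.

    Pass 1 resolves every dog with at most one heterozygous locus (the
    phase is forced) and registers its haplotypes: three-locus
    homozygotes at tier ``hom3``, then single-locus heterozygotes at
    tier ``hom2``.  Pass 2 repeatedly scans unresolved dogs and resolves
    any whose phase-consistent diplotypes include exactly one made
    entirely of registry haplotypes, until a fixpoint (bounded by
    ``max_rounds``).

    By default haplotypes inferred for multi-heterozygous dogs do not
    extend the registry, keeping the anchor set homozygote-derived; with
    ``resolve_and_extend=True`` each newly resolved dog's haplotypes
    join the registry, which can cascade into further resolutions.

    A dog with several surviving candidates stays unresolved — no
    frequency-based tie-breaking; that role belongs to :func:`em_phase`.
    """
    if not genotypes:
        raise ValueError("cannot phase an empty cohort")

    registry: dict[HaplotypeLabel, str] = {}
    outcome: dict[str, DogPhase] = {}
    pending: list[DogGenotype] = []

    # Pass 1, tier hom3 before hom2 so first-seen tiers reflect anchoring depth.
    for g in genotypes:
        if g.n_het == 0:
            d = enumerate_diplotypes(g)[0]
            outcome[g.dog_id] = DogPhase(g.dog_id, g.breed, "resolved", "hom3", d, 1)
            registry.setdefault(d.hap1, "hom3")
        elif g.n_het > 1:
            pending.append(g)
    for g in genotypes:
        if g.n_het == 1:
            d = enumerate_diplotypes(g)[0]
            outcome[g.dog_id] = DogPhase(g.dog_id, g.breed, "resolved", "hom2", d, 1)
            for h in d.haplotypes:
                registry.setdefault(h, "hom2")

    # Pass 2: registry-consistent filtering to fixpoint.
    candidates = {g.dog_id: enumerate_diplotypes(g) for g in pending}
    n_surviving = {g.dog_id: len(candidates[g.dog_id]) for g in pending}
    rounds = 0
    while pending and rounds < max_rounds:
        rounds += 1
        still_pending: list[DogGenotype] = []
        changed = False
        for g in pending:
            tier = "hom1_ref" if g.n_het == 2 else "het_ref"
            survivors = [
                d
                for d in candidates[g.dog_id]
                if d.hap1 in registry and d.hap2 in registry
            ]
            n_surviving[g.dog_id] = len(survivors)
            if len(survivors) == 1:
                d = survivors[0]
                outcome[g.dog_id] = DogPhase(
                    g.dog_id, g.breed, "resolved", tier, d, 1
                )
                if resolve_and_extend:
                    for h in d.haplotypes:
                        registry.setdefault(h, tier)
                changed = True
            else:
                still_pending.append(g)
        pending = still_pending
        if not changed:
            break

    for g in pending:
        outcome[g.dog_id] = DogPhase(
            g.dog_id, g.breed, "unresolved", None, None, n_surviving[g.dog_id]
        )

    return PhasingResult(
        records=[outcome[g.dog_id] for g in genotypes],
        registry=registry,
        n_rounds=rounds,
        resolve_and_extend=resolve_and_extend,
        genotypes=list(genotypes),
    )


@dataclass
class EMResult:
    """Maximum-likelihood haplotype frequencies and posterior-mode phases."""

    frequencies: dict[HaplotypeLabel, float]
    modal_diplotypes: dict[str, Diplotype]
    log_likelihoods: list[float]
    n_iter: int
    converged: bool

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihoods[-1]


def em_phase(
    genotypes: list[DogGenotype],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Gene-counting EM for haplotype frequencies.

    The haplotype space is the union of haplotypes appearing in any
    dog's phase-consistent diplotypes.  Under Hardy–Weinberg random
    pairing the likelihood of a dog is the sum over its candidate
    diplotypes of ``p_i * p_j`` (times 2 when heterozygous); the E-step
    distributes each dog's two chromosomes over candidates by posterior
    weight and the M-step re-normalises expected counts.  The
    log-likelihood is non-decreasing; iteration stops when its gain
    drops below ``tol``.
    """
    if not genotypes:
        raise ValueError("cannot run EM on an empty cohort")

    dog_cands = [enumerate_diplotypes(g) for g in genotypes]
    hap_index: dict[HaplotypeLabel, int] = {}
    for cands in dog_cands:
        for d in cands:
            for h in d.haplotypes:
                hap_index.setdefault(h, len(hap_index))
    K = len(hap_index)
    haps = list(hap_index)

    # Per dog: candidate index pairs and heterozygosity multiplier.
    pair_i = [np.array([hap_index[d.hap1] for d in c]) for c in dog_cands]
    pair_j = [np.array([hap_index[d.hap2] for d in c]) for c in dog_cands]
    mult = [
        np.array([1.0 if d.homozygous else 2.0 for d in c]) for c in dog_cands
    ]

    n = len(genotypes)
    p = np.full(K, 1.0 / K)
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(K)
        loglik = 0.0
        for i, j, m in zip(pair_i, pair_j, mult, strict=True):
            w = m * p[i] * p[j]
            tot = w.sum()
            loglik += math.log(tot) if tot > 0 else -math.inf
            if tot > 0:
                w = w / tot
            else:  # degenerate start: spread evenly
                w = np.full(len(w), 1.0 / len(w))
            np.add.at(counts, i, w)
            np.add.at(counts, j, w)
        p = counts / (2.0 * n)
        logliks.append(loglik)
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            converged = True
            break

    modal: dict[str, Diplotype] = {}
    for g, cands, i, j, m in zip(
        genotypes, dog_cands, pair_i, pair_j, mult, strict=True
    ):
        w = m * p[i] * p[j]
        modal[g.dog_id] = cands[int(np.argmax(w))]

    freqs = {haps[k]: float(p[k]) for k in range(K)}
    return EMResult(
        frequencies=freqs,
        modal_diplotypes=modal,
        log_likelihoods=logliks,
        n_iter=it,
        converged=converged,
    )
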