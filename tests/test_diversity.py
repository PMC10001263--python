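"""Frequency tables, heterozygosity, Fis, rarefied richness and HWE."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dlahap.diversity import (
    allele_summary,
    build_haplotype_table,
    cohort_summary,
    diversity_reports,
    expected_heterozygosity,
    format_percent,
    haplotype_richness,
    hwe_test,
    inbreeding_fis,
    observed_heterozygosity,
    round_half_up,
)
from dlahap.nomenclature import AlleleName, HaplotypeLabel, parse_haplotype
from dlahap.phasing import Diplotype, phase_cohort
from dlahap.simulate import BreedConfig, SimConfig, simulate_cohort


def _hap(i, j, k, mid="12"):
    return HaplotypeLabel(
        AlleleName("88", (f"{i:03d}", "01")),
        AlleleName(mid, (f"{j:03d}", "01")),
        AlleleName("DRB1", (f"{k:03d}", "01")),
    )


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, decimals, mode, expected",
        [
            (198, 829, 1, "truncate", 23.8),  # 23.88.. truncated, not rounded to 23.9
            (198, 829, 1, "half_up", 23.9),
            (68, 1606, 2, "half_up", 4.23),
            (62, 1606, 2, "half_up", 3.86),
            (1228, 1547, 1, "half_up", 79.4),
            (319, 1547, 1, "half_up", 20.6),
            (32, 33, 1, "half_up", 97.0),
            (29, 35, 1, "half_up", 82.9),
        ],
    )
    def test_percent_conventions(self, num, den, decimals, mode, expected):
        assert format_percent(num, den, decimals, mode) == expected

    def test_half_up_ties(self):
        assert round_half_up(0.3145, 3) == 0.315
        assert round_half_up(0.25, 1) == 0.3


class TestObservedHeterozygosity:
    @pytest.mark.parametrize(
        "N, n_hom, ho", [(35, 24, 0.314), (20, 9, 0.550), (7, 0, 1.000), (4, 4, 0.0)]
    )
    def test_examples(self, N, n_hom, ho):
        assert observed_heterozygosity(N, n_hom) == pytest.approx(ho)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            observed_heterozygosity(0, 0)
        with pytest.raises(ValueError):
            observed_heterozygosity(5, 6)


class TestExpectedHeterozygosity:
    def test_simple_cases(self):
        assert expected_heterozygosity([0.5, 0.5]) == pytest.approx(0.5)
        assert expected_heterozygosity([1.0]) == 0.0
        assert expected_heterozygosity([1.0], N=10, mode="unbiased") == 0.0

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10).map(
            lambda w: [x / sum(w) for x in w]
        )
    )
    def test_matches_direct_summation_and_unbiased_dominates(self, p):
        he = expected_heterozygosity(p)
        assert he == pytest.approx(1.0 - sum(x * x for x in p))
        assert expected_heterozygosity(p, N=25, mode="unbiased") >= he

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            expected_heterozygosity([0.5, 0.4])


class TestFis:
    def test_all_homozygous_gives_one(self):
        dips = [Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))] * 3 + [
            Diplotype.of(_hap(2, 2, 2), _hap(2, 2, 2))
        ] * 2
        assert inbreeding_fis(dips).fis == pytest.approx(1.0)

    def test_monomorphic_not_applicable(self):
        dips = [Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))] * 4
        est = inbreeding_fis(dips)
        assert math.isnan(est.fis) and math.isnan(est.fis_simple)

    def test_near_zero_for_random_pairing(self):
        cfg = SimConfig(
            breeds=(BreedConfig("b", 2000, 8, 1.0, 0.0),), frac_88L=0.25, seed=21
        )
        cohort = simulate_cohort(cfg)
        est = inbreeding_fis([d.diplotype for d in cohort.dogs])
        assert abs(est.fis) < 0.05

    def test_requires_two_dogs(self):
        with pytest.raises(ValueError):
            inbreeding_fis([Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))])


class TestRichness:
    def test_degenerate_cases(self):
        assert haplotype_richness([6], 3) == pytest.approx(1.0)
        assert haplotype_richness([3, 2, 1], 6) == pytest.approx(3.0)

    def test_exhaustive_subsample_oracle(self):
        counts = (3, 2, 1)
        g = 2
        genes = [0, 0, 0, 1, 1, 2]
        distinct = [
            len(set(sub)) for sub in itertools.combinations(genes, g)
        ]
        assert haplotype_richness(counts, g) == pytest.approx(np.mean(distinct))

    def test_monotone_in_g(self):
        counts = (5, 3, 2, 1, 1)
        values = [haplotype_richness(counts, g) for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(5.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            haplotype_richness([3, 2], 6)
        with pytest.raises(ValueError):
            haplotype_richness([3, 0], 2)


class TestHWE:
    def _random_cohort(self, seed, n=50, k=5, fis=0.0):
        cfg = SimConfig(
            breeds=(BreedConfig("b", n, k, 1.0, fis),), frac_88L=0.2, seed=seed
        )
        return [d.diplotype for d in simulate_cohort(cfg).dogs]

    def test_deterministic_under_seed(self):
        dips = self._random_cohort(3)
        a = hwe_test(dips, n_perm=500, seed=11)
        b = hwe_test(dips, n_perm=500, seed=11)
        assert a.p_value == b.p_value and a.chi2 == b.chi2

    def test_detects_strong_disequilibrium(self):
        # 50 dogs, all homozygous, two haplotypes: no heterozygotes at all
        dips = [Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))] * 25 + [
            Diplotype.of(_hap(2, 2, 2), _hap(2, 2, 2))
        ] * 25
        res = hwe_test(dips, n_perm=999, seed=0)
        assert res.p_value < 0.01
        assert res.p_asymptotic < 0.01

    def test_monomorphic_not_applicable(self):
        dips = [Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))] * 5
        assert math.isnan(hwe_test(dips).p_value)

    def test_matches_exhaustive_repairing_on_tiny_cohort(self):
        # 3 dogs / 6 chromosomes: enumerate all 6! orderings exactly
        dips = [
            Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1)),
            Diplotype.of(_hap(1, 1, 1), _hap(2, 2, 2)),
            Diplotype.of(_hap(2, 2, 2), _hap(2, 2, 2)),
        ]
        res = hwe_test(dips, n_perm=20000, seed=5)
        chrom = [0, 0, 0, 1, 1, 1]
        obs_stat = res.chi2
        exceed = total = 0
        for perm in itertools.permutations(range(6)):
            arr = [chrom[i] for i in perm]
            pairs = Counter(
                tuple(sorted(arr[2 * t : 2 * t + 2])) for t in range(3)
            )
            p = 0.5
            exp = {(0, 0): 3 * p * p, (0, 1): 6 * p * p, (1, 1): 3 * p * p}
            stat = sum(
                (pairs.get(c, 0) - e) ** 2 / e for c, e in exp.items()
            )
            exceed += stat >= obs_stat - 1e-12
            total += 1
        exact_p = exceed / total
        assert res.p_value == pytest.approx(exact_p, abs=0.02)


class TestHaplotypeTable:
    def test_single_homozygous_dog(self):
        dips = [Diplotype.of(_hap(1, 1, 1), _hap(1, 1, 1))]
        res = phase_cohort([dips[0].to_genotype("d0", "b")])
        table = build_haplotype_table(res)
        (entry,) = table.entries.values()
        assert entry.count == 2 and entry.frequency == 1.0
        assert entry.n_homozygous_dogs == 1 and not entry.singleton

    def test_conservation_and_singletons(self, multi_breed_cohort):
        res = phase_cohort(multi_breed_cohort.genotypes())
        table = build_haplotype_table(res)
        assert sum(e.count for e in table.entries.values()) == table.total_copies
        assert {e.haplotype for e in table.singletons} == {
            e.haplotype for e in table.entries.values() if e.count == 1
        }
        assert sum(e.frequency for e in table.entries.values()) == pytest.approx(1.0)

    def test_min_count_partition_excludes_singletons(self, multi_breed_cohort):
        res = phase_cohort(multi_breed_cohort.genotypes())
        t1 = build_haplotype_table(res, min_count=1)
        t2 = build_haplotype_table(res, min_count=2)
        only_in_t1 = {e.haplotype for e in t1.retained} - {
            e.haplotype for e in t2.retained
        }
        assert only_in_t1 == {e.haplotype for e in t2.singletons}
        part = t2.structure_partition()
        total = sum(d["n_copies"] for d in part.values())
        assert total == sum(e.count for e in t2.retained)


class TestAlleleSummary:
    def test_direct_count_oracle(self, multi_breed_cohort):
        genotypes = multi_breed_cohort.genotypes()
        df = allele_summary(genotypes)
        n = len(genotypes)
        # brute-force recount for every reported allele
        for _, row in df.iterrows():
            slot_idx = {"88": 0, "12/88L": 1, "DRB1": 2}[row["slot"]]
            copies = sum(
                (g.pairs[slot_idx][0].format() == row["allele"])
                + (g.pairs[slot_idx][1].format() == row["allele"])
                for g in genotypes
            )
            carriers = sum(
                row["allele"] in {a.format() for a in g.pairs[slot_idx]}
                for g in genotypes
            )
            assert row["count"] == copies
            assert row["frequency"] == pytest.approx(copies / (2 * n))
            assert row["n_carriers"] == carriers
            assert row["carrier_proportion"] == pytest.approx(carriers / n)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_summary([])


class TestReportsAndSummary:
    def test_breed_reports_consistency(self, multi_breed_cohort):
        res = phase_cohort(multi_breed_cohort.genotypes())
        reports = diversity_reports(res, min_dogs=10, n_perm=300, seed=0)
        for r in reports:
            assert r.ho == pytest.approx(1 - r.n_homozygous / r.N)
            assert 0 <= r.he_biased < 1
            assert r.he_unbiased >= r.he_biased
            assert r.hr <= r.n_haplotypes + 1e-9
            assert r.hr_g <= 2 * r.N

    def test_mean_ho_is_unweighted_and_order_invariant(self, multi_breed_cohort):
        res = phase_cohort(multi_breed_cohort.genotypes())
        reports = diversity_reports(res, min_dogs=10, n_perm=100, seed=0)
        summary = cohort_summary(reports)
        expected = round_half_up(
            np.mean([round_half_up(r.ho, 3) for r in reports]), 3
        )
        assert summary.mean_ho == expected
        reversed_summary = cohort_summary(list(reversed(reports)))
        assert reversed_summary.mean_ho == summary.mean_ho

    def test_single_breed_mean_is_its_ho(self, multi_breed_cohort):
        res = phase_cohort(multi_breed_cohort.genotypes())
        reports = diversity_reports(
            res, min_dogs=10, n_perm=100, seed=0, include=["akita"]
        )
        assert len(reports) == 1
        assert cohort_summary(reports).mean_ho == round_half_up(reports[0].ho, 3)
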