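"""Cohort summaries: rates, breakdowns, sharing, association, clustering."""

import numpy as np
import pandas as pd
import pytest

from mitopair.classify import classify_cohort
from mitopair.errors import ValidationError
from mitopair.io import PairedVariantRecord, VariantKey, VariantObservation
from mitopair.summary import (
    CohortTable,
    association_test,
    class_breakdown,
    cluster_profiles,
    gene_rates,
    percent,
    rate_per_kb,
    round_half_up,
    subtype_sharing,
)


def record(pid, pos, ref, alt, blood_maf, tumor_maf, depth=10000):
    return PairedVariantRecord(
        key=VariantKey(pos, ref, alt),
        blood=VariantObservation(pid, "blood", round(blood_maf * depth), depth),
        tumor=VariantObservation(pid, "tumor", round(tumor_maf * depth), depth),
    )


def build_cohort(records, patients=None, **meta_cols):
    pids = patients or sorted({r.patient_id for r in records})
    meta = pd.DataFrame({"patient_id": pids, **meta_cols})
    return CohortTable(patients=meta, records=classify_cohort(records))


class TestRates:
    @pytest.mark.parametrize(
        "count,length,expected,decimals",
        [
            (709, 16569, 42.79, 2),
            (47, 956, 49.2, 1),
            (0, 956, 0.0, 1),
        ],
    )
    def test_rate_per_kb(self, count, length, expected, decimals):
        assert round_half_up(rate_per_kb(count, length), decimals) == expected

    def test_rate_properties(self):
        # linear in count, inverse in length
        assert rate_per_kb(20, 500) == 2 * rate_per_kb(10, 500)
        assert rate_per_kb(10, 1000) == rate_per_kb(10, 500) / 2

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            rate_per_kb(1, 0)

    def test_percent_half_up(self):
        assert percent(68, 92) == 73.9
        assert percent(62, 68) == 91.2
        assert percent(1, 8) == 12.5


class TestGeneRates:
    def test_counts_assign_to_every_overlapping_gene(self, gene_map):
        ref = gene_map.ref_base(8550)
        alt = "A" if ref != "A" else "G"
        records = [record("P01", 8550, ref, alt, 0.0, 0.4)]
        cohort = build_cohort(records)
        rates = gene_rates(cohort, gene_map).set_index("gene")
        assert rates.loc["ATP8", "count"] == 1
        assert rates.loc["ATP6", "count"] == 1

    def test_both_tallies_reported(self, gene_map):
        # two alt alleles at one position: 2 variants, 1 position
        ref = gene_map.ref_base(13333)
        alts = [b for b in "ACGT" if b != ref][:2]
        records = [record("P01", 13333, ref, a, 0.0, 0.4) for a in alts]
        cohort = build_cohort(records)
        rates = gene_rates(cohort, gene_map).set_index("gene")
        assert rates.loc["ND5", "count"] == 2
        assert rates.loc["ND5", "count_positions"] == 1


class TestClassBreakdown:
    def test_small_constructed_cohort(self, gene_map, code):
        g = gene_map.ref_base
        records = [
            # P01: one germline, one somatic missense (13333 G>A)
            record("P01", 663, g(663), "G", 0.5, 0.9),
            record("P01", 13333, "G", "A", 0.0, 0.4),
            # P02: carries the germline variant only
            record("P02", 663, g(663), "G", 0.99, 0.99),
            # P03: nothing somatic; probable mutation
            record("P03", 4823, "T", "C", 0.005, 0.5),
        ]
        classified = classify_cohort(records, gene_map=gene_map, genetic_code=code)
        cohort = CohortTable(
            patients=pd.DataFrame({"patient_id": ["P01", "P02", "P03"]}),
            records=classified,
        )
        bd = class_breakdown(cohort)
        assert bd["origin"]["germline"]["count"] == 1
        assert bd["origin"]["somatic"]["count"] == 1
        assert bd["origin"]["probable_mutation"]["count"] == 1
        assert bd["variants"]["distinct_variants"] == 3
        assert bd["patients"]["somatic_positive"]["count"] == 1
        assert bd["patients"]["somatic_positive"]["pct"] == 33.3
        assert bd["somatic"]["coding"]["count"] == 1
        assert bd["somatic"]["missense"]["count"] == 1

    def test_positive_fraction_zero_without_somatic(self):
        records = [record("P01", 663, "A", "G", 0.5, 0.5)]
        cohort = build_cohort(records, patients=["P01", "P02"])
        bd = class_breakdown(cohort)
        assert bd["patients"]["somatic_positive"]["count"] == 0

    def test_empty_cohort(self):
        cohort = CohortTable(patients=pd.DataFrame({"patient_id": []}), records=[])
        assert class_breakdown(cohort) == {"empty": True}


class TestSubtypeSharing:
    def make(self, gene_map):
        g = gene_map.ref_base
        # somatic mutations: m1 in LA+LB, m2 only LA, m3 only LB
        records = [
            record("P01", 1000, g(1000), [b for b in "ACGT" if b != g(1000)][0], 0.0, 0.3),
            record("P02", 1000, g(1000), [b for b in "ACGT" if b != g(1000)][0], 0.0, 0.3),
            record("P01", 2000, g(2000), [b for b in "ACGT" if b != g(2000)][0], 0.0, 0.3),
            record("P03", 3000, g(3000), [b for b in "ACGT" if b != g(3000)][0], 0.0, 0.3),
        ]
        return build_cohort(
            records,
            patients=["P01", "P02", "P03", "P04"],
            subtype=["LA", "LB", "LB", "unassigned"],
        )

    def test_venn_partition(self, gene_map):
        sharing = subtype_sharing(self.make(gene_map))
        assert sharing.exclusive_counts == {"LA": 1, "LB": 1}
        shared = sharing.venn[frozenset(["LA", "LB"])]
        assert len(shared) == 1
        # exclusive + shared partition the universe
        total = sum(len(v) for v in sharing.venn.values())
        assert total == len(sharing.universe) == 3

    def test_rates_use_genome_length(self, gene_map):
        sharing = subtype_sharing(self.make(gene_map))
        assert sharing.rates_per_kb["LA"] == pytest.approx(2 * 1000 / 16569)

    def test_single_subtype_all_exclusive(self, gene_map):
        g = gene_map.ref_base
        records = [
            record("P01", 1000, g(1000), [b for b in "ACGT" if b != g(1000)][0], 0.0, 0.3)
        ]
        cohort = build_cohort(records, subtype=["LA"])
        sharing = subtype_sharing(cohort)
        assert sharing.exclusive_counts == {"LA": 1}
        assert all(len(k) == 1 for k in sharing.venn)


class TestAssociationTest:
    def test_perfect_independence(self):
        res = association_test([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """[[5,0],[0,5]]: only 1 of C(10,5)=252 tables per tail is as extreme."""
        res = association_test([[5, 0], [0, 5]])
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_chi2_for_large_tables(self):
        res = association_test([[50, 60], [55, 45]])
        assert res.test_used == "chi2"

    def test_degenerate_margin(self):
        with pytest.raises(ValidationError):
            association_test([[0, 0], [5, 5]])

    def test_null_p_uniformity(self):
        """Under planted independence, chi-square p-values are ~uniform."""
        from scipy import stats

        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            a = rng.multinomial(200, [0.25] * 4).reshape(2, 2)
            if (a.sum(0) == 0).any() or (a.sum(1) == 0).any():
                continue
            pvals.append(association_test(a).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestClustering:
    def mutation(self, gene_map, pid, pos):
        ref = gene_map.ref_base(pos)
        alt = [b for b in "ACGT" if b != ref][0]
        return record(pid, pos, ref, alt, 0.0, 0.4)

    def test_identical_profiles_merge_at_zero(self, gene_map):
        records = [self.mutation(gene_map, p, 1000) for p in ("P01", "P02")]
        res = cluster_profiles(build_cohort(records))
        assert res.linkage[0, 2] == 0.0

    def test_disjoint_profiles_distance_one(self, gene_map):
        records = [
            self.mutation(gene_map, "P01", 1000),
            self.mutation(gene_map, "P02", 2000),
        ]
        res = cluster_profiles(build_cohort(records))
        assert res.linkage[0, 2] == 1.0

    def test_planted_groups_recovered(self, gene_map):
        """8 patients in 2 planted mutation-profile groups: the 2-cluster
        cut separates them."""
        group_a = [1000, 2000, 3000]
        group_b = [9000, 10000, 11000]
        records = []
        for i in range(4):
            for pos in group_a:
                records.append(self.mutation(gene_map, f"A{i}", pos))
        for i in range(4):
            for pos in group_b:
                records.append(self.mutation(gene_map, f"B{i}", pos))
        res = cluster_profiles(build_cohort(records))
        labels = res.cut(2)
        a_labels = {labels[f"A{i}"] for i in range(4)}
        b_labels = {labels[f"B{i}"] for i in range(4)}
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_fewer_than_two_patients_signals_none(self, gene_map):
        records = [self.mutation(gene_map, "P01", 1000)]
        assert cluster_profiles(build_cohort(records)) is None
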