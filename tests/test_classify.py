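"""Origin/ploidy threshold classification and heteroplasmy-shift statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopair.classify import (
    ABSENT,
    GERMLINE,
    PROBABLE_MUTATION,
    SOMATIC,
    ClassificationConfig,
    classify_cohort,
    classify_origin,
    classify_ploidy,
    germline_evidenced_keys,
    mann_whitney_u,
    recurrence,
    shift_analysis,
)
from mitopair.errors import InputError, ValidationError
from mitopair.io import PairedVariantRecord, VariantKey, VariantObservation
from mitopair.summary import CohortTable

CFG = ClassificationConfig()


def record(blood_maf, tumor_maf, pid="P01", pos=663, ref="A", alt="G", depth=10000):
    return PairedVariantRecord(
        key=VariantKey(pos, ref, alt),
        blood=VariantObservation(pid, "blood", round(blood_maf * depth), depth),
        tumor=VariantObservation(pid, "tumor", round(tumor_maf * depth), depth),
    )


class TestOrigin:
    @pytest.mark.parametrize(
        "blood,tumor,expected",
        [
            (0.0005, 0.30, SOMATIC),
            (0.005, 0.99, PROBABLE_MUTATION),
            (0.50, 0.0, GERMLINE),  # germline regardless of tumor proportion
            (0.0, 0.0, ABSENT),
            (0.0, 0.011, SOMATIC),
            (0.001, 0.30, PROBABLE_MUTATION),  # boundary: somatic rule is strict
            (0.011, 0.0, GERMLINE),
        ],
    )
    def test_thresholds(self, blood, tumor, expected):
        assert classify_origin(record(blood, tumor), CFG) == expected

    def test_cohort_germline_propagation(self):
        """A variant germline-evidenced in one patient cannot be somatic in another."""
        carrier = record(0.50, 0.60, pid="P01")
        other = record(0.0, 0.30, pid="P02")
        germ = germline_evidenced_keys([carrier, other], CFG)
        assert classify_origin(other, CFG, germ) == GERMLINE
        # without the cohort context the same record is somatic
        assert classify_origin(other, CFG) == SOMATIC

    def test_invalid_maf_rejected(self):
        rec = PairedVariantRecord(
            key=VariantKey(663, "A", "G"),
            blood=VariantObservation("P01", "blood", 0, 0),
            tumor=VariantObservation("P01", "tumor", 0, 100),
        )
        # depth-0 observation yields maf 0.0, fine; invalid config instead:
        with pytest.raises(InputError):
            ClassificationConfig(somatic_normal_max=0.5, somatic_tumor_min=0.01)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        blood=st.floats(0, 1, allow_nan=False),
        tumor=st.floats(0, 1, allow_nan=False),
    )
    def test_partition_property(self, blood, tumor):
        """Every observation gets exactly one class; tumor-positive records
        are germline, somatic or probable — never absent."""
        origin = classify_origin(record(blood, tumor), CFG)
        assert origin in (GERMLINE, SOMATIC, PROBABLE_MUTATION, ABSENT)
        if tumor > CFG.somatic_tumor_min:
            assert origin != ABSENT

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        blood=st.floats(0, 0.01, allow_nan=False),
        tumor=st.floats(0.02, 1, allow_nan=False),
        bump=st.floats(1.0, 5.0),
    )
    def test_threshold_monotonicity(self, blood, tumor, bump):
        """Raising somatic_normal_max only moves records probable->somatic."""
        lo = ClassificationConfig()
        hi = ClassificationConfig(somatic_normal_max=min(0.009, 0.001 * bump))
        a = classify_origin(record(blood, tumor), lo)
        b = classify_origin(record(blood, tumor), hi)
        if a == SOMATIC:
            assert b == SOMATIC
        if b == PROBABLE_MUTATION:
            assert a == PROBABLE_MUTATION


class TestPloidy:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.50, "heteroplasmic"),
            (0.96, "homoplasmic"),
            (0.95, "homoplasmic"),  # documented boundary decision
            (0.01, "heteroplasmic"),
            (0.0099, "undetected"),
            (0.005, "undetected"),
            (1.0, "homoplasmic"),
            (0.0, "undetected"),
        ],
    )
    def test_step_function(self, maf, expected):
        assert classify_ploidy(maf, CFG) == expected

    def test_range_check(self):
        with pytest.raises(ValidationError):
            classify_ploidy(1.5, CFG)


def make_cohort(records, n_patients=None):
    import pandas as pd

    pids = sorted({r.patient_id for r in records})
    if n_patients:
        pids = [f"P{i:02d}" for i in range(1, n_patients + 1)]
    classified = classify_cohort(records)
    return CohortTable(
        patients=pd.DataFrame({"patient_id": pids}), records=classified
    )


class TestShiftAnalysis:
    def test_uniform_shift(self):
        records = [record(0.10, 0.90, pid=f"P{i:02d}") for i in range(1, 6)]
        cohort = make_cohort(records)
        res = shift_analysis(cohort, VariantKey(663, "A", "G"))
        assert res.n_pairs == 5
        assert np.allclose(res.deltas.values, 0.80, atol=1e-6)
        assert res.n_shift_to_homoplasmy == 0

    def test_null_case(self):
        records = [record(0.30, 0.30, pid=f"P{i:02d}") for i in range(1, 6)]
        cohort = make_cohort(records)
        res = shift_analysis(cohort, VariantKey(663, "A", "G"))
        assert np.allclose(res.deltas.values, 0.0)
        assert res.p_value > 0.9

    def test_shift_to_homoplasmy_flagged(self):
        records = [record(0.10, 0.97, pid="P01"), record(0.12, 0.50, pid="P02")]
        cohort = make_cohort(records)
        res = shift_analysis(cohort, VariantKey(663, "A", "G"))
        assert res.n_shift_to_homoplasmy == 1

    def test_no_carriers_returns_none(self):
        records = [record(0.0, 0.30, pid="P01", pos=100, ref="C", alt="T")]
        cohort = make_cohort(records)
        assert shift_analysis(cohort, VariantKey(663, "A", "G")) is None

    def test_u_statistic_matches_bruteforce_ranks(self):
        """U equals the all-pairs count oracle on a Beta-skewed carrier set."""
        rng = np.random.default_rng(663)
        blood = rng.uniform(0.05, 0.20, size=12)
        tumor = rng.beta(8, 2, size=12)
        u, p, method = mann_whitney_u(blood, tumor)
        brute = sum(
            1.0 if b > t else (0.5 if b == t else 0.0) for b in blood for t in tumor
        )
        assert u == pytest.approx(brute)
        assert method == "asymptotic"

    def test_exact_method_for_small_samples(self):
        u, p, method = mann_whitney_u([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert method == "exact"
        # all 20 arrangements: P(U=0 two-sided) = 2/20
        assert p == pytest.approx(0.1)


class TestRecurrence:
    def test_carrier_counts_and_singletons(self):
        records = [
            record(0.5, 0.5, pid="P01"),
            record(0.5, 0.5, pid="P02"),
            record(0.0, 0.3, pid="P03", pos=100, ref="C", alt="T"),
        ]
        cohort = make_cohort(records, n_patients=92)
        rec = recurrence(cohort)
        germ = rec[rec["origin"] == GERMLINE].iloc[0]
        assert germ["carriers"] == 2
        assert not germ["singleton"]
        assert germ["frequency"] == pytest.approx(2 / 92)
        som = rec[rec["origin"] == SOMATIC].iloc[0]
        assert som["carriers"] == 1
        assert som["singleton"]
        assert som["frequency"] == pytest.approx(1 / 92)

    def test_empty_cohort(self):
        import pandas as pd

        cohort = CohortTable(patients=pd.DataFrame({"patient_id": []}), records=[])
        assert recurrence(cohort).empty
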