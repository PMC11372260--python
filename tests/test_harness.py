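import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import icc2_mean_squares, two_pass_mean_sd
from tmtvbench import (
    CaseRecord,
    ValidationDataError,
    agreement,
    diff_stats,
    flag_discrepancies,
    icc,
    load_discrepant_cases,
    reference_tmtv,
    validate_implementation,
)
from tmtvbench.harness import discrepant_case_records


class TestReferenceTMTV:
    def test_even_count_averages_middle_pair(self):
        assert reference_tmtv([178, 229, 137, 159]) == pytest.approx(168.5)

    def test_odd_count_middle_order_statistic(self):
        assert reference_tmtv([275, 129, 282]) == pytest.approx(275.0)

    def test_identical_values(self):
        assert reference_tmtv([42.0, 42.0, 42.0]) == 42.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            reference_tmtv([100.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1, 3000), min_size=2, max_size=6), st.randoms())
    def test_permutation_invariant_and_bounded(self, values, rnd):
        ref = reference_tmtv(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert reference_tmtv(shuffled) == pytest.approx(ref)
        assert min(values) <= ref <= max(values)


class TestAgreement:
    def test_exact_match_passes_with_zero_diffs(self):
        res = agreement(100.0, 100.0)
        assert res.passed and res.abs_diff == 0 and res.rel_diff == 0

    def test_low_outlier_reader_fails_both_arms(self):
        res = agreement(252.0, 412.5)
        assert res.abs_diff == pytest.approx(160.5)
        assert res.rel_diff == pytest.approx(0.389, abs=1e-3)
        assert not res.passed

    def test_large_case_passes_via_relative_arm(self):
        res = agreement(1650.0, 1665.0)
        assert res.abs_diff == pytest.approx(15.0)  # fails the 10 cm^3 arm
        assert res.rel_diff == pytest.approx(0.009, abs=1e-3)
        assert res.passed

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            agreement(10.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(1, 2000), st.floats(1, 2000), st.floats(0.1, 50), st.floats(0.01, 0.5))
    def test_pass_is_monotone_in_tolerances(self, value, ref, abs_tol, rel_tol):
        base = agreement(value, ref, abs_tol, rel_tol).passed
        wider = agreement(value, ref, abs_tol * 2, rel_tol * 2).passed
        assert wider or not base  # base passing implies wider passing


class TestICC:
    def test_identical_readers_give_one(self):
        m = np.tile(np.array([[100.0], [250.0], [400.0], [90.0]]), (1, 3))
        assert icc(m).icc == pytest.approx(1.0)

    def test_zero_total_variance_defined_as_one(self):
        assert icc(np.full((4, 3), 7.0)).icc == 1.0

    def test_matches_mean_squares_oracle(self, rng):
        m = rng.normal(200, 80, (30, 4)) + rng.normal(0, 20, (30, 1))
        assert icc(m).icc == pytest.approx(icc2_mean_squares(m), abs=1e-9)

    def test_case_order_permutation_invariant(self, rng):
        m = rng.normal(200, 80, (20, 3))
        perm = rng.permutation(20)
        assert icc(m[perm]).icc == pytest.approx(icc(m).icc)

    def test_casewise_deletion_of_missing_readers(self, rng):
        m = rng.normal(200, 80, (20, 4))
        with_nan = m.copy()
        with_nan[3, 2] = np.nan
        expected = icc(np.delete(m, 3, axis=0)).icc
        assert icc(with_nan).icc == pytest.approx(expected)
        assert icc(with_nan).n_cases == 19


class TestDiffStats:
    def test_identical_pairs(self):
        s = diff_stats([100, 200, 300], [100, 200, 300])
        assert s.mean_diff == 0 and s.sd_diff == 0
        assert s.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        s = diff_stats(np.array([105, 205, 305.0]), np.array([100, 200, 300.0]))
        assert s.mean_diff == pytest.approx(5.0) and s.sd_diff == 0.0

    def test_constant_series_flags_r_as_nan(self):
        s = diff_stats([5.0, 5.0, 5.0], [4.0, 6.0, 5.0])
        assert np.isnan(s.pearson_r)

    def test_matches_two_pass_oracle(self, rng):
        v = rng.uniform(10, 2000, 50)
        r = v + rng.normal(0, 30, 50)
        s = diff_stats(v, r)
        mean, sd = two_pass_mean_sd(v - r)
        assert s.mean_diff == pytest.approx(mean, abs=1e-9)
        assert s.sd_diff == pytest.approx(sd, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_stats([1, 2], [1, 2, 3])


class TestFlagDiscrepancies:
    def test_spleen_outlier_case_flagged(self):
        rec = CaseRecord("F05", {"1": 1680, "2": 1706, "3": 1650, "4": 567})
        rep = flag_discrepancies(rec)
        assert rep.reference == pytest.approx(1665.0)
        assert rep.deviations["rel_dev"].max() == pytest.approx(0.659, abs=1e-3)
        assert rep.flagged

    def test_moderate_spread_case_flagged(self):
        rep = flag_discrepancies(CaseRecord("H11", {"1": 178, "2": 229, "3": 137, "4": 159}))
        assert rep.deviations["rel_dev"].max() == pytest.approx(0.359, abs=1e-3)
        assert rep.flagged

    def test_all_equal_not_flagged(self):
        rep = flag_discrepancies(CaseRecord("X", {"1": 100.0, "2": 100.0, "3": 100.0}))
        assert not rep.flagged

    def test_all_published_adjudicated_cases_flagged_at_defaults(self):
        for rec in discrepant_case_records():
            assert flag_discrepancies(rec).flagged, rec.case_id

    def test_relative_rule_alone_catches_all_spleen_cases(self):
        df = load_discrepant_cases()
        spleen = df[df["note_category"] == "spleen"]["case_id"].unique()
        assert len(spleen) == 5
        for rec in discrepant_case_records():
            if rec.case_id in spleen:
                rep = flag_discrepancies(rec, rel_thresh=0.25, abs_thresh=np.inf)
                assert rep.flagged, rec.case_id


class TestValidateImplementation:
    @staticmethod
    def _tables():
        measured = pd.DataFrame(
            {
                "case_id": ["a", "a", "b", "b"],
                "stage": [1, 4, 1, 4],
                "reader_id": ["r"] * 4,
                "tmtv_cm3": [100.0, 90.0, 500.0, 480.0],
            }
        )
        reference = pd.DataFrame(
            {
                "case_id": ["a", "a", "b", "b"],
                "stage": [1, 4, 1, 4],
                "reference_tmtv_cm3": [100.0, 90.0, 500.0, 480.0],
            }
        )
        return measured, reference

    def test_identical_tables_pass_fully(self):
        measured, reference = self._tables()
        rep = validate_implementation(measured, reference)
        assert rep["all_pass"] and rep["pass_fraction"] == 1.0

    def test_single_perturbed_case_is_the_only_failure(self):
        measured, reference = self._tables()
        measured.loc[2, "tmtv_cm3"] *= 1.5
        rep = validate_implementation(measured, reference)
        assert [f["case_id"] for f in rep["failures"]] == ["b"]
        assert rep["per_stage"]["TMTV1"]["n_pass"] == 1
        assert rep["per_stage"]["TMTV4"]["pass_fraction"] == 1.0

    def test_disjoint_keys_rejected(self):
        measured, reference = self._tables()
        reference["case_id"] = ["x", "x", "y", "y"]
        with pytest.raises(ValidationDataError):
            validate_implementation(measured, reference)


def test_packaged_discrepant_table_shape():
    df = load_discrepant_cases()
    assert df["case_id"].nunique() == 8
    counts = df.groupby("case_id")["tmtv_cm3"].count()
    assert set(counts) <= {3, 4}  # cases read by 3 or 4 readers
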