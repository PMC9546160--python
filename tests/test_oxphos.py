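"""Log-ratio metrics, control references, z-bins, subject summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from interneuron_profiler import oxphos as ox
from interneuron_profiler.errors import (
    ClassificationError,
    ControlReferenceError,
    InputError,
)

SEVERITY_ORDER = {c: i for i, c in enumerate(ox.EXPRESSION_CATEGORIES)}


def _cells(**cols):
    defaults = {"i_ndufb8": 200.0, "i_coxi": 200.0, "i_porin": 200.0,
                "i_cbp": 200.0}
    defaults.update(cols)
    return pd.DataFrame([defaults])


class TestComputeRatios:
    def test_equal_intensities_give_unit_ratio(self):
        out = ox.compute_ratios(_cells(i_ndufb8=200.0, i_porin=200.0))
        assert out.loc[0, "r_ndufb8"] == 1.0

    def test_log_power_identity(self):
        # NDUFB8 = porin² on the raw scale -> ratio of logs is 2
        out = ox.compute_ratios(_cells(i_ndufb8=400.0, i_porin=20.0))
        assert np.isclose(out.loc[0, "r_ndufb8"], 2.0, rtol=1e-14)

    def test_direct_log_evaluation(self):
        out = ox.compute_ratios(_cells(i_ndufb8=200.0, i_porin=400.0))
        assert np.isclose(out.loc[0, "r_ndufb8"],
                          np.log(200.0) / np.log(400.0), rtol=1e-14)

    def test_log_of_ratio_mode(self):
        out = ox.compute_ratios(_cells(i_ndufb8=100.0, i_porin=400.0),
                                ratio_mode="log_of_ratio")
        assert np.isclose(out.loc[0, "r_ndufb8"], np.log(100.0 / 400.0))

    def test_guarded_cell_flagged_not_dropped(self):
        out = ox.compute_ratios(_cells(i_porin=0.0))
        assert len(out) == 1
        assert bool(out.loc[0, "excluded"])
        assert "i_porin" in out.loc[0, "exclusion_reason"]
        assert np.isnan(out.loc[0, "r_ndufb8"])

    def test_missing_column_rejected(self):
        with pytest.raises(InputError):
            ox.compute_ratios(pd.DataFrame({"i_ndufb8": [1.0]}))


class TestReferenceAndZ:
    def test_hand_computed_sample_sd(self):
        ref = ox.build_reference([0.9, 1.0, 1.1])
        assert np.isclose(ref.mean, 1.0, rtol=1e-14)
        assert np.isclose(ref.sd, 0.1, rtol=1e-12)
        assert ref.n == 3

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ControlReferenceError):
            ox.build_reference([1.0, 1.0, 1.0], region="occipital",
                               subtype="pv", metric="r_ndufb8")

    def test_single_cell_rejected(self):
        with pytest.raises(ControlReferenceError):
            ox.build_reference([1.0])

    @pytest.mark.parametrize("value, expected", [
        (1.0, 0.0),       # value = mean
        (1.2, 2.0),       # mean + 2 sd
        (0.85, -1.5),     # direct arithmetic
    ])
    def test_zscore_arithmetic(self, value, expected):
        ref = ox.ControlReference("", "", "", mean=1.0, sd=0.1, n=10)
        assert np.isclose(ox.zscore(value, ref), expected, rtol=1e-12)


class TestClassifyExpression:
    @pytest.mark.parametrize("z, category", [
        (-4.2, "severe_deficiency"),
        (-4.0, "severe_deficiency"),   # boundary to the extreme side
        (-3.5, "deficiency"),
        (-3.0, "deficiency"),
        (-2.5, "low"),
        (-2.0, "low"),
        (0.0, "normal"),
        (1.99, "normal"),
        (2.0, "increased"),
        (2.5, "increased"),
    ])
    def test_bin_assignment(self, z, category):
        assert ox.classify_expression(z) == category

    def test_nonfinite_rejected(self):
        with pytest.raises(ClassificationError):
            ox.classify_expression(np.nan)

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_every_finite_z_gets_exactly_one_category(self, z):
        assert ox.classify_expression(z) in ox.EXPRESSION_CATEGORIES

    @given(st.floats(min_value=-20, max_value=0, allow_nan=False),
           st.floats(min_value=0.001, max_value=5, allow_nan=False))
    def test_monotone_in_ndufb8_intensity(self, z, step):
        """Lowering NDUFB8 (porin fixed) never looks less deficient."""
        ref = ox.ControlReference("", "", "", mean=1.0, sd=0.05, n=10)
        porin = 200.0
        # invert z -> intensity, then lower the intensity by `step` in z
        hi = ox.classify_expression(z)
        lo = ox.classify_expression(z - step)
        assert SEVERITY_ORDER[lo] <= SEVERITY_ORDER[hi]
        # and on the raw-intensity path
        r_hi = ref.mean + z * ref.sd
        i_hi = np.exp(r_hi * np.log(porin))
        i_lo = i_hi * 0.9
        out = ox.compute_ratios(pd.DataFrame({
            "i_ndufb8": [i_hi, i_lo], "i_coxi": [100.0, 100.0],
            "i_porin": [porin, porin], "i_cbp": [100.0, 100.0]}))
        z_pair = ox.zscore(out["r_ndufb8"], ref)
        cats = [ox.classify_expression(v) for v in z_pair]
        assert SEVERITY_ORDER[cats[1]] <= SEVERITY_ORDER[cats[0]]


class TestControlSelfCalibration:
    def test_control_z_standardised_against_own_reference(self, classified_cells):
        ctrl = classified_cells[classified_cells["group"] == "control"]
        for metric in ("ndufb8", "coxi"):
            for (_, _), grp in ctrl.groupby(["region", "subtype"]):
                z = grp[f"z_{metric}"]
                assert abs(z.mean()) < 1e-10
                assert np.isclose(z.std(ddof=1), 1.0, rtol=1e-10)


class TestSummaries:
    def _classified(self, cats):
        n = len(cats)
        return pd.DataFrame({
            "subject": ["P01"] * n, "group": ["alpers"] * n,
            "region": ["occipital"] * n, "subtype": ["pv"] * n,
            "excluded": [False] * n,
            "cat_ndufb8": cats, "cat_coxi": cats,
            "cat_log_porin": ["normal"] * n, "cat_log_cbp": ["normal"] * n,
        })

    def test_unanimous_severe(self):
        summary = ox.summarize_subject(
            self._classified(["severe_deficiency"] * 10))
        row = summary[summary["metric"] == "r_ndufb8"].iloc[0]
        assert row["severe_deficiency"] == 1.0
        assert row["n_cells"] == 10

    def test_proportions_sum_to_one(self, classified_cells):
        summary = ox.summarize_subject(classified_cells)
        totals = summary[list(ox.EXPRESSION_CATEGORIES)].sum(axis=1)
        assert np.allclose(totals[summary["n_cells"] > 0], 1.0)

    def test_empty_input_gives_empty_summary(self):
        assert len(ox.summarize_subject(self._classified([]).iloc[:0])) == 0

    def test_planted_mixture_recovered_at_large_n(self, classified_cells):
        """Severe fractions track the generator mixture at cohort scale."""
        pv = classified_cells[(classified_cells["group"] == "alpers")
                              & (classified_cells["subtype"] == "pv")]
        frac = (pv["cat_ndufb8"] == "severe_deficiency").mean()
        planted = 0.60
        tol = 3 * np.sqrt(planted * (1 - planted) / len(pv)) + 0.01
        assert abs(frac - planted) < tol


def test_per_subject_reference_mode_runs(classified_cells):
    refs = ox.build_references(classified_cells, pool="per-subject")
    assert all(r.n == 9 for r in refs.values())  # 9 control subjects
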