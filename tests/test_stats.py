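"""Cohort selection, the two linear models, slope ratios and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import structage as sa
from structage.stats import (
    CONVERSION_GROUPS,
    ModelFit,
    ScanRecord,
    aging_slope_percent,
    fdr_correct,
    fit_cross_sectional,
    fit_longitudinal,
    records_to_frame,
    select_longitudinal_cohort,
)


def scan_row(sid, scan, age, diag, delta, pa):
    return dict(
        subject_id=sid, scan_id=scan, age_at_scan=age, diagnosis=diag,
        delta_scan=delta, pa_x=pa,
    )


def longitudinal_frame(
    n_per_group=20,
    slopes=(1.0, 1.1, 1.3),
    offsets=(0.0, 0.0, 0.0),
    sd_int=0.0,
    sd_slope=0.0,
    sd_resid=0.0,
    seed=0,
    times=(0.0, 1.5, 3.0),
):
    rng = np.random.default_rng(seed)
    rows, groups = [], []
    k = 0
    for gi, grp in enumerate(CONVERSION_GROUPS):
        for _ in range(n_per_group):
            sid = f"s{k:04d}"
            a0 = rng.uniform(60, 80)
            u0 = rng.normal(0, sd_int) if sd_int else 0.0
            u1 = rng.normal(0, sd_slope) if sd_slope else 0.0
            for j, d in enumerate(times):
                pa = (
                    5.0 + 0.9 * a0 + offsets[gi] + slopes[gi] * d
                    + u0 + u1 * d
                    + (rng.normal(0, sd_resid) if sd_resid else 0.0)
                )
                rows.append(scan_row(sid, f"{sid}_{j}", a0 + d, "healthy", d, pa))
            groups.append((sid, grp))
            k += 1
    return pd.DataFrame(rows), pd.DataFrame(groups, columns=["subject_id", "group"])


class TestScanRecord:
    def test_frame_conversion(self):
        recs = [
            ScanRecord("s1", "s1_0", 70.0, "healthy", 0.0, {"pa_hippo": 72.0}),
            ScanRecord("s1", "s1_1", 72.0, "MCI", 2.0, {"pa_hippo": 76.0}),
        ]
        df = records_to_frame(recs)
        assert list(df["pa_hippo"]) == [72.0, 76.0]

    def test_invalid_diagnosis_and_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            ScanRecord("s", "s0", 70.0, "demented", 0.0)
        with pytest.raises(ValueError):
            ScanRecord("s", "s0", 70.0, "healthy", -1.0)


class TestCohortSelection:
    def test_selection_rules(self):
        df = pd.DataFrame(
            [
                # healthy at 68, healthy at 72 -> non-converter
                scan_row("a", "a0", 68, "healthy", 0, 70),
                scan_row("a", "a1", 72, "healthy", 4, 74),
                # single scan -> excluded
                scan_row("b", "b0", 75, "healthy", 0, 75),
                # baseline MCI -> excluded even though later ADD
                scan_row("c", "c0", 68, "MCI", 0, 75),
                scan_row("c", "c1", 72, "ADD", 4, 80),
                # last scan under 70 -> excluded
                scan_row("d", "d0", 60, "healthy", 0, 60),
                scan_row("d", "d1", 64, "MCI", 4, 68),
                # healthy -> ADD at 74 -> ADD converter
                scan_row("e", "e0", 70, "healthy", 0, 72),
                scan_row("e", "e1", 74, "ADD", 4, 80),
            ]
        )
        sel = select_longitudinal_cohort(df).set_index("subject_id")["group"]
        assert sel.to_dict() == {"a": "non_converter", "e": "ADD_converter"}

    def test_selection_is_order_invariant_pure_filter(self):
        df, _ = longitudinal_frame(n_per_group=5, seed=1)
        shuffled = df.sample(frac=1.0, random_state=3)
        a = select_longitudinal_cohort(df).sort_values("subject_id")
        b = select_longitudinal_cohort(shuffled).sort_values("subject_id")
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
        assert set(a["subject_id"]) <= set(df["subject_id"])


class TestCrossSectional:
    @staticmethod
    def baseline_frame(n=300, beta=(5.0, 0.9, 3.0, 7.0), sd=0.0, seed=0, permute=False):
        rng = np.random.default_rng(seed)
        age = rng.uniform(50, 90, n)
        diag = np.array(["healthy", "MCI", "ADD"])[rng.integers(0, 3, n)]
        if permute:
            diag = rng.permutation(diag)
        pa = (
            beta[0] + beta[1] * age
            + np.where(diag == "MCI", beta[2], 0.0)
            + np.where(diag == "ADD", beta[3], 0.0)
            + rng.normal(0, sd, n)
        )
        return pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(n)],
                scan_id=[f"s{i}_0" for i in range(n)],
                age_at_scan=age, diagnosis=diag, delta_scan=0.0, pa_x=pa,
            )
        )

    def test_noiseless_coefficients_exact(self):
        df = self.baseline_frame()
        fit = fit_cross_sectional(df, ["pa_x"])["pa_x"]
        assert fit.coef("intercept") == pytest.approx(5.0, abs=1e-6)
        assert fit.coef("age") == pytest.approx(0.9, abs=1e-6)
        assert fit.coef("MCI") == pytest.approx(3.0, abs=1e-6)
        assert fit.coef("ADD") == pytest.approx(7.0, abs=1e-6)

    def test_missing_diagnosis_level_named_in_error(self):
        df = self.baseline_frame()
        df = df[df["diagnosis"] != "ADD"]
        with pytest.raises(ValueError, match="ADD"):
            fit_cross_sectional(df, ["pa_x"])

    def test_duplicate_subjects_rejected(self):
        df = self.baseline_frame(n=30)
        dup = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(ValueError, match="one scan per subject"):
            fit_cross_sectional(dup, ["pa_x"])

    def test_amygdala_scale_offsets_recovered_within_ci(self):
        """One replicate of the diagnosed-cohort simulation: +3.5 / +8.0
        year offsets, residual SD 4, n = 1000."""
        df = self.baseline_frame(n=1000, beta=(5.0, 0.9, 3.5, 8.0), sd=4.0, seed=7)
        fit = fit_cross_sectional(df, ["pa_x"])["pa_x"]
        for term, truth in (("MCI", 3.5), ("ADD", 8.0)):
            row = fit.coefficients.query("term == @term").iloc[0]
            assert row["ci_low"] <= truth <= row["ci_high"]


class TestLongitudinal:
    def test_noiseless_slopes_exact(self):
        df, groups = longitudinal_frame()
        fit = fit_longitudinal(df, groups, ["pa_x"])["pa_x"]
        assert fit.group_slopes["non_converter"] == pytest.approx(1.0, abs=1e-6)
        assert fit.group_slopes["MCI_converter"] == pytest.approx(1.1, abs=1e-6)
        assert fit.group_slopes["ADD_converter"] == pytest.approx(1.3, abs=1e-6)

    def test_converter_intercept_offset_recovered(self):
        """+2-year converter effect appears as the group intercept offset."""
        df, groups = longitudinal_frame(
            n_per_group=40, offsets=(0.0, 2.0, 2.0),
            sd_int=1.0, sd_slope=0.05, sd_resid=0.5, seed=9,
        )
        fit = fit_longitudinal(df, groups, ["pa_x"])["pa_x"]
        for term in ("offset_MCI_converter", "offset_ADD_converter"):
            row = fit.coefficients.query("term == @term").iloc[0]
            assert row["ci_low"] <= 2.0 <= row["ci_high"]

    def test_random_effect_variances_reported(self):
        df, groups = longitudinal_frame(
            n_per_group=40, sd_int=3.0, sd_slope=0.2, sd_resid=1.5, seed=2
        )
        fit = fit_longitudinal(df, groups, ["pa_x"])["pa_x"]
        assert fit.random_effect_variances["intercept"] > 0
        assert fit.residual_variance > 0

    def test_single_scan_subject_rejected(self):
        df, groups = longitudinal_frame(n_per_group=5)
        df = df[~((df.subject_id == "s0000") & (df.delta_scan > 0))]
        with pytest.raises(ValueError, match=">= 2"):
            fit_longitudinal(df, groups, ["pa_x"])


class TestAgingSlopePercent:
    @staticmethod
    def fit_with(slopes):
        return ModelFit(
            structure="x", kind="longitudinal",
            coefficients=pd.DataFrame(), group_slopes=slopes,
        )

    def test_quarter_faster(self):
        f = self.fit_with(
            {"non_converter": 2.0, "MCI_converter": 2.5, "ADD_converter": 2.0}
        )
        assert aging_slope_percent(f)["MCI_converter"] == pytest.approx(25.0)

    def test_equal_slopes_are_zero_percent(self):
        f = self.fit_with(
            {"non_converter": 1.5, "MCI_converter": 1.5, "ADD_converter": 1.5}
        )
        assert aging_slope_percent(f)["ADD_converter"] == pytest.approx(0.0)

    def test_signed_percent_convention(self):
        f = self.fit_with(
            {"non_converter": 1.0, "MCI_converter": 1.0, "ADD_converter": 0.968}
        )
        assert aging_slope_percent(f)["ADD_converter"] == pytest.approx(-3.2)

    def test_zero_reference_slope_rejected(self):
        f = self.fit_with(
            {"non_converter": 0.0, "MCI_converter": 1.0, "ADD_converter": 1.0}
        )
        with pytest.raises(ZeroDivisionError):
            aging_slope_percent(f)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_stepup_hand_example(self):
        # min_{j>=i} p_(j) * m / j: all four collapse to 0.04
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        adjusted = fdr_correct(p)
        adjusted_perm = fdr_correct(p[perm])
        np.testing.assert_allclose(adjusted_perm[np.argsort(perm)], adjusted)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 40)
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_stepup_properties_hold_for_arbitrary_inputs(self, p):
        """Adjusted values never fall below raw, never exceed 1, and are
        monotone in the order statistics (step-up shape)."""
        p = np.asarray(p)
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
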