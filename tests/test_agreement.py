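"""Agreement statistics: closed-form oracles and distributional properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from biswater import (
    bland_altman,
    frequency_sweep,
    lin_ccc,
    mape,
    method_agreement,
    pearson_r,
    see,
    stratified_report,
)


class TestPearson:
    def test_identity_and_antilinearity(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # r = 3 / sqrt(2 * 14/3)
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981981, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestLinCCC:
    def test_identity(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_value_with_n_divisor(self):
        # shift by 1: 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-12)

    def test_shift_lowers_ccc_but_not_pearson(self):
        x = np.array([3.0, 5.0, 9.0, 12.0])
        y = x + 2.5
        assert pearson_r(x, y) == pytest.approx(1.0)
        assert lin_ccc(x, y) < 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.data(),
    )
    def test_ccc_bounded_by_pearson(self, xs, data):
        ys = data.draw(
            st.lists(st.floats(-100, 100), min_size=len(xs), max_size=len(xs))
        )
        x, y = np.array(xs), np.array(ys)
        if np.var(x) < 1e-9 or np.var(y) < 1e-9:
            return
        assert abs(lin_ccc(x, y)) <= abs(pearson_r(x, y)) + 1e-12


class TestSEE:
    def test_perfect_line_gives_zero(self):
        pred = np.array([30.0, 40.0, 50.0])
        assert see(2 * pred + 1, pred) == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_residual(self):
        pred = np.array([1.0, 2.0, 3.0])
        ref = np.array([1.0, 2.0, 4.0])  # slope 1.5, intercept -2/3
        fitted = 1.5 * pred - 2 / 3
        expected = np.sqrt(np.sum((ref - fitted) ** 2) / 1)
        assert see(ref, pred) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(40, 5, 50)
        ref = pred + rng.normal(0, 2, 50)
        assert see(ref + 7, pred + 7) == pytest.approx(see(ref, pred), rel=1e-9)


class TestBlandAltman:
    def test_perfect_agreement(self):
        ref = np.array([30.0, 40.0, 50.0])
        ba = bland_altman(ref, ref)
        assert ba.bias_l == 0 and ba.sd_l == 0 and ba.loa_l == (0.0, 0.0)

    def test_hand_values_absolute_and_percent(self):
        # d = (2, -5); %d = (5, -10)  [n=2 below the precondition, so extend]
        ref = np.array([40.0, 50.0, 40.0, 50.0])
        pred = np.array([38.0, 55.0, 38.0, 55.0])
        ba = bland_altman(ref, pred)
        assert ba.bias_l == pytest.approx(-1.5)
        assert ba.bias_pct == pytest.approx(-2.5)

    def test_loa_is_exactly_bias_pm_2sd(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(40, 8, 100)
        pred = ref + rng.normal(1, 2, 100)
        ba = bland_altman(ref, pred)
        assert ba.loa_l[0] == pytest.approx(ba.bias_l - 2 * ba.sd_l, rel=1e-12)
        assert ba.loa_l[1] == pytest.approx(ba.bias_l + 2 * ba.sd_l, rel=1e-12)
        assert ba.loa_l[1] - ba.loa_l[0] == pytest.approx(4 * ba.sd_l, rel=1e-12)

    def test_trend_detects_volume_dependent_error(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(40, 8, 200)
        pred = ref - 0.3 * (ref - 40) + rng.normal(0, 0.5, 200)
        ba = bland_altman(ref, pred)
        assert ba.trend_r > 0.9
        assert ba.trend_p < 1e-6


class TestMape:
    def test_hand_value(self):
        m, sd, ci = mape([40.0, 50.0], [38.0, 55.0], n_boot=200, seed=0)
        assert m == pytest.approx(7.5)
        assert sd == pytest.approx(2.5)
        assert ci[0] <= m <= ci[1]

    def test_permutation_invariance(self):
        ref = np.array([40.0, 50.0, 45.0, 60.0])
        pred = np.array([38.0, 55.0, 44.0, 58.0])
        perm = [2, 0, 3, 1]
        m1, sd1, _ = mape(ref, pred, n_boot=50, seed=1)
        m2, sd2, _ = mape(ref[perm], pred[perm], n_boot=50, seed=1)
        assert m1 == pytest.approx(m2) and sd1 == pytest.approx(sd2)

    def test_mape_at_least_abs_bias_pct(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(40, 8, 100)
        pred = ref + rng.normal(1, 3, 100)
        ba = bland_altman(ref, pred)
        m, _, _ = mape(ref, pred, n_boot=50, seed=0)
        assert m >= abs(ba.bias_pct) - 1e-12

    def test_bootstrap_ci_coverage(self):
        """CI of the mean covers the population MAPE ~95% of the time."""
        rng = np.random.default_rng(7)
        # |N(0, 5)| percentage errors: population mean = 5*sqrt(2/pi)
        true_mape = 5.0 * np.sqrt(2 / np.pi)
        hits = 0
        n_cohorts = 200
        for i in range(n_cohorts):
            ref = np.full(60, 40.0)
            pred = ref * (1 + rng.normal(0, 0.05, 60))
            _, _, (lo, hi) = mape(ref, pred, n_boot=200, seed=i)
            hits += lo <= true_mape <= hi
        coverage = hits / n_cohorts
        assert 0.88 <= coverage <= 0.99


class TestStratifiedReport:
    @staticmethod
    def _predictions(n=500, seed=21, male_offset_l=0.0):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        ref = rng.normal(40, 8, n)
        pred = ref + rng.normal(0, 1.5, n)
        pred = np.where(sex == "male", pred - male_offset_l, pred)
        return pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(n)],
                "sex": sex,
                "method": "sun",
                "tbw_pred_l": pred,
                "tbw_reference_l": ref,
            }
        )

    def test_injected_male_bias_recovered(self):
        df = self._predictions(male_offset_l=2.0)
        report = stratified_report(df, n_boot=100, seed=0)
        male = report[(report.stratum == "male")].iloc[0]
        female = report[(report.stratum == "female")].iloc[0]
        se_m = male.sd_l / np.sqrt(male.n)
        se_f = female.sd_l / np.sqrt(female.n)
        assert abs(male.bias_l - 2.0) < 3 * se_m
        assert abs(female.bias_l) < 3 * se_f

    def test_stratum_ns_sum_to_pooled(self):
        report = stratified_report(self._predictions(n=80), n_boot=50, seed=0)
        pooled = report[report.stratum == "pooled"].iloc[0]
        assert (
            report[report.stratum.isin(["male", "female"])].n.sum() == pooled.n
        )

    def test_single_sex_stratum_equals_pooled(self):
        df = self._predictions(n=60)
        df["sex"] = "female"
        report = stratified_report(df, n_boot=50, seed=0)
        pooled = report[report.stratum == "pooled"].iloc[0]
        female = report[report.stratum == "female"].iloc[0]
        assert female.bias_l == pytest.approx(pooled.bias_l)
        assert female.mape_pct == pytest.approx(pooled.mape_pct)

    def test_missing_predictions_dropped_per_method(self):
        df = self._predictions(n=30)
        df.loc[:4, "tbw_pred_l"] = np.nan
        report = stratified_report(df, n_boot=50, seed=0)
        assert report[report.stratum == "pooled"].iloc[0].n == 25


class TestFrequencySweep:
    def test_affine_tbw_in_quotient_gives_unit_correlation(self, clean_cohort):
        sub = clean_cohort[:30]
        heights = [r.subject.height_cm for r in sub]
        spectra = [r.spectrum for r in sub]
        fits = [r.truth.cole for r in sub]
        # construct TBW as an exact affine function of H^2/Rinf
        quot_inf = np.array(
            [r.subject.height_cm**2 / r.truth.cole.rinf_ohm for r in sub]
        )
        tbw = 0.5 * quot_inf + 3.0
        ecw = [r.truth.ecw_l for r in sub]
        sweep = frequency_sweep(heights, spectra, fits, tbw, ecw)
        assert sweep.r_tbw_inf == pytest.approx(1.0, abs=1e-9)

    def test_compartment_frequency_ordering(self, noisy_cohort):
        heights = [r.subject.height_cm for r in noisy_cohort]
        spectra = [r.spectrum for r in noisy_cohort]
        fits = [r.truth.cole for r in noisy_cohort]
        tbw = [r.reference.tbw_dilution_l for r in noisy_cohort]
        ecw = [r.reference.ecw_dilution_l for r in noisy_cohort]
        sweep = frequency_sweep(heights, spectra, fits, tbw, ecw)
        # ECW peaks in the low-frequency band (below ~0.75 fc for the
        # generator's fc ~ 40 kHz), TBW at the top of the measured band.
        assert sweep.argmax_ecw_hz < 30e3
        assert sweep.argmax_tbw_hz > 100e3
        assert sweep.argmax_ecw_hz < sweep.argmax_tbw_hz
        table = sweep.to_frame()
        assert table.frequency_hz.iloc[0] == 0.0
        assert np.isinf(table.frequency_hz.iloc[-1])
        assert (table[["r_tbw", "r_ecw"]].abs() <= 1.0 + 1e-12).all().all()

    def test_too_few_subjects_rejected(self, clean_cohort):
        rec = clean_cohort[0]
        with pytest.raises(ValueError, match=">= 3"):
            frequency_sweep(
                [rec.subject.height_cm],
                [rec.spectrum],
                [rec.truth.cole],
                [rec.truth.tbw_l],
                [rec.truth.ecw_l],
            )


class TestMethodAgreement:
    def test_invariants_hold_on_random_data(self):
        rng = np.random.default_rng(33)
        ref = rng.normal(40, 8, 120)
        pred = 0.9 * ref + rng.normal(2, 2, 120)
        ma = method_agreement("sun", ref, pred, n_boot=100, seed=0)
        assert abs(ma.lin_ccc) <= abs(ma.pearson_r) <= 1
        assert ma.mape_pct >= abs(ma.bias_pct) - 1e-12
        assert ma.loa_l == pytest.approx(
            (ma.bias_l - 2 * ma.sd_l, ma.bias_l + 2 * ma.sd_l)
        )
        assert ma.sd_l >= 0 and ma.mape_pct >= 0
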