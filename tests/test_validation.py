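import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftirquant import (
    CalibrationModel,
    DerivativeConfig,
    BandWindow,
    PrecisionLevel,
    Rounding,
    SigmaDefinition,
    build_report,
    fit_calibration,
    first_derivative,
    lod,
    loq,
    mean_recovery,
    precision_summary,
    recovery,
    report_value,
    robustness_rsd,
    selectivity_score,
    simulate_spectrum,
    simulate_tablet_spectrum,
)
from ftirquant.validation import LOQ_LOD_RATIO


def model(sigma, slope=1.375):
    return CalibrationModel(slope=slope, intercept=0.0, r_squared=1.0, residual_sigma=sigma)


class TestDetectionLimits:
    def test_published_lod_loq_from_implied_sigma(self, table_model):
        # σ implied by the printed LOD via 3.3σ/S = 0.052757 with S = 1.375
        assert lod(table_model) == pytest.approx(0.052757, abs=5e-7)
        assert loq(table_model) == pytest.approx(0.159869, abs=1e-6)

    @pytest.mark.parametrize("sigma,expected", [(0.0, 0.0), (1.375 / 3.3, 1.0)])
    def test_closed_forms(self, sigma, expected):
        assert lod(model(sigma)) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(sigma=st.floats(1e-6, 1.0), slope=st.floats(1e-3, 10.0))
    def test_loq_lod_ratio_is_exact(self, sigma, slope):
        m = model(sigma, slope)
        assert loq(m) / lod(m) == pytest.approx(LOQ_LOD_RATIO, abs=1e-9)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            lod(model(0.01, slope=-1.0))

    def test_intercept_sigma_matches_ols_standard_error(self):
        # independent oracle: the intercept standard error from the OLS
        # formula σ·sqrt(Σx²/(n·Σ(x−x̄)²)) must equal linregress's value
        from scipy import stats

        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        y = 1.375 * x - 0.014 + np.array([0.01, -0.02, 0.005, 0.01, -0.005])
        m = fit_calibration(list(zip(x, y)))
        res = stats.linregress(x, y)
        got = lod(m, sigma_definition=SigmaDefinition.INTERCEPT)
        assert got == pytest.approx(3.3 * res.intercept_stderr / m.slope, rel=1e-9)

    def test_explicit_blank_sigma(self):
        m = model(0.5)
        assert lod(m, sigma_definition="explicit", sigma=0.1) == pytest.approx(0.33 / 1.375)


class TestRecovery:
    @pytest.mark.parametrize(
        "claimed,measured,expected",
        [(0.5, 0.499, 99.80), (0.511, 0.517, 101.17), (0.511, 0.505, 98.82), (0.514, 0.505, 98.24)],
    )
    def test_reported_cells_under_truncation(self, claimed, measured, expected):
        assert recovery(claimed, measured).reported() == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(0.01, 10.0))
    def test_identity_recovery_is_100(self, c):
        assert recovery(c, c).reported() == pytest.approx(100.00)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 2.0), b=st.floats(0.01, 2.0), k=st.floats(0.1, 10.0))
    def test_scale_invariance(self, a, b, k):
        assert recovery(k * a, k * b).recovery_pct == pytest.approx(
            recovery(a, b).recovery_pct, rel=1e-9
        )

    def test_nonpositive_claim_rejected(self):
        with pytest.raises(ValueError, match="claimed"):
            recovery(0.0, 0.5)

    def test_mean_of_brand_c_replicates(self):
        assert mean_recovery([98.24, 99.41, 100.58]) == pytest.approx(99.41)

    def test_mean_of_brand_a_replicates(self):
        # the three printed replicates average to 99.80 (not the printed 99.81)
        assert mean_recovery([98.82, 99.41, 101.17]) == pytest.approx(99.80)

    def test_mean_permutation_invariant_and_single(self):
        vals = [98.2, 101.3, 99.9]
        assert mean_recovery(vals) == mean_recovery(vals[::-1])
        assert mean_recovery([recovery(0.5, 0.499)]) == pytest.approx(99.80)
        with pytest.raises(ValueError):
            mean_recovery([])

    def test_rounding_modes(self):
        assert report_value(98.8258, Rounding.TRUNCATE2) == pytest.approx(98.82)
        assert report_value(98.8258, Rounding.ROUND2) == pytest.approx(98.83)
        assert report_value(98.8258, Rounding.FULL) == 98.8258
        assert report_value(-1.239, Rounding.TRUNCATE2) == pytest.approx(-1.23)


class TestPrecision:
    def test_constant_readings(self):
        p = precision_summary([5, 5, 5], "intra_day")
        assert p.sd == 0.0 and p.rsd_pct == 0.0 and p.level is PrecisionLevel.INTRA_DAY

    def test_hand_computed_sample_sd(self):
        p = precision_summary([1, 2, 3], PrecisionLevel.INTER_DAY)
        assert p.mean == pytest.approx(2.0)
        assert p.sd == pytest.approx(1.0)
        assert p.rsd_pct == pytest.approx(50.0)

    def test_two_point_closed_form(self):
        p = precision_summary([2, 4], "intra_day")
        assert p.mean == pytest.approx(3.0)
        assert p.sd == pytest.approx(np.sqrt(2))
        assert p.rsd_pct == pytest.approx(100 * np.sqrt(2) / 3, abs=5e-3)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(0.1, 100.0))
    def test_rsd_is_scale_free(self, k):
        base = [0.63, 0.65, 0.68, 0.64]
        assert precision_summary([k * v for v in base], "intra_day").rsd_pct == pytest.approx(
            precision_summary(base, "intra_day").rsd_pct, rel=1e-9
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="≥ 2"):
            precision_summary([1.0], "intra_day")
        assert precision_summary([-1.0, 1.0], "intra_day").rsd_pct is None


class TestSelectivity:
    def test_self_difference_is_zero(self, noiseless_profile):
        api, _ = simulate_spectrum(noiseless_profile.without_excipients(), 0.5)
        d = first_derivative(api)
        assert selectivity_score(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_grids_rejected(self, noiseless_profile):
        from dataclasses import replace

        a, _ = simulate_spectrum(noiseless_profile.without_excipients(), 0.5)
        b, _ = simulate_spectrum(
            replace(noiseless_profile, grid=(700.0, 2000.0, 2.0)).without_excipients(), 0.5
        )
        with pytest.raises(ValueError, match="grid"):
            selectivity_score(first_derivative(a), first_derivative(b))

    def test_raw_channel_rejected(self, noiseless_profile):
        a, _ = simulate_spectrum(noiseless_profile.without_excipients(), 0.5)
        with pytest.raises(ValueError, match="derivative"):
            selectivity_score(a, a)

    def test_concentration_ratio_scaling(self, noiseless_profile):
        from dataclasses import replace

        # flat baseline: its drift is concentration-independent and would
        # otherwise leak into the scaled difference
        std = replace(noiseless_profile, baseline_slope=0.0).without_excipients()
        api, _ = simulate_spectrum(std, 0.4)
        double, _ = simulate_spectrum(std, 0.8)
        da, dd = first_derivative(api), first_derivative(double)
        assert selectivity_score(da, dd, concentration_ratio=2.0) == pytest.approx(0.0, abs=1e-9)


class TestRobustnessAndReport:
    def test_robustness_rsd_small_under_mild_perturbations(self, noiseless_profile):
        tablet, _ = simulate_tablet_spectrum(noiseless_profile, 0.5)
        series_pts = []
        from ftirquant import band_area, generate_calibration_series

        for c, s in generate_calibration_series(noiseless_profile):
            series_pts.append((c, band_area(first_derivative(s))))
        m = fit_calibration(series_pts)
        variants = [
            (DerivativeConfig(window_points=w), BandWindow(1550 + d, 1605 + d))
            for w in (7, 9, 11)
            for d in (-2.0, 0.0, 2.0)
        ]
        p = robustness_rsd(tablet, m, variants)
        assert p.rsd_pct is not None and p.rsd_pct < 5.0

    def test_report_assembly_and_rendering(self, table_model):
        report = build_report(
            table_model,
            recoveries={
                "A": [(0.511, 0.505), (0.511, 0.508), (0.511, 0.517)],
                "C": [(0.514, 0.505), (0.514, 0.511), (0.511, 0.514)],
            },
            precision_readings={("A", "intra_day"): [0.63, 0.65, 0.64]},
            selectivity=0.004,
        )
        assert report.loq / report.lod == pytest.approx(LOQ_LOD_RATIO, abs=1e-9)
        assert report.mean_recovery_pct["C"] == pytest.approx(99.41)
        text = report.render()
        assert "98.82" in text and "99.41" in text and "0.052757" in text
        assert "selective" in text

    def test_interferent_flagged_non_selective(self, table_model):
        report = build_report(table_model, selectivity=0.31)
        assert not report.selectivity["selective"]
        assert "NON-SELECTIVE" in report.render()

    def test_empty_sections_omitted(self, table_model):
        text = build_report(table_model).render()
        assert "Accuracy" not in text and "Precision" not in text
        assert "Selectivity" not in text
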