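"""Stern-Volmer, LOD, Job's-plot and the scalar sensing helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchkit.sensing import (
    DomainError,
    FitError,
    JobPlot,
    JobSeries,
    LODCalibration,
    SternVolmer,
    TitrationSeries,
    detection_limit,
    dilution_corrected_conc,
    job_analyze,
    quenching_efficiency,
    reversibility_index,
    selectivity_panel,
    stern_volmer_fit,
)
from quenchkit.simulate import (
    BindingSimSpec,
    QuenchSimSpec,
    simulate_job_series,
    simulate_lod_calibration,
    simulate_titration,
)

KSV = 6.52e6  # M^-1, the magnitude of the reported quenching constant
Q_GRID = np.linspace(0.0, 1e-6, 10)


class TestSternVolmer:
    def test_exact_recovery_noiseless(self):
        t = simulate_titration(
            QuenchSimSpec(mechanism="dynamic_SV", seed=0, ksv=KSV), Q_GRID
        )
        for fix in (False, True):
            res = stern_volmer_fit(t, fix_intercept=fix)
            assert res.ksv == pytest.approx(KSV, rel=1e-10)
            assert res.intercept == pytest.approx(1.0, abs=1e-9)
            assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_constant_intensity_gives_zero_ksv(self):
        t = TitrationSeries(Q_GRID, np.full(Q_GRID.size, 500.0), i0=500.0)
        res = stern_volmer_fit(t)
        assert res.ksv == pytest.approx(0.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0)

    def test_noisy_recovery_within_ten_percent(self):
        t = simulate_titration(
            QuenchSimSpec(mechanism="dynamic_SV", seed=7, ksv=KSV,
                          i0=1000.0, noise_sd=10.0),
            Q_GRID,
        )
        res = stern_volmer_fit(t)
        assert res.ksv == pytest.approx(KSV, rel=0.10)

    def test_free_intercept_warns_when_far_from_one(self):
        y = 2.0 + KSV * Q_GRID  # intercept 2, not 1
        t = TitrationSeries(Q_GRID, 1000.0 / y, i0=1000.0)
        res = stern_volmer_fit(t)
        assert res.warnings

    def test_range_mask_restricts_fit(self):
        # masking to the low-concentration points still recovers the
        # planted slope and reports the reduced point count
        grid = np.linspace(0, 2e-5, 12)
        t = simulate_titration(
            QuenchSimSpec(mechanism="static_complex", seed=0, ka=1e6,
                          probe_conc_M=1e-8),
            grid,
        )
        mask = grid <= 6e-6
        res = stern_volmer_fit(t, fix_intercept=True, range_mask=mask)
        assert res.n_points_used == int(mask.sum()) < grid.size
        assert res.ksv == pytest.approx(1e6, rel=0.05)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(FitError):
            SternVolmer([0.0, 1e-6], [100.0, 90.0], i0=100.0)
        with pytest.raises(DomainError):
            SternVolmer([0.0, 1e-6, 2e-6], [100.0, -5.0, 50.0], i0=100.0)

    def test_from_dataframe_and_summary(self):
        import pandas as pd

        t = simulate_titration(
            QuenchSimSpec(mechanism="dynamic_SV", seed=0, ksv=KSV), Q_GRID
        )
        df = pd.DataFrame({"conc_M": t.conc_M, "intensity": t.intensity})
        res = SternVolmer.from_dataframe(df, i0=t.i0).fit()
        assert res.ksv == pytest.approx(KSV, rel=1e-8)
        assert "Ksv" in res.summary()


class TestStaticQuenching:
    def test_weak_binding_apparent_ksv_equals_ka(self):
        """In the dilute-probe, weak-complexation limit the static model's
        Stern-Volmer slope equals the association constant."""
        ka = 1e4
        grid = np.linspace(0.0, 1e-5, 10)
        t = simulate_titration(
            QuenchSimSpec(mechanism="static_complex", seed=0, ka=ka,
                          probe_conc_M=1e-7),
            grid,
        )
        res = stern_volmer_fit(t, fix_intercept=True)
        assert res.ksv == pytest.approx(ka, rel=0.05)

    def test_zero_quencher_leaves_intensity_untouched(self):
        grid = np.zeros(5)
        t = simulate_titration(
            QuenchSimSpec(mechanism="static_complex", seed=0, ka=1e6, i0=777.0),
            grid,
        )
        np.testing.assert_allclose(t.intensity, 777.0)


class TestDetectionLimit:
    def test_formula_identity_exact(self):
        series, blanks = simulate_lod_calibration(5.89e8, 0.3467, seed=11)
        res = detection_limit(series, blanks)
        assert res.lod_M * abs(res.slope) == pytest.approx(3 * res.sigma_blank, rel=1e-15)
        assert res.sigma_blank == pytest.approx(np.std(blanks, ddof=1))

    def test_zero_sigma_gives_zero_lod(self):
        series, blanks = simulate_lod_calibration(5.89e8, 0.0, seed=1)
        assert detection_limit(series, blanks).lod_M == 0.0

    def test_planted_lod_recovered(self):
        lod_true = 1.766e-9
        slope = 5.89e8
        series, blanks = simulate_lod_calibration(slope, lod_true * slope / 3, seed=5)
        res = detection_limit(series, blanks)
        assert res.lod_M == pytest.approx(lod_true, rel=0.5)  # single noisy replicate

    def test_delta_intensity_response_flips_slope_sign_only(self):
        series, blanks = simulate_lod_calibration(-5.89e8, 0.3467, seed=2,
                                                  intercept=1000.0)
        raw = detection_limit(series, blanks, response="intensity")
        delta = detection_limit(series, blanks, response="delta_intensity")
        assert raw.slope == pytest.approx(-delta.slope)
        assert raw.lod_M == pytest.approx(delta.lod_M)

    def test_rejects_too_few_blanks(self):
        series, _ = simulate_lod_calibration(5.89e8, 0.3467, seed=0)
        with pytest.raises(DomainError):
            LODCalibration(series.conc_M, series.intensity, [1.0, 2.0], i0=100.0)

    def test_zero_slope_is_fit_error(self):
        t = TitrationSeries(np.linspace(0, 1e-8, 5), np.full(5, 100.0), i0=100.0)
        with pytest.raises(FitError):
            detection_limit(t, [100.0, 100.1, 99.9])


class TestJobPlot:
    def test_one_to_one_maximum_at_half(self):
        series = simulate_job_series(
            BindingSimSpec(ka=1e6, seed=0, stoichiometry=(1, 1), c_total_M=2e-5),
            n_points=11,
        )
        res = job_analyze(series)
        assert res.x_max == pytest.approx(0.5, abs=0.01)
        assert res.ratio == (1, 1)
        assert not res.inconclusive

    def test_one_to_two_maximum_near_third(self):
        series = simulate_job_series(
            BindingSimSpec(ka=1e6, seed=0, stoichiometry=(1, 2), c_total_M=2e-5),
            n_points=41,
        )
        res = job_analyze(series)
        assert res.x_max == pytest.approx(1 / 3, abs=0.01)
        assert res.ratio == (1, 2)

    def test_two_to_one_host_guest(self):
        series = simulate_job_series(
            BindingSimSpec(ka=1e6, seed=0, stoichiometry=(2, 1), c_total_M=2e-5),
            n_points=41,
        )
        res = job_analyze(series)
        assert res.x_max == pytest.approx(2 / 3, abs=0.01)
        assert res.ratio == (2, 1)

    def test_exact_symmetric_parabola_peaks_at_half(self):
        x = np.linspace(0.1, 0.9, 9)
        res = JobPlot(x, -(x - 0.5) ** 2).fit()
        assert res.x_max == pytest.approx(0.5, abs=1e-12)

    def test_one_to_one_curve_is_symmetric(self):
        series = simulate_job_series(
            BindingSimSpec(ka=1e6, seed=0, stoichiometry=(1, 1)), n_points=11
        )
        assert job_analyze(series).symmetry >= 0.999

    def test_boundary_maximum_is_inconclusive(self):
        x = np.linspace(0.1, 0.9, 9)
        res = JobPlot(x, x).fit()  # strictly increasing
        assert res.inconclusive
        assert res.ratio is None

    def test_baseline_correction_removes_linear_trend(self):
        series = simulate_job_series(
            BindingSimSpec(ka=1e6, seed=0, stoichiometry=(1, 1)), n_points=11
        )
        tilted = series.signal + 3e-6 * series.mole_fraction
        res = JobPlot(series.mole_fraction, tilted, baseline_correction=True).fit()
        assert res.x_max == pytest.approx(0.5, abs=0.02)

    def test_needs_five_points(self):
        with pytest.raises(DomainError):
            JobSeries(np.array([0.2, 0.5, 0.8]), np.array([1.0, 2.0, 1.0]))


class TestScalarHelpers:
    @pytest.mark.parametrize("i, expected", [(100.0, 0.0), (0.0, 100.0), (50.0, 50.0)])
    def test_quenching_efficiency(self, i, expected):
        assert quenching_efficiency(100.0, i) == pytest.approx(expected)

    def test_quenching_enhancement_is_negative(self):
        assert quenching_efficiency(100.0, 120.0) == pytest.approx(-20.0)

    def test_selectivity_flags_strongest_quencher(self):
        panel = selectivity_panel(
            1000.0,
            {"PA": 100.0, "2NP": 960.0, "3NP": 970.0, "4NP": 955.0,
             "3NA": 980.0, "ANP": 950.0},
        )
        assert panel.flagged == "PA"
        assert panel.selective
        assert panel.responses["PA"] == pytest.approx(0.9)

    def test_selectivity_no_response_no_flag(self):
        panel = selectivity_panel(1000.0, {"a": 1000.0, "b": 1000.0})
        assert panel.flagged is None and not panel.selective

    def test_selectivity_single_entry_flagged(self):
        panel = selectivity_panel(1000.0, {"PA": 100.0})
        assert panel.flagged == "PA"

    def test_interference_mode_retains_target_response(self):
        panel = selectivity_panel(
            1000.0, {"PA": 100.0},
            interference={"2NP": (950.0, 120.0)},
        )
        assert panel.interference["2NP"] == pytest.approx(1 - 120.0 / 950.0)

    @pytest.mark.parametrize(
        "recovered, expected", [(1000.0, 1.0), (100.0, 0.0), (550.0, 0.5)]
    )
    def test_reversibility_fractions(self, recovered, expected):
        res = reversibility_index(1000.0, 100.0, recovered)
        assert res.fraction == pytest.approx(expected)

    def test_reversibility_overshoot_clipped_with_raw_kept(self):
        res = reversibility_index(1000.0, 100.0, 1100.0)
        assert res.fraction == 1.0
        assert res.raw == pytest.approx(10.0 / 9.0)

    def test_reversibility_undefined_without_quench(self):
        with pytest.raises(DomainError):
            reversibility_index(1000.0, 1000.0, 1000.0)

    def test_dilution_correction(self):
        conc = dilution_corrected_conc([0.0, 2.0, 4.0], 1e-3, 2.0)
        assert conc[0] == 0.0
        assert conc[1] == pytest.approx(2e-3 * 1e-3 / 2.002)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.floats(1e-3, 1e6))
def test_intensity_rescaling_invariance(scale):
    """Quenching efficiency and reversibility are dimensionless: rescaling
    all intensities by a common positive factor leaves them unchanged."""
    assert quenching_efficiency(100.0 * scale, 37.0 * scale) == pytest.approx(
        quenching_efficiency(100.0, 37.0), rel=1e-9
    )
    a = reversibility_index(100.0 * scale, 20.0 * scale, 60.0 * scale)
    b = reversibility_index(100.0, 20.0, 60.0)
    assert a.fraction == pytest.approx(b.fraction, rel=1e-9)
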