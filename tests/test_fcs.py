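"""Autocorrelation estimators and diffusion-model fits."""

import numpy as np
import pytest

from ffskit import (
    CorrelationCurve,
    DEFAULT_BEAM,
    PhotonTrace,
    autocorrelate_direct,
    autocorrelate_multitau,
    average_curves,
    fit_acf,
    model_acf,
    select_model,
    taud_to_D,
)
from ffskit.fcs import FCSDiffusionModel, restrict_lags

from conftest import make_membrane_trace


def _curve_from_model(model_id, params, lags, sem=None, source=None):
    return CorrelationCurve(
        lags=lags, G=model_acf(model_id, params, lags), sem=sem,
        source=source or {},
    )


class TestDirectCorrelator:
    def test_constant_trace_has_zero_correlation(self):
        trace = PhotonTrace(counts=np.full(1000, 7), bin_time=1e-5)
        curve = autocorrelate_direct(trace, np.arange(1, 10) * 1e-5)
        assert np.allclose(curve.G, 0.0)

    def test_matches_hand_enumeration_on_impulse_pair(self):
        # two spikes 4 bins apart in a 10-bin trace
        counts = np.array([0, 0, 5, 0, 0, 0, 5, 0, 0, 0])
        trace = PhotonTrace(counts=counts, bin_time=1e-3)
        lags_bins = [1, 2, 3, 4]
        curve = autocorrelate_direct(trace, [k * 1e-3 for k in lags_bins])
        mu = counts.mean()
        for k, g in zip(lags_bins, curve.G):
            d = counts - mu
            oracle = np.mean(
                [d[i] * d[i + k] for i in range(len(counts) - k)]
            ) / mu**2
            assert g == pytest.approx(oracle, abs=1e-12)
        # the impulse pair produces the peak at lag 4
        assert curve.G[3] == pytest.approx(3.5)
        assert curve.G[3] == max(curve.G)

    def test_lag_validation(self):
        trace = PhotonTrace(counts=np.arange(100) % 3, bin_time=1e-5)
        with pytest.raises(ValueError, match="integer multiples"):
            autocorrelate_direct(trace, [1.5e-5])
        with pytest.raises(ValueError, match="duration/2"):
            autocorrelate_direct(trace, [60 * 1e-5])


class TestMultiTau:
    def test_constant_trace_gives_zero(self):
        trace = PhotonTrace(counts=np.full(8192, 3), bin_time=1e-5)
        curve = autocorrelate_multitau(trace, m=16, levels=8)
        assert np.allclose(curve.G, 0.0)

    def test_lag_grid_arithmetic(self):
        trace = PhotonTrace(counts=np.full(8192, 3), bin_time=1e-5)
        curve = autocorrelate_multitau(trace, m=16, levels=8)
        assert curve.lags.size == 16 + 7 * 8
        assert curve.lags[-1] == pytest.approx(16 * 2**7 * 1e-5)
        assert np.all(np.diff(curve.lags) > 0)

    def test_m_validation(self):
        trace = PhotonTrace(counts=np.full(100, 3), bin_time=1e-5)
        with pytest.raises(ValueError, match="even"):
            autocorrelate_multitau(trace, m=7)
        with pytest.raises(ValueError, match="too short"):
            autocorrelate_multitau(
                PhotonTrace(counts=np.full(8, 1), bin_time=1e-5), m=16
            )

    def test_agrees_with_direct_estimator_on_simulated_trace(self):
        """Multi-tau equals the exact correlator within 2% at native-bin lags."""
        cfg, trace = make_membrane_trace(
            seed=99, duration=1.0, occupancy=10.0, epsilon=6500.0, d_coeff=70.0
        )
        mt = autocorrelate_multitau(trace, m=16)
        keep = mt.lags <= 16 * trace.bin_time  # lags evaluated at native binning
        direct = autocorrelate_direct(trace, mt.lags[keep])
        rel = np.abs(mt.G[keep] - direct.G) / np.abs(direct.G)
        assert rel.max() < 0.02

    def test_rebinned_levels_agree_with_direct_on_structured_signal(self):
        """The 2x-rebinned levels reproduce the exact correlator within 2%.

        A deterministic slowly-varying signal isolates the rebinning
        kernel from Monte-Carlo noise: the triangular average over a
        rebinned lag must match the point evaluation when the
        correlation structure is smooth on the kernel scale.
        """
        t = np.arange(100_000)
        counts = np.rint(
            20 + 10 * np.sin(2 * np.pi * t / 4000.0)
            + 5 * np.cos(2 * np.pi * t / 9000.0)
        ).astype(int)
        trace = PhotonTrace(counts=counts, bin_time=1e-5)
        mt = autocorrelate_multitau(trace, m=16, levels=6)
        direct = autocorrelate_direct(trace, mt.lags)
        rel = np.abs(mt.G - direct.G) / np.abs(direct.G)
        assert rel.max() < 0.02


class TestModelACF:
    def test_amplitude_is_inverse_occupancy(self):
        g = model_acf("3d1c", dict(N=10, tau_d=1e-4, S=5, g_inf=0.0), [0.0])
        assert g[0] == pytest.approx(0.1, rel=1e-9)

    def test_half_decay_at_residence_time_2d(self):
        g = model_acf("2d1c", dict(N=1, tau_d=1e-3, g_inf=0.0), [1e-3])
        assert g[0] == pytest.approx(0.5)

    def test_axial_factor_at_residence_time_3d(self):
        g = model_acf("3d1c", dict(N=1, tau_d=1e-3, S=5, g_inf=0.0), [1e-3])
        assert g[0] == pytest.approx(0.5 * (1 + 1 / 25) ** -0.5, abs=1e-5)
        assert g[0] == pytest.approx(0.49029, abs=1e-5)

    def test_two_component_is_fraction_weighted_sum(self):
        lags = np.logspace(-5, -1, 30)
        p1 = dict(N=2.0, tau_d=1e-4, g_inf=0.01)
        p2 = dict(N=2.0, tau_d=1e-3, g_inf=0.01)
        mix = model_acf(
            "2d2c",
            dict(N=2.0, tau_d1=1e-4, tau_d2=1e-3, frac1=0.3, g_inf=0.01),
            lags,
        )
        manual = 0.3 * model_acf("2d1c", p1, lags) + 0.7 * model_acf("2d1c", p2, lags)
        assert np.allclose(mix, manual, atol=1e-12)

    def test_3d_model_approaches_2d_as_s_grows(self):
        """Closed-form limit: the axial factor vanishes for S -> infinity."""
        tau_d = 2e-4
        lags = np.linspace(1e-6, 10 * tau_d, 100)
        g3 = model_acf("3d1c", dict(N=1, tau_d=tau_d, S=1e3, g_inf=0.0), lags)
        g2 = model_acf("2d1c", dict(N=1, tau_d=tau_d, g_inf=0.0), lags)
        assert np.max(np.abs(g3 - g2) / g2) < 1e-3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="N must be positive"):
            model_acf("2d1c", dict(N=0, tau_d=1e-4, g_inf=0.0), [1e-5])
        with pytest.raises(ValueError, match="tau_d"):
            model_acf("2d1c", dict(N=1, tau_d=-1e-4, g_inf=0.0), [1e-5])
        with pytest.raises(ValueError, match="unknown model_id"):
            model_acf("4d9c", dict(N=1), [1e-5])


class TestTaudToD:
    def test_arithmetic(self):
        assert taud_to_D(1.43e-4, 0.2) == pytest.approx(69.93, abs=0.01)
        assert taud_to_D(1.0, 0.2) == pytest.approx(0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            taud_to_D(0.0, 0.2)
        with pytest.raises(ValueError):
            taud_to_D(1e-4, -0.2)


class TestFitACF:
    lags = np.unique(np.rint(np.logspace(0, 4.3, 60)).astype(int)) * 1e-5

    def _source(self):
        return {"bin_time_s": 1e-5, "duration_s": 10.0}

    def test_exact_model_data_recovered_to_four_significant_figures(self):
        truth = dict(N=5.0, tau_d=2e-4, S=DEFAULT_BEAM.S, g_inf=0.0)
        curve = _curve_from_model("3d1c", truth, self.lags, source=self._source())
        fit = fit_acf(curve, "3d1c")
        assert fit.params["N"] == pytest.approx(5.0, rel=1e-4)
        assert fit.params["tau_d"] == pytest.approx(2e-4, rel=1e-4)
        assert not fit.flagged

    def test_round_trip_residence_time_to_diffusion(self):
        d_true = 42.0
        tau_d = DEFAULT_BEAM.w0**2 / (4 * d_true)
        truth = dict(N=2.0, tau_d=tau_d, S=DEFAULT_BEAM.S, g_inf=0.0)
        curve = _curve_from_model("3d1c", truth, self.lags, source=self._source())
        fit = fit_acf(curve, "3d1c")
        assert fit.D[0] == pytest.approx(d_true, rel=1e-4)

    def test_weighted_fit_uses_sem(self):
        truth = dict(N=5.0, tau_d=2e-4, S=DEFAULT_BEAM.S, g_inf=0.0)
        sem = np.full(self.lags.size, 1e-3)
        curve = _curve_from_model(
            "3d1c", truth, self.lags, sem=sem, source=self._source()
        )
        fit = fit_acf(curve, "3d1c")
        assert fit.params["tau_d"] == pytest.approx(2e-4, rel=1e-3)

    def test_too_few_points_rejected(self):
        curve = _curve_from_model(
            "2d1c", dict(N=1, tau_d=1e-4, g_inf=0), np.logspace(-5, -1, 10)
        )
        with pytest.raises(ValueError, match=">= 20 lag points"):
            fit_acf(curve, "2d1c")

    def test_narrow_lag_span_rejected(self):
        curve = _curve_from_model(
            "2d1c", dict(N=1, tau_d=1e-4, g_inf=0), np.linspace(1e-4, 5e-4, 30)
        )
        with pytest.raises(ValueError, match="two decades"):
            fit_acf(curve, "2d1c")


class TestAmplitudeAndOccupancy:
    def test_zero_lag_amplitude_matches_gamma_over_occupancy(
        self, membrane_trace_bank
    ):
        """G(tau->0) = gamma / N_eff with N_eff molecules in the PSF volume."""
        amps = []
        for cfg, trace in membrane_trace_bank:
            curve = autocorrelate_multitau(trace, m=16)
            amps.append(curve.G[0])
        sp = membrane_trace_bank[0][0].species[0]
        a_box = membrane_trace_bank[0][0].box_measure()
        n_eff = sp.mean_number * DEFAULT_BEAM.psf_integral(2) / a_box
        expected = DEFAULT_BEAM.contrast_gamma(2) / n_eff
        assert np.mean(amps) == pytest.approx(expected, rel=0.15)

    def test_fitted_occupancy_scales_linearly_with_concentration(self):
        """Fitted N doubles when the simulated mean number doubles (4x range)."""
        factors = [1.0, 2.0, 4.0]
        tau_d = DEFAULT_BEAM.w0**2 / (4 * 6.12)
        fitted = []
        for fac in factors:
            vals = []
            for seed in (3, 5, 7):
                cfg, trace = make_membrane_trace(
                    seed=seed * int(fac * 10), duration=5.0, occupancy=fac
                )
                curve = restrict_lags(
                    autocorrelate_multitau(trace, m=16), 20 * tau_d
                )
                vals.append(fit_acf(curve, "2d1c").N)
            fitted.append(np.mean(vals))
        predicted = fitted[0] * np.array(factors)
        slope = np.sum(np.array(fitted) * predicted) / np.sum(predicted**2)
        assert slope == pytest.approx(1.0, abs=0.15)


class TestModelSelection:
    def _noisy_curve(self, model_id, params, seed=0, sigma=1e-4):
        lags = np.unique(np.rint(np.logspace(0, 4, 60)).astype(int)) * 1e-5
        rng = np.random.default_rng(seed)
        g = model_acf(model_id, params, lags) + rng.normal(0, sigma, lags.size)
        return CorrelationCurve(lags=lags, G=g,
                                source={"bin_time_s": 1e-5, "duration_s": 10.0})

    def test_single_component_data_prefers_one_component(self):
        curve = self._noisy_curve("2d1c", dict(N=2.0, tau_d=2e-4, g_inf=0.0))
        f1 = fit_acf(curve, "2d1c")
        f2 = fit_acf(curve, "2d2c")
        choice = select_model(f1, f2)
        assert choice.choice == "1c"

    def test_two_component_data_detected(self):
        curve = self._noisy_curve(
            "2d2c",
            dict(N=2.0, tau_d1=5e-5, tau_d2=5e-4, frac1=0.5, g_inf=0.0),
        )
        f1 = fit_acf(curve, "2d1c")
        f2 = fit_acf(
            curve, "2d2c", init=dict(tau_d1=4e-5, tau_d2=6e-4, frac1=0.5)
        )
        choice = select_model(f1, f2)
        assert choice.choice == "2c"
        assert choice.f_statistic > 10

    def test_identical_residuals_give_parsimony(self):
        curve = self._noisy_curve("2d1c", dict(N=2.0, tau_d=2e-4, g_inf=0.0))
        f1 = fit_acf(curve, "2d1c")
        f2 = fit_acf(curve, "2d1c")
        f2.n_free = f1.n_free + 2  # same residuals presented as a larger model
        choice = select_model(f1, f2)
        assert choice.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert choice.choice == "1c"

    def test_mismatched_curves_rejected(self):
        c1 = self._noisy_curve("2d1c", dict(N=2.0, tau_d=2e-4, g_inf=0.0), seed=1)
        c2 = self._noisy_curve("2d1c", dict(N=2.0, tau_d=2e-4, g_inf=0.0), seed=2)
        f1 = fit_acf(c1, "2d1c")
        f2 = fit_acf(c2, "2d2c")
        with pytest.raises(ValueError, match="same correlation curve"):
            select_model(f1, f2)


class TestCurveUtilities:
    def test_average_curves_reports_sem(self):
        lags = np.array([1e-5, 2e-5, 4e-5])
        curves = [
            CorrelationCurve(lags=lags, G=np.array([1.0, 0.5, 0.25]) * s)
            for s in (0.9, 1.0, 1.1)
        ]
        avg = average_curves(curves)
        assert avg.G[0] == pytest.approx(1.0)
        assert avg.sem[0] == pytest.approx(np.std([0.9, 1.0, 1.1], ddof=1) / np.sqrt(3))

    def test_restrict_lags_window(self):
        lags = np.array([1e-5, 1e-4, 1e-3, 1e-2])
        curve = CorrelationCurve(lags=lags, G=np.ones(4))
        cut = restrict_lags(curve, 1e-3)
        assert cut.lags.size == 3
        with pytest.raises(ValueError, match="no lags left"):
            restrict_lags(curve, 1e-9)

    def test_strictly_increasing_lags_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CorrelationCurve(lags=np.array([2e-5, 1e-5]), G=np.zeros(2))
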