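import numpy as np
import pytest

from mpasl import (FermiModel, FermiParams, HUMAN_SHAPE, MultiPhaseSeries,
                   Posterior, PriorSpec, evaluate_fermi, fit_fermi_batch,
                   fit_multiphase, generate_series, goodness_of_fit,
                   snr_estimate)

THETAS8 = np.arange(8) * 45.0


def _series(params, snr=1e9, seed=0, n_repeats=1):
    return generate_series(params, HUMAN_SHAPE, snr=snr, seed=seed,
                           n_repeats=n_repeats)


class TestFitMultiphase:
    def test_noiseless_recovery(self):
        truth = FermiParams(delta_m=20.0, m_s=1000.0, phi=110.0)
        post = fit_multiphase(_series(truth), FermiModel(HUMAN_SHAPE))
        assert post.delta_m == pytest.approx(truth.delta_m, rel=1e-3)
        assert post.m_s == pytest.approx(truth.m_s, rel=1e-3)
        assert post.phi == pytest.approx(truth.phi, abs=0.1)
        assert post.converged

    def test_consistency_as_noise_vanishes(self):
        truth = FermiParams(delta_m=20.0, m_s=1000.0, phi=200.0)
        errs = []
        for snr in (100, 1000, 10000):
            post = fit_multiphase(_series(truth, snr=snr, seed=3),
                                  FermiModel(HUMAN_SHAPE))
            errs.append(abs(post.delta_m - truth.delta_m))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    def test_fixed_phase_prior_pins_phase(self):
        truth = FermiParams(delta_m=20.0, m_s=1000.0, phi=73.0)
        post = fit_multiphase(_series(truth, snr=20, seed=5),
                              FermiModel(HUMAN_SHAPE),
                              priors=PriorSpec.fixed_phase(73.0))
        assert post.phi == pytest.approx(73.0, abs=1e-4)
        assert post.variances["phi"] < 1e-6

    def test_degenerate_constant_series(self):
        ser = MultiPhaseSeries(thetas=THETAS8, values=np.full(8, 500.0))
        post = fit_multiphase(ser, FermiModel(HUMAN_SHAPE))
        assert post.delta_m == pytest.approx(0.0, abs=1e-6)
        assert post.variances["phi"] > 1e6  # phase unidentified
        assert np.isnan(post.r_squared)

    def test_positive_bias_when_free_smaller_when_fixed(self):
        """The documented low-SNR behaviour: free 3-parameter fits
        overestimate the amplitude; pinning the phase shrinks the bias."""
        rng = np.random.default_rng(42)
        truth = FermiParams(delta_m=20.0, m_s=1000.0, phi=0.0)
        clean = evaluate_fermi(truth, HUMAN_SHAPE, THETAS8)
        n = 4000
        y = clean[None] + rng.standard_normal((n, 8)) * (1000.0 / 40.0)
        free = fit_fermi_batch(THETAS8, y, HUMAN_SHAPE)
        fixed = fit_fermi_batch(THETAS8, y, HUMAN_SHAPE, phi_fixed=np.zeros(n))
        bias_free = free["delta_m"].mean() - truth.delta_m
        bias_fixed = fixed["delta_m"].mean() - truth.delta_m
        assert bias_free > 0
        assert abs(bias_fixed) < abs(bias_free)

    def test_averaging_equivalence(self):
        """Fitting the mean of M series matches fitting at SNR * sqrt(M):
        the spread of the amplitude estimates agrees within MC error."""
        rng = np.random.default_rng(7)
        truth = FermiParams(delta_m=30.0, m_s=1000.0, phi=45.0)
        clean = evaluate_fermi(truth, HUMAN_SHAPE, THETAS8)
        n, M, snr = 1500, 16, 25.0
        noisy = clean[None, None] + rng.standard_normal((n, M, 8)) * (1000.0 / snr)
        mean_fit = fit_fermi_batch(THETAS8, noisy.mean(axis=1), HUMAN_SHAPE)
        hi = clean[None] + rng.standard_normal((n, 8)) * (1000.0 / (snr * np.sqrt(M)))
        hi_fit = fit_fermi_batch(THETAS8, hi, HUMAN_SHAPE)
        sd_mean = mean_fit["delta_m"].std()
        sd_hi = hi_fit["delta_m"].std()
        assert sd_mean == pytest.approx(sd_hi, rel=0.15)

    def test_phase_wrap_equivalence(self):
        truth = FermiParams(delta_m=100.0, m_s=1000.0, phi=350.0)
        post = fit_multiphase(_series(truth, snr=200, seed=1),
                              FermiModel(HUMAN_SHAPE))
        assert 0.0 <= post.phi < 360.0
        d = min(abs(post.phi - 350.0), 360.0 - abs(post.phi - 350.0))
        assert d < 2.0


class TestGoodnessOfFit:
    def test_exact_fit(self):
        ser = MultiPhaseSeries(THETAS8, np.arange(8.0))
        assert goodness_of_fit(ser, np.arange(8.0)) == pytest.approx(1.0)

    def test_mean_prediction(self):
        ser = MultiPhaseSeries(THETAS8, np.arange(8.0))
        assert goodness_of_fit(ser, np.full(8, 3.5)) == pytest.approx(0.0)

    def test_hand_computed(self):
        ser = MultiPhaseSeries(np.array([0.0, 90.0, 180.0, 270.0]),
                               np.array([1.0, 2.0, 3.0, 4.0]))
        assert goodness_of_fit(ser, np.array([1.0, 2.0, 3.0, 5.0])) == \
            pytest.approx(1.0 - 1.0 / 5.0)

    def test_zero_variance_signalled(self):
        ser = MultiPhaseSeries(THETAS8, np.full(8, 2.0))
        with pytest.raises(ValueError):
            goodness_of_fit(ser, np.full(8, 2.0))

    def test_length_mismatch(self):
        ser = MultiPhaseSeries(THETAS8, np.arange(8.0))
        with pytest.raises(ValueError):
            goodness_of_fit(ser, np.arange(5.0))


class TestSnrEstimate:
    def _post(self, m_s, noise_sd):
        return Posterior(delta_m=1.0, m_s=m_s, phi=0.0, velocity=None,
                         variances={}, noise_sd=noise_sd, r_squared=1.0,
                         converged=True, n_iter=1)

    def test_definition(self):
        assert snr_estimate(self._post(1000.0, 25.0)) == pytest.approx(40.0)
        assert snr_estimate(self._post(1000.0, 15.9)) == pytest.approx(62.9, abs=0.1)

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError):
            snr_estimate(self._post(1000.0, 0.0))

    def test_recovers_simulated_snr(self):
        """Whole-batch mean of Ms / sigma-hat tracks the generating SNR."""
        rng = np.random.default_rng(11)
        truth = FermiParams(delta_m=21.0, m_s=1000.0, phi=30.0)
        clean = evaluate_fermi(truth, HUMAN_SHAPE, THETAS8)
        snr = 63.0
        n_vox, n_rep = 400, 8
        y = clean[None, :, None] + rng.standard_normal((n_vox, 8, n_rep)) * (1000.0 / snr)
        fit = fit_fermi_batch(THETAS8, y, HUMAN_SHAPE)
        est = (fit["m_s"] / fit["noise_sd"]).mean()
        assert est == pytest.approx(snr, rel=0.06)


class TestSeriesValidation:
    def test_too_few_phases(self):
        with pytest.raises(ValueError):
            MultiPhaseSeries(np.array([0.0, 120.0, 240.0]), np.zeros(3))

    def test_non_increasing(self):
        with pytest.raises(ValueError):
            MultiPhaseSeries(np.array([0.0, 90.0, 90.0, 270.0]), np.zeros(4))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            MultiPhaseSeries(np.array([0.0, 90.0, 180.0, 360.0]), np.zeros(4))
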