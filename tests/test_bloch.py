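import numpy as np
import pytest

from mpasl import (HUMAN_PULSE_TRAIN, RAT_PULSE_TRAIN, InversionLookup,
                   LookupModel, PulseTrainParams, build_lookup,
                   evaluate_lookup_model, mean_velocity_profile,
                   simulate_spin_profile)
from bloch_reference import reference_spin_profile

OFFSETS17 = np.linspace(-np.pi, np.pi, 17)


class TestSpinProfile:
    def test_zero_flip_leaves_magnetisation(self):
        p = PulseTrainParams(label_gradient=16.3, mean_gradient=1.62,
                             pulse_interval=1200, pulse_width=600,
                             flip_angle=1e-12)
        assert np.allclose(simulate_spin_profile(p, 30.0, OFFSETS17), 1.0)

    def test_mz_bounded(self):
        for v in (5.0, 30.0, 60.0):
            mz = simulate_spin_profile(RAT_PULSE_TRAIN, v, OFFSETS17)
            assert np.all(np.abs(mz) <= 1.0 + 1e-12)

    def test_inversion_at_matched_phase(self):
        # on-resonance phase increment inverts; opposite phase does not
        mz = simulate_spin_profile(RAT_PULSE_TRAIN, 30.0, [0.0, np.pi])
        assert mz[0] < -0.7
        assert mz[1] > 0.7

    def test_rejects_non_positive_velocity(self):
        with pytest.raises(ValueError):
            simulate_spin_profile(RAT_PULSE_TRAIN, 0.0, [0.0])

    @pytest.mark.parametrize("pulses,velocity", [
        (RAT_PULSE_TRAIN, 30.0),
        (HUMAN_PULSE_TRAIN, 30.0),
    ])
    def test_agrees_with_fine_step_integrator(self, pulses, velocity):
        """Hard-pulse propagation vs a brute-force 10-us Bloch integration."""
        ours = simulate_spin_profile(pulses, velocity, OFFSETS17)
        ref = reference_spin_profile(pulses, velocity, OFFSETS17)
        assert np.max(np.abs(ours - ref)) < 0.02

    def test_oracle_agreement_across_velocities(self, ):
        for v in (10.0, 60.0):
            ours = simulate_spin_profile(RAT_PULSE_TRAIN, v, OFFSETS17[::2])
            ref = reference_spin_profile(RAT_PULSE_TRAIN, v, OFFSETS17[::2])
            assert np.max(np.abs(ours - ref)) < 0.02


class TestMeanVelocityProfile:
    def test_matches_annular_average(self):
        # explicit Poiseuille discretisation: 6 annuli, area weights
        # (2k-1)/36, mid-annulus speeds 2*vbar*(1 - ((k-1/2)/6)^2)
        vbar = 25.0
        k = np.arange(1, 7)
        speeds = 2.0 * vbar * (1.0 - ((k - 0.5) / 6.0) ** 2)
        weights = (2.0 * k - 1.0) / 36.0
        assert weights.sum() == pytest.approx(1.0)
        offsets = np.linspace(-np.pi, np.pi, 9)
        expected = sum(w * simulate_spin_profile(RAT_PULSE_TRAIN, s, offsets)
                       for w, s in zip(weights, speeds))
        got = mean_velocity_profile(RAT_PULSE_TRAIN, vbar, offsets)
        assert np.allclose(got, expected)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            mean_velocity_profile(RAT_PULSE_TRAIN, -5.0, [0.0])


class TestLookup:
    def test_dimensions_and_nodes(self, small_lookup):
        assert small_lookup.mz.shape == (33, 3)
        # interpolation exactness at grid nodes
        d = np.rad2deg(small_lookup.phase_grid[7])
        v = small_lookup.velocities[1]
        assert small_lookup.interp_mz(d, v) == pytest.approx(
            small_lookup.mz[7, 1], abs=1e-12)

    def test_deterministic_rebuild(self):
        a = build_lookup(RAT_PULSE_TRAIN, velocities=(20.0,), n_phase=9)
        b = build_lookup(RAT_PULSE_TRAIN, velocities=(20.0,), n_phase=9)
        assert np.array_equal(a.mz, b.mz)

    def test_save_load_roundtrip(self, small_lookup, tmp_path):
        path = tmp_path / "lookup.json"
        small_lookup.save(path)
        back = InversionLookup.load(path)
        assert np.allclose(back.mz, small_lookup.mz)
        assert np.allclose(back.velocities, small_lookup.velocities)
        assert back.pulse_params == small_lookup.pulse_params

    def test_velocity_out_of_range(self, small_lookup):
        with pytest.raises(ValueError):
            small_lookup.interp_mz(0.0, 80.0)

    def test_velocity_midpoint_linear(self, small_lookup):
        v0, v1 = small_lookup.velocities[0], small_lookup.velocities[1]
        mid = small_lookup.interp_mz(30.0, 0.5 * (v0 + v1))
        ends = 0.5 * (small_lookup.interp_mz(30.0, v0)
                      + small_lookup.interp_mz(30.0, v1))
        assert mid == pytest.approx(ends, abs=1e-12)


class TestLookupModel:
    def test_zero_amplitude(self, small_lookup):
        out = evaluate_lookup_model(
            small_lookup,
            {"delta_m": 0.0, "m_s": 800.0, "phi": 33.0, "velocity": 20.0},
            np.arange(0, 360, 45.0))
        assert np.allclose(out, 800.0)

    def test_node_closed_form(self, small_lookup):
        # theta - phi exactly on a grid node, velocity tabulated
        d_deg = np.rad2deg(small_lookup.phase_grid[10])
        params = {"delta_m": 50.0, "m_s": 1000.0, "phi": 0.0, "velocity": 40.0}
        out = evaluate_lookup_model(small_lookup, params, [d_deg])
        expected = 1000.0 - 50.0 * (-small_lookup.mz[10, 2])
        assert out[0] == pytest.approx(expected, abs=1e-9)

    def test_sign_convention(self, rat_lookup):
        """Full inversion at matched phase gives the labelled (low) signal."""
        model = LookupModel(rat_lookup)
        sig = model.predict(50.0, 1000.0, 0.0, 30.0, np.array([0.0, 180.0]))
        assert sig[0] < 1000.0 - 25.0   # labelled: well below Ms
        assert sig[1] > 1000.0 + 25.0   # control: well above Ms

    def test_only_phase_difference_matters(self, small_lookup):
        thetas = np.arange(0, 360, 45.0)
        a = evaluate_lookup_model(
            small_lookup, {"delta_m": 30.0, "m_s": 1000.0, "phi": 10.0,
                           "velocity": 20.0}, thetas)
        b = evaluate_lookup_model(
            small_lookup, {"delta_m": 30.0, "m_s": 1000.0, "phi": 130.0,
                           "velocity": 20.0}, thetas + 120.0)
        assert np.allclose(a, b)
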