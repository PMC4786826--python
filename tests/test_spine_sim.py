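"""Excitation synthesis, chain model construction, and response simulation."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import eigh

import spineshm as sh
from spineshm.exceptions import ConfigurationError

from conftest import single_mass_model


class TestExcitation:
    def test_pulse_train_shape_and_determinism(self, default_cfg):
        force = sh.generate_excitation(default_cfg)
        assert force.shape == (50_000,)
        again = sh.generate_excitation(dataclasses.replace(default_cfg))
        np.testing.assert_array_equal(force, again)

    def test_per_pulse_rms_equals_target(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, force_rms=2.5)
        force = sh.generate_excitation(cfg)
        for p in range(cfg.n_pulses):
            pulse = force[p * 5000:(p + 1) * 5000]
            assert np.sqrt(np.mean(pulse**2)) == pytest.approx(2.5, rel=1e-12)

    def test_amplitude_spectrum_flat_in_band_zero_outside(self, default_cfg):
        """Direct DFT of one pulse: equal magnitude at every in-band bin
        (CV < 1e-6), zero magnitude outside the band."""
        force = sh.generate_excitation(default_cfg)
        pulse = force[:5000]
        mags = np.abs(np.fft.rfft(pulse))
        freqs = np.fft.rfftfreq(5000, d=1 / 5000.0)
        band = (freqs >= 1) & (freqs <= 2000)
        in_band = mags[band]
        assert np.std(in_band) / np.mean(in_band) < 1e-6
        assert np.max(mags[~band]) < 1e-9 * np.mean(in_band)

    def test_seeds_differ_pulses_differ(self, default_cfg):
        force = sh.generate_excitation(default_cfg)
        other = sh.generate_excitation(dataclasses.replace(default_cfg, seed=8))
        assert not np.allclose(force, other)
        # distinct pulses within one train (independent phase draws)
        assert not np.allclose(force[:5000], force[5000:10000])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f_min": 100.0, "f_max": 100.0},       # degenerate band
            {"f_min": -5.0},
            {"sample_rate": 3000.0},                # Nyquist violation
            {"n_pulses": 0},
            {"pulse_duration": 0.0},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            sh.ExcitationConfig(**kwargs)


class TestSpineModel:
    def test_default_model_is_valid_six_node_chain(self, default_model):
        assert default_model.node_labels == ("T12", "L1", "L2", "L3", "L4", "L5")
        assert default_model.masses.shape == (6,)
        assert default_model.stiffnesses.shape == (5,)
        assert default_model.sensor_labels == ("L1", "L2", "L3", "L4", "L5")
        assert np.all(default_model.sensor_attenuation > 0)
        assert np.all(default_model.sensor_attenuation <= 1)
        assert np.all(np.diff(default_model.sensor_attenuation) <= 0)

    def test_two_node_request_rejected(self):
        with pytest.raises(ConfigurationError):
            sh.build_spine_model(node_labels=("T12", "L1"))

    @pytest.mark.parametrize("bad", [
        {"masses": (0.15,) * 5 + (0.0,)},
        {"stiffnesses": (8e6, 8e6, -1.0, 8e6, 8e6)},
        {"sensor_attenuation": (1.0, 0.9, 0.8, 0.7, 1.5)},
        {"noise_rms": -1.0},
    ])
    def test_nonpositive_or_out_of_range_parameters_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            sh.build_spine_model(**bad)

    def test_fundamental_resonance_in_band_eigen_oracle(self, default_model):
        """Brute-force generalized eigenanalysis of (K, M) places the
        fundamental inside the excited 1-2000 Hz band."""
        w2 = eigh(
            default_model.stiffness_matrix(),
            default_model.mass_matrix(),
            eigvals_only=True,
        )
        f0 = np.sqrt(w2.min()) / (2 * np.pi)
        assert 1.0 <= f0 <= 2000.0
        assert f0 == pytest.approx(default_model.natural_frequencies()[0], rel=1e-12)


class TestAlteration:
    def test_identity_factors_leave_model_unchanged(self, default_model):
        same = sh.apply_alteration(default_model, sh.Alteration("L3", 1.0, 1.0))
        np.testing.assert_array_equal(same.masses, default_model.masses)
        np.testing.assert_array_equal(same.stiffnesses, default_model.stiffnesses)

    def test_input_model_unmodified(self, default_model):
        before = default_model.stiffnesses.copy()
        sh.apply_alteration(default_model, sh.Alteration("L1", 0.5))
        np.testing.assert_array_equal(default_model.stiffnesses, before)

    def test_zero_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            sh.Alteration("L1", stiffness_factor=0.0)

    def test_unknown_level_rejected(self, default_model):
        with pytest.raises(KeyError):
            sh.apply_alteration(default_model, sh.Alteration("T13", 0.5))

    @pytest.mark.parametrize("level", ["L1", "L2", "L3", "L4", "L5"])
    def test_stiffness_reduction_lowers_fundamental(self, default_model, level):
        """Eigen-oracle monotonicity: softening any link strictly lowers the
        fundamental resonance."""
        altered = sh.apply_alteration(default_model, sh.Alteration(level, 0.5))
        assert altered.natural_frequencies()[0] < default_model.natural_frequencies()[0]


class TestSimulateRecording:
    def test_zero_force_zero_noise_gives_zero_output(self, noiseless_model, small_cfg):
        rec = sh.simulate_recording(
            noiseless_model, np.zeros(small_cfg.n_samples), small_cfg
        )
        for ch in rec.accel.values():
            np.testing.assert_array_equal(ch, 0.0)

    def test_superposition(self, noiseless_model, small_cfg):
        """Linearity: response to f1+f2 equals the sum of responses."""
        f1 = sh.generate_excitation(small_cfg)
        f2 = sh.generate_excitation(dataclasses.replace(small_cfg, seed=99))
        r1 = sh.simulate_recording(noiseless_model, f1, small_cfg)
        r2 = sh.simulate_recording(noiseless_model, f2, small_cfg)
        r12 = sh.simulate_recording(noiseless_model, f1 + f2, small_cfg)
        for s in r12.sensors:
            np.testing.assert_allclose(r12.accel[s], r1.accel[s] + r2.accel[s],
                                       rtol=1e-8, atol=1e-10)

    def test_doubling_force_doubles_response(self, noiseless_model, small_cfg):
        f = sh.generate_excitation(small_cfg)
        r1 = sh.simulate_recording(noiseless_model, f, small_cfg)
        r2 = sh.simulate_recording(noiseless_model, 2 * f, small_cfg)
        for s in r1.sensors:
            np.testing.assert_allclose(r2.accel[s], 2 * r1.accel[s],
                                       rtol=1e-8, atol=1e-12)

    def test_noise_reproducible_from_seed(self, default_model, small_cfg):
        f = sh.generate_excitation(small_cfg)
        r1 = sh.simulate_recording(default_model, f, small_cfg, noise_seed=5)
        r2 = sh.simulate_recording(default_model, f, small_cfg, noise_seed=5)
        r3 = sh.simulate_recording(default_model, f, small_cfg, noise_seed=6)
        for s in r1.sensors:
            np.testing.assert_array_equal(r1.accel[s], r2.accel[s])
        assert not np.allclose(r1.accel["L1"], r3.accel["L1"])

    def test_sampling_mismatch_rejected(self, default_model, small_cfg):
        with pytest.raises(ConfigurationError):
            sh.simulate_recording(default_model, np.zeros(123), small_cfg)

    def test_single_mass_resonance_matches_closed_form(self):
        """1-DOF reduction: the simulated FRF magnitude peaks within one
        frequency bin of (1/2pi) sqrt(k/m)."""
        model = single_mass_model(f0_hz=350.0)
        cfg = sh.ExcitationConfig(seed=3)
        rec = sh.simulate_recording(model, sh.generate_excitation(cfg), cfg)
        pulse = slice(0, 5000)
        F = np.fft.rfft(rec.force[pulse])
        A = np.fft.rfft(rec.accel["L1"][pulse])
        freqs = np.fft.rfftfreq(5000, d=1 / 5000.0)
        band = (freqs >= 1) & (freqs <= 2000)
        frf = np.abs(A[band] / F[band])
        f_peak = freqs[band][np.argmax(frf)]
        f0 = np.sqrt(model.ground_stiffness / model.masses[0]) / (2 * np.pi)
        assert abs(f_peak - f0) <= 1.0

    def test_response_rms_non_increasing_with_distance(self, noiseless_model, default_cfg):
        """Attenuation ordering: per-sensor response RMS falls from L1 to L5."""
        rec = sh.simulate_recording(
            noiseless_model, sh.generate_excitation(default_cfg), default_cfg
        )
        rms = [np.sqrt(np.mean(rec.accel[s] ** 2)) for s in ("L1", "L2", "L3", "L4", "L5")]
        assert all(a >= b for a, b in zip(rms, rms[1:]))

    def test_frf_peaks_match_eigen_oracle(self, noiseless_model, default_cfg):
        """The simulated chain's FRF global maximum lies within one bin of an
        undamped natural frequency from the eigen decomposition."""
        rec = sh.simulate_recording(
            noiseless_model, sh.generate_excitation(default_cfg), default_cfg
        )
        spec = sh.analyze_recording(rec, kernel_bins=1)
        nat = noiseless_model.natural_frequencies()
        for i in range(len(spec.sensors)):
            f_peak = spec.frequencies[np.argmax(spec.frf[i])]
            assert np.min(np.abs(nat - f_peak)) <= 1.0


class TestTwinCohort:
    def test_empty_cohort(self):
        cohort = sh.generate_twin_cohort(0, 0, seed=1)
        assert cohort.recordings == [] and cohort.members == []

    def test_counting_contract(self, small_cfg):
        cohort = sh.generate_twin_cohort(5, 5, cfg=small_cfg, seed=1)
        assert len(cohort.recordings) == 60          # 10 pairs x 2 twins x 3 trials
        assert len(cohort.members) == 20
        assert sum(m.altered for m in cohort.members) == 5
        for m in cohort.members:
            assert len(cohort.recordings_for(m.subject_id)) == 3

    def test_reproducible_from_seed(self, small_cfg):
        a = sh.generate_twin_cohort(1, 1, cfg=small_cfg, seed=42)
        b = sh.generate_twin_cohort(1, 1, cfg=small_cfg, seed=42)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.force, rb.force)
            for s in ra.sensors:
                np.testing.assert_array_equal(ra.accel[s], rb.accel[s])

    def test_zero_variability_twins_identical(self, small_cfg):
        cohort = sh.generate_twin_cohort(
            1, 0, variability=0.0, cfg=small_cfg, seed=3,
            base_model=sh.build_spine_model(noise_rms=0.0),
        )
        t1 = cohort.recordings_for("pair01_t1")
        t2 = cohort.recordings_for("pair01_t2")
        for ra, rb in zip(t1, t2):
            for s in ra.sensors:
                np.testing.assert_allclose(ra.accel[s], rb.accel[s], atol=1e-12)

    def test_discordant_twin_carries_alteration_ground_truth(self, small_cfg):
        cohort = sh.generate_twin_cohort(1, 2, cfg=small_cfg, seed=5)
        altered = [m for m in cohort.members if m.altered]
        assert [m.subject_id for m in altered] == ["pair02_t2", "pair03_t2"]
        assert all(m.alteration_level == "L1" for m in altered)
        concordant = [m for m in cohort.members if m.group == "Concordant"]
        assert all(not m.altered for m in concordant)
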