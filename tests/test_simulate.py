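"""Stochastic release simulator, presets, spike stage and calibrators."""

import dataclasses

import numpy as np
import pytest

from synaptrain import (
    CalibrationError,
    ConfigurationError,
    Recording,
    SimResult,
    SpikeModelParams,
    StimulusProtocol,
    SynapseParams,
    ValidationError,
    calibrate_refill,
    calibrate_spike_threshold,
    failure_mask_from_releases,
    make_preset,
    preset_table_yaml,
    quantal_gamma_params,
    simulate_quantal_condition,
    simulate_spike_response,
    simulate_train,
)
from synaptrain.presets import (
    CD_FAILURE_RATE,
    N_SITES,
    QUANTAL_MEAN_PA,
    QUANTAL_MEDIAN_PA,
    TRAIN_20HZ_100,
    cd_p0,
    success_mixture_weights,
)
from synaptrain.simulate import facilitation_factors


def small_params(**overrides):
    defaults = dict(
        n_sites=10, p0=0.1, facil_increment=0.0, facil_tau_s=0.4,
        pool_size=10, refill_rate=np.inf, quantal_shape=4.0,
        quantal_scale=10.0, noise_sd_pA=0.0,
    )
    defaults.update(overrides)
    return SynapseParams(**defaults)


class TestPresets:
    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            make_preset("KO")

    def test_quantal_regime_p0_inverts_failure_rate(self):
        # (1 - p0)^20 = 0.88  =>  p0 = 1 - 0.88**(1/20)
        p = make_preset("Cd")
        assert p.p0 == pytest.approx(0.006371, abs=1e-6)
        assert (1 - p.p0) ** N_SITES == pytest.approx(CD_FAILURE_RATE, rel=1e-12)
        assert p.facil_increment == 0.0

    def test_quantal_gamma_matches_measured_success_statistics(self):
        """The success-amplitude mixture has the measured mean and median."""
        from scipy import stats

        k, theta = quantal_gamma_params()
        w = success_mixture_weights()
        counts = np.arange(1, w.size + 1)
        mean = float((w * counts * k * theta).sum())
        assert mean == pytest.approx(QUANTAL_MEAN_PA, rel=1e-9)
        median_cdf = float(
            (w * stats.gamma.cdf(QUANTAL_MEDIAN_PA, a=k * counts, scale=theta)).sum()
        )
        assert median_cdf == pytest.approx(0.5, abs=1e-9)

    def test_genotypes_share_quantal_parameters(self):
        wt, ps = make_preset("WT"), make_preset("PSKO")
        assert wt.quantal_shape == ps.quantal_shape
        assert wt.quantal_scale == ps.quantal_scale
        assert ps.facil_increment < wt.facil_increment
        assert ps.refill_rate < wt.refill_rate

    def test_preset_table_yaml_parses(self):
        import yaml

        table = yaml.safe_load(preset_table_yaml())
        assert set(table) == {"spike_model", "WT", "PSKO", "Cd"}
        assert table["Cd"]["refill_rate"] is None  # instant refill


class TestSimulateTrain:
    def test_seed_determinism(self):
        p = make_preset("WT")
        proto = StimulusProtocol(20.0, 10)
        a = simulate_train(p, proto, 5, seed=7)
        b = simulate_train(p, proto, 5, seed=7)
        np.testing.assert_array_equal(a.recording.sweeps, b.recording.sweeps)
        np.testing.assert_array_equal(a.vesicles_released, b.vesicles_released)

    def test_occupancy_and_release_bounds(self):
        p = make_preset("PSKO")
        sim = simulate_train(p, StimulusProtocol(40.0, 50), 10, seed=1)
        assert sim.vesicles_released.min() >= 0
        assert np.all(sim.vesicles_released <= sim.occupancy_pre)
        assert np.all(sim.occupancy_pre <= p.pool_size)

    def test_zero_refill_conserves_pool(self):
        p = small_params(refill_rate=0.0, p0=0.3)
        sim = simulate_train(p, StimulusProtocol(20.0, 40), 50, seed=2)
        assert np.all(sim.vesicles_released.sum(axis=1) <= p.pool_size)

    def test_no_facilitation_instant_refill_is_flat_binomial(self):
        """With a=0 and instant refill, releases are i.i.d. binomial(M, p0)."""
        p = small_params(pool_size=20, n_sites=20, p0=0.1)
        sim = simulate_train(p, StimulusProtocol(20.0, 10), 2000, seed=3)
        rel = sim.vesicles_released
        mc_sigma = np.sqrt(20 * 0.1 * 0.9 / rel.size)
        assert abs(rel.mean() - 2.0) < 3 * mc_sigma
        # per-stimulus mean amplitude has no trend
        col_means = sim.recording.sweeps.mean(axis=0)
        slope = np.polyfit(np.arange(10), col_means, 1)[0]
        assert abs(slope) < 0.5

    def test_single_site_binomial_oracle(self):
        """One site, p0=0.1, one stimulus: failures ~ 90% (analytic binomial)."""
        p = small_params(n_sites=1, pool_size=1, p0=0.1)
        sim = simulate_train(p, StimulusProtocol(1.0, 1), 10_000, seed=4)
        failures = (sim.vesicles_released == 0).mean()
        assert abs(failures - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10_000)

    def test_facilitation_factors_monotone_in_increment_and_frequency(self):
        proto = StimulusProtocol(20.0, 10)
        f1 = facilitation_factors(small_params(facil_increment=0.5), proto)
        f2 = facilitation_factors(small_params(facil_increment=1.0), proto)
        assert np.all(f2 >= f1)
        f_fast = facilitation_factors(
            small_params(facil_increment=0.5), StimulusProtocol(40.0, 10)
        )
        assert np.all(f_fast >= f1)

    def test_amplitude_is_noise_clipped_magnitude(self):
        p = small_params(p0=0.0, noise_sd_pA=5.0)
        sim = simulate_train(p, StimulusProtocol(20.0, 5), 100, seed=5)
        assert sim.recording.sweeps.min() >= 0.0
        assert np.all(sim.vesicles_released == 0)


class TestQuantalCondition:
    def test_requires_facilitation_off(self):
        with pytest.raises(ValidationError):
            simulate_quantal_condition(make_preset("WT"), 10, seed=0)

    def test_zero_p0_all_failures(self):
        p = small_params(p0=0.0)
        sim = simulate_quantal_condition(p, 200, seed=0)
        assert failure_mask_from_releases(sim).failure_rate == 1.0

    def test_failure_rate_within_binomial_ci(self):
        sim = simulate_quantal_condition(make_preset("Cd"), 2000, seed=0)
        rate = failure_mask_from_releases(sim).failure_rate
        ci99 = 2.576 * np.sqrt(0.88 * 0.12 / 2000)
        assert abs(rate - 0.88) < ci99

    def test_success_mean_near_single_vesicle_mean(self):
        """Sparse successes average close to the quantal gamma mean."""
        p = small_params(n_sites=1, pool_size=1, p0=0.05)
        sim = simulate_quantal_condition(p, 20_000, seed=6)
        amps = sim.recording.sweeps[sim.vesicles_released > 0]
        assert amps.mean() == pytest.approx(40.0, rel=0.03)


class TestSpikeStage:
    @staticmethod
    def constant_amplitude_sim(amp, n_stim=10, n_sweeps=4, freq=20.0):
        proto = StimulusProtocol(freq, n_stim)
        rec = Recording(np.full((n_sweeps, n_stim), amp), proto)
        zeros = np.zeros((n_sweeps, n_stim), dtype=int)
        return SimResult(rec, zeros, zeros)

    def test_near_zero_threshold_spikes_everywhere(self):
        sim = self.constant_amplitude_sim(50.0)
        spk = SpikeModelParams(tau_m_s=0.1, weight=1.0, threshold=1e-9)
        assert simulate_spike_response(sim, spk).all()

    def test_infinite_threshold_never_spikes(self):
        sim = self.constant_amplitude_sim(50.0)
        spk = SpikeModelParams(tau_m_s=0.1, weight=1.0, threshold=np.inf)
        assert not simulate_spike_response(sim, spk).any()

    def test_geometric_series_saturation_oracle(self):
        """Constant drive saturates at V = w*A / (1 - exp(-dt/tau))."""
        amp, tau, freq = 40.0, 0.2, 20.0
        decay = np.exp(-1 / (freq * tau))
        v_inf = amp / (1 - decay)
        sim = self.constant_amplitude_sim(amp, n_stim=200, freq=freq)
        above = SpikeModelParams(tau_m_s=tau, weight=1.0, threshold=v_inf * 1.01)
        assert not simulate_spike_response(sim, above).any()
        below = SpikeModelParams(tau_m_s=tau, weight=1.0, threshold=v_inf * 0.99)
        assert simulate_spike_response(sim, below).any()

    def test_membrane_noise_reproducible_from_seed(self):
        sim = self.constant_amplitude_sim(50.0)
        spk = SpikeModelParams(tau_m_s=0.1, weight=1.0, threshold=80.0,
                               v_noise_sd=30.0)
        a = simulate_spike_response(sim, spk, seed=9)
        b = simulate_spike_response(sim, spk, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCalibrators:
    def test_zero_target_gives_zero_refill(self):
        p = make_preset("WT")
        assert calibrate_refill(p, TRAIN_20HZ_100, 0.0) == 0.0

    def test_refill_rate_monotone_in_target(self):
        p = make_preset("WT")
        r7 = calibrate_refill(p, TRAIN_20HZ_100, 7.0, n_sweeps=32, seed=0)
        r13 = calibrate_refill(p, TRAIN_20HZ_100, 13.0, n_sweeps=32, seed=0)
        assert 0 < r7 < r13

    def test_unattainable_target_reports_bracket(self):
        p = make_preset("WT")
        with pytest.raises(CalibrationError) as err:
            calibrate_refill(p, TRAIN_20HZ_100, 5000.0)
        assert err.value.bracket is not None

    def test_calibrated_refill_reproduces_target_on_fresh_seed(self):
        p = make_preset("WT")
        r = calibrate_refill(p, TRAIN_20HZ_100, 13.0, n_sweeps=64, seed=0)
        p = dataclasses.replace(p, refill_rate=r)
        sim = simulate_train(p, TRAIN_20HZ_100, 200, seed=12345)
        steady = sim.vesicles_released[:, 50:].mean()
        assert steady == pytest.approx(13.0, rel=0.04)

    def test_threshold_calibration_limits_and_monotonicity(self):
        p = make_preset("WT")
        proto = StimulusProtocol(20.0, 20)
        spk = SpikeModelParams(tau_m_s=0.35, weight=1.0, threshold=500.0,
                               v_noise_sd=100.0)
        th_easy = calibrate_spike_threshold(
            p, spk, proto, (10, 0.95), n_sweeps=512, seed=0
        )
        th_hard = calibrate_spike_threshold(
            p, spk, proto, (10, 0.30), n_sweeps=512, seed=0
        )
        assert th_easy < th_hard  # higher target fraction -> lower threshold
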