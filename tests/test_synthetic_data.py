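import numpy as np
import pytest

from mea_ephys.burst_detection import detect_bursts
from mea_ephys.synthetic_data import (
    BurstConfig,
    DischargeConfig,
    SimulationConfig,
    SpikeConfig,
    default_effect_table,
    make_spike_template,
    resolve_effects,
    score_detection,
    simulate_channel,
    simulate_experiment,
)

FS = 30000.0


def quiet_config(**kw):
    """Config with only lone spikes active unless overridden."""
    base = dict(
        fs=FS,
        duration_s=60.0,
        burst=BurstConfig(rate_per_min=0.0),
        discharge=DischargeConfig(rate_per_min=0.0),
        line_noise_uV=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSpikeTemplate:
    def test_peak_amplitude_as_requested(self):
        tpl = make_spike_template(FS, 100.0)
        assert np.max(np.abs(tpl)) == pytest.approx(100.0)

    def test_biphasic_and_zero_mean(self):
        tpl = make_spike_template(FS, 100.0)
        assert tpl.max() > 0 and tpl.min() < 0
        assert abs(tpl.sum()) < 1e-9 * np.abs(tpl).sum()

    def test_energy_concentrated_in_spike_band(self):
        tpl = make_spike_template(FS, 100.0)
        spec = np.abs(np.fft.rfft(tpl, n=4096)) ** 2
        freqs = np.fft.rfftfreq(4096, 1 / FS)
        band = (freqs >= 600) & (freqs <= 6000)
        assert spec[band].sum() / spec.sum() > 0.70

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            make_spike_template(8000.0, 100.0)


class TestConditionEffects:
    def test_factor_products_and_interaction(self):
        eff = resolve_effects("GLUT1-DS/5mM/Veh")
        table = default_effect_table()
        expected = (
            table["GLUT1-DS"].spike_rate
            * table["5mM"].spike_rate
            * table["Veh"].spike_rate
            * table["GLUT1-DS+5mM"].spike_rate
        )
        assert eff.spike_rate == pytest.approx(expected)
        # interaction entry must NOT fire for the healthy genotype
        healthy = resolve_effects("healthy/5mM/Veh")
        assert healthy.spike_rate == pytest.approx(1.0)

    def test_unknown_factor_rejected(self):
        with pytest.raises(KeyError):
            resolve_effects("healthy/42mM")


class TestSimulateChannel:
    def test_poisson_spike_count_and_determinism(self):
        cfg = quiet_config()
        for seed in [0, 1, 2, 3]:
            rng = np.random.default_rng(seed)
            _, truth = simulate_channel(cfg, "healthy/25mM/Veh", rng)
            assert abs(truth.spike_times_s.size - 120) <= 33
        s1, t1 = simulate_channel(cfg, "healthy/25mM/Veh", np.random.default_rng(9))
        s2, t2 = simulate_channel(cfg, "healthy/25mM/Veh", np.random.default_rng(9))
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(t1.spike_times_s, t2.spike_times_s)

    def test_ttx_like_silencing(self):
        cfg = quiet_config()
        cfg.effects["TTX"].spike_rate = 0.0
        cfg.effects["TTX"].burst_rate = 0.0
        _, truth = simulate_channel(cfg, "TTX", np.random.default_rng(0))
        assert truth.spike_times_s.size == 0
        assert truth.burst_intervals_s == []

    def test_injected_bursts_satisfy_the_burst_rule_exactly(self):
        cfg = SimulationConfig(duration_s=60.0)
        for cond in ["healthy/25mM/Veh", "GLUT1-DS/5mM/Veh", "healthy/25mM/KCl"]:
            _, truth = simulate_channel(cfg, cond, np.random.default_rng(5))
            for run in truth.burst_spike_times_s:
                assert run.size >= 5
                assert np.max(np.diff(run)) <= 0.050
                assert np.min(np.diff(run)) >= 0.005
                # the detector's grouping recovers each injected burst as-is
            all_spikes = truth.spike_times_s
            detected = detect_bursts(all_spikes)
            assert len(detected) == len(truth.burst_intervals_s)

    def test_isi_scaling_that_breaks_the_rule_is_rejected(self):
        cfg = SimulationConfig()
        cfg.effects["GLUT1-DS"].burst_isi = 5.0  # would push gaps past 50 ms
        with pytest.raises(ValueError, match="50 ms"):
            simulate_channel(cfg, "GLUT1-DS", np.random.default_rng(0))


class TestSimulateExperiment:
    def test_mea_layout(self):
        cfg = SimulationConfig(duration_s=2.0)
        rec, truth = simulate_experiment(cfg, "healthy/25mM/Veh")
        assert rec.n_channels == 32
        assert rec.channel_ids[0] == "S1-E1" and rec.channel_ids[-1] == "S4-E8"
        assert set(rec.site_of_channel.values()) == {1, 2, 3, 4}
        assert rec.duration_s == pytest.approx(2.0)
        assert set(truth.channels) == set(rec.channel_ids)

    def test_glucose_drop_raises_truth_spike_rate_only_in_glut1(self):
        cfg = SimulationConfig(duration_s=60.0, seed=11)
        rates = {}
        for cond in [
            "GLUT1-DS/25mM/Veh", "GLUT1-DS/5mM/Veh",
            "healthy/25mM/Veh", "healthy/5mM/Veh",
        ]:
            _, truth = simulate_experiment(cfg, cond)
            rates[cond] = truth.spike_rate_hz()
        glut_ratio = rates["GLUT1-DS/5mM/Veh"] / rates["GLUT1-DS/25mM/Veh"]
        healthy_ratio = rates["healthy/5mM/Veh"] / rates["healthy/25mM/Veh"]
        assert 1.35 <= glut_ratio <= 1.65
        assert 0.9 <= healthy_ratio <= 1.1

    def test_reproducible_per_seed_and_independent_across_arms(self):
        cfg = SimulationConfig(duration_s=2.0, seed=7)
        rec1, _ = simulate_experiment(cfg, "healthy/25mM/Veh")
        rec2, _ = simulate_experiment(cfg, "healthy/25mM/Veh")
        np.testing.assert_array_equal(rec1.data, rec2.data)
        rec3, _ = simulate_experiment(cfg, "healthy/25mM/KCl")
        assert not np.array_equal(rec1.data, rec3.data)


class TestScoreDetection:
    def test_perfect_detection(self):
        t = np.array([1.0, 2.0, 3.0])
        s = score_detection(t, t)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_detection_has_zero_recall(self):
        s = score_detection(np.array([1.0, 2.0]), np.array([]))
        assert s.recall == 0.0 and s.f1 == 0.0

    def test_matches_optimal_bipartite_matching_on_small_lists(self):
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(0)
        for _ in range(100):
            truth = np.sort(rng.uniform(0, 1, rng.integers(1, 6)))
            det = np.sort(
                np.concatenate(
                    [truth + rng.normal(0, 0.002, truth.size),
                     rng.uniform(0, 1, rng.integers(0, 3))]
                )
            )
            greedy = score_detection(truth, det, tol_s=0.002).n_matched
            # oracle: maximum one-to-one matching via assignment on the
            # within-tolerance adjacency matrix
            adj = (np.abs(det[None, :] - truth[:, None]) <= 0.002).astype(float)
            rows, cols = linear_sum_assignment(-adj)
            best = int(adj[rows, cols].sum())
            assert greedy == best
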