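import numpy as np
import pytest

from mea_ephys.epileptiform import (
    DB_EPS,
    DischargeParams,
    burst_psd,
    compute_timefreq,
    detect_discharges,
    normalize_timefreq,
    preprocess_lfp,
)
from mea_ephys.filters import decimate_to
from mea_ephys.signal_io import Recording

FS = 30000.0


def make_rec(x, fs=FS):
    return Recording(np.asarray(x, dtype=float)[None, :], fs, ["ch0"])


def packet(fs, freq, dur, amp, center_s, n_total):
    """Gaussian-windowed sinusoid embedded in an n_total-sample zero trace."""
    x = np.zeros(n_total)
    n = int(dur * fs)
    t = (np.arange(n) - n / 2) / fs
    atom = amp * np.exp(-(t**2) / (2 * (dur / 6) ** 2)) * np.cos(2 * np.pi * freq * t)
    i = int(center_s * fs) - n // 2
    x[i : i + n] += atom
    return x


class TestPreprocessLfp:
    def test_line_noise_suppressed(self):
        # steady-state: central half, clear of the high-Q notch edge ringing
        t = np.arange(int(10 * FS)) / FS
        rec = make_rec(np.sin(2 * np.pi * 50 * t))
        out = preprocess_lfp(rec)
        n = out.n_samples
        assert np.std(out.data[0][n // 4 : -n // 4]) < 1e-3 * np.std(rec.data[0])

    def test_passband_tone_survives(self):
        t = np.arange(int(5 * FS)) / FS
        out = preprocess_lfp(make_rec(np.sin(2 * np.pi * 20 * t)))
        amp = np.sqrt(2) * np.std(out.data[0][int(FS) : -int(FS)])
        assert 0.89 <= amp <= 1.0

    def test_spike_band_tone_rejected(self):
        t = np.arange(int(5 * FS)) / FS
        out = preprocess_lfp(make_rec(np.sin(2 * np.pi * 1000 * t)))
        assert np.std(out.data[0]) < 0.05

    def test_output_dc_removed(self):
        # a 5 uV offset must vanish; edges carry the band-pass step response,
        # so check the steady-state (central) portion
        rng = np.random.default_rng(0)
        out = preprocess_lfp(make_rec(rng.normal(5.0, 10.0, int(5 * FS))))
        n = out.n_samples
        assert abs(np.mean(out.data[0][n // 4 : -n // 4])) < 0.05


class TestDetectDischarges:
    def test_flat_signal_yields_no_events(self):
        assert detect_discharges(make_rec(np.zeros(60000)))["ch0"] == []

    def test_sub_refractory_events_merge(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.5, int(10 * FS))
        x += packet(FS, 20.0, 0.04, 30.0, 5.000, x.size)
        x += packet(FS, 20.0, 0.04, 30.0, 5.030, x.size)  # 30 ms later
        events = detect_discharges(make_rec(x))["ch0"]
        assert len(events) == 1

    def test_supra_refractory_events_stay_distinct(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.5, int(10 * FS))
        x += packet(FS, 20.0, 0.04, 30.0, 5.000, x.size)
        x += packet(FS, 20.0, 0.04, 30.0, 5.070, x.size)  # 70 ms later
        events = detect_discharges(make_rec(x))["ch0"]
        assert len(events) == 2

    def test_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, int(30 * FS))
        for c in np.arange(2.0, 28.0, 2.5):
            x += packet(FS, 15.0, 0.1, rng.uniform(3, 12), c, x.size)
        rec = make_rec(x)
        counts = [
            len(detect_discharges(rec, DischargeParams(k_sigma=k))["ch0"])
            for k in [2.0, 3.0, 4.5, 6.0, 8.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_false_event_rate_on_filtered_noise(self):
        rng = np.random.default_rng(4)
        rec = preprocess_lfp(make_rec(rng.normal(0, 10.0, int(60 * FS))))
        events = detect_discharges(rec)["ch0"]
        assert len(events) / 60.0 < 0.5


class TestTimeFrequency:
    def test_pure_tone_peaks_at_nearest_grid_frequency(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        tf = compute_timefreq(np.sin(2 * np.pi * 20 * t), fs)
        marginal = tf.power.mean(axis=0)
        nearest = tf.freqs_hz[np.argmin(np.abs(tf.freqs_hz - 20.0))]
        assert tf.freqs_hz[np.argmax(marginal)] == pytest.approx(nearest)

    def test_zero_signal_power_is_the_epsilon_floor(self):
        tf = compute_timefreq(np.zeros(500), 100.0)
        np.testing.assert_allclose(tf.power, 10 * np.log10(DB_EPS))

    def test_amplitude_doubling_adds_six_db(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        tf1 = compute_timefreq(np.sin(2 * np.pi * 20 * t), fs)
        tf2 = compute_timefreq(2 * np.sin(2 * np.pi * 20 * t), fs)
        row = np.argmax(tf1.power.mean(axis=0))
        diff = tf2.power.mean(axis=0)[row] - tf1.power.mean(axis=0)[row]
        assert diff == pytest.approx(20 * np.log10(2), abs=0.05)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_timefreq(np.zeros(100), 100.0)


class TestNormalizeTimefreq:
    def _noise_map(self, seed=0, dur=60.0):
        rng = np.random.default_rng(seed)
        return compute_timefreq(rng.normal(0, 1.0, int(dur * 100)), 100.0)

    def test_stationary_noise_mostly_floored(self):
        tf = self._noise_map()
        z = normalize_timefreq(tf, (0.0, 60.0))
        assert (z.power == 2.0).mean() >= 0.95
        assert z.power.min() >= 2.0

    def test_baseline_zmap_prefloor_mean_near_zero(self):
        tf = self._noise_map(seed=1)
        z = normalize_timefreq(tf, (0.0, 60.0), floor_z=None)
        assert np.all(np.abs(z.power.mean(axis=0)) < 0.1)

    def test_injected_packet_stands_out_at_its_frequency_and_time(self):
        fs = 100.0
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, int(60 * fs))
        n = int(0.5 * fs)
        t = (np.arange(n) - n / 2) / fs
        x[int(40 * fs) - n // 2 : int(40 * fs) + (n - n // 2)] += (
            10 * np.exp(-(t**2) / (2 * 0.08**2)) * np.cos(2 * np.pi * 20 * t)
        )
        z = normalize_timefreq(compute_timefreq(x, fs), (0.0, 10.0))
        row = np.argmin(np.abs(z.freqs_hz - 20.0))
        peak_time = z.times_s[np.argmax(z.power[:, row])]
        assert z.power[:, row].max() > 2.0
        assert abs(peak_time - 40.0) <= 0.1

    def test_zero_baseline_variance_names_the_frequency(self):
        tf = compute_timefreq(np.zeros(1000), 100.0)
        with pytest.raises(ValueError, match="Hz"):
            normalize_timefreq(tf, (0.0, 10.0))


class TestBurstPSD:
    def test_zero_segment_gives_zero_psd(self):
        res = burst_psd(np.zeros(int(0.5 * FS)), FS)
        assert np.all(res.psd == 0.0)
        assert res.band_mean_power == 0.0

    def test_power_scales_with_amplitude_squared(self):
        t = np.arange(int(2 * FS)) / FS
        a = burst_psd(np.sin(2 * np.pi * 20 * t), FS)
        b = burst_psd(2 * np.sin(2 * np.pi * 20 * t), FS)
        assert b.band_mean_power / a.band_mean_power == pytest.approx(4.0, rel=0.05)

    def test_welch_satisfies_parseval(self):
        from scipy.signal import welch

        rng = np.random.default_rng(5)
        x = rng.normal(0, 3.0, int(4 * FS))
        nper = int(0.256 * FS)
        freqs, psd = welch(x, fs=FS, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend=False)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_frequencies_restricted_to_band(self):
        res = burst_psd(np.random.default_rng(6).normal(0, 1, int(1 * FS)), FS)
        assert res.freqs_hz.min() >= 4.0 and res.freqs_hz.max() <= 40.0

    def test_short_segment_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="periodogram"):
            res = burst_psd(np.ones(int(0.1 * FS)), FS)
        assert np.all(np.isfinite(res.psd))
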