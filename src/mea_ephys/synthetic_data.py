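"""Ground-truthed synthetic MEA recordings.

Emulates the phenomenology of organoid recordings on a 4-site x 8-electrode
MEA biochip: Gaussian background noise, 50 Hz line contamination, ~100 uV
biphasic spikes with spectral energy in 600-6,000 Hz, spike bursts obeying the
>=5 spikes / <=50 ms rule exactly, and epileptiform 4-40 Hz wave packets.
Condition effects (KCl depolarisation, TTX sodium-channel block, GLUT1-DS
genotype, 25 vs 5 mM glucose) act as multipliers on event rates, burst
geometry and low-frequency power, so every pipeline stage can be scored
against a known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_io import Recording

_MIN_BURST_SPIKES = 5
#: spikes closer than this are unresolvable by a 5 ms cut-out detector
_SPIKE_DEAD_TIME_S = 0.006
#: lone spikes keep this distance from burst spikes so they cannot extend a burst
_BURST_GUARD_S = 0.055


@dataclass
class SpikeConfig:
    rate_hz: float = 2.0  # lone (non-burst) spikes per second
    amplitude_uV: float = 100.0
    width_ms: float = 1.0


@dataclass
class BurstConfig:
    rate_per_min: float = 6.0
    spikes_per_burst: float = 8.0  # Poisson mean, floored at 5
    intra_isi_ms: tuple[float, float] = (9.0, 15.0)  # uniform range
    #: 4-40 Hz oscillation underlying each burst (epileptiform-like LFP)
    lfp_amplitude_uV: float = 20.0
    lfp_freq_hz: tuple[float, float] = (10.0, 20.0)


@dataclass
class DischargeConfig:
    rate_per_min: float = 4.0
    center_freq_hz: tuple[float, float] = (8.0, 30.0)
    duration_s: tuple[float, float] = (0.1, 0.4)
    #: kept below the 6-sigma spike threshold (60 uV at sigma=10) so slow
    #: discharges do not masquerade as fast spikes in the ground truth
    amplitude_uV: float = 35.0


@dataclass
class ConditionEffects:
    """Multiplicative condition effects. All default to 1 (no effect)."""

    spike_rate: float = 1.0
    burst_rate: float = 1.0
    burst_isi: float = 1.0  # scales intra-burst intervals (duration knob)
    burst_size: float = 1.0  # scales spikes per burst (second duration knob)
    discharge_rate: float = 1.0
    lfp_amplitude: float = 1.0  # scales the 4-40 Hz packets under bursts

    def combine(self, other: "ConditionEffects") -> "ConditionEffects":
        return ConditionEffects(
            *(a * b for a, b in zip(asdict(self).values(), asdict(other).values()))
        )


def default_effect_table() -> dict[str, ConditionEffects]:
    """Per-factor multipliers emulating the reported phenotype directions.

    * KCl depolarisation: more spikes, more but shorter bursts.
    * TTX: near-silenced activity (sodium-channel block).
    * GLUT1-DS: fewer but longer bursts with much stronger 4-40 Hz power
      and more frequent discharges.
    * Glucose drop 25 -> 5 mM stresses only the GLUT1-DS genotype (the
      ``GLUT1-DS+5mM`` interaction entry), raising spike/burst metrics.

    Magnitudes are simulator configuration chosen to make the directions
    unambiguous at n = 32 electrodes; they are not effect-size claims.
    """
    return {
        "Veh": ConditionEffects(),
        "KCl": ConditionEffects(spike_rate=2.5, burst_rate=2.0, burst_size=0.6),
        "TTX": ConditionEffects(
            spike_rate=0.05, burst_rate=0.05, burst_size=0.8, discharge_rate=0.1
        ),
        "healthy": ConditionEffects(),
        "GLUT1-DS": ConditionEffects(
            burst_rate=0.5, burst_isi=2.0, discharge_rate=2.0, lfp_amplitude=3.0
        ),
        "25mM": ConditionEffects(),
        "5mM": ConditionEffects(),
        "GLUT1-DS+5mM": ConditionEffects(
            spike_rate=1.5, burst_rate=1.5, burst_isi=1.6, burst_size=1.25
        ),
    }


@dataclass
class SimulationConfig:
    fs: float = 30000.0
    duration_s: float = 60.0
    n_sites: int = 4
    electrodes_per_site: int = 8
    noise_sigma_uV: float = 10.0
    line_noise_uV: float = 5.0  # 50 Hz amplitude
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    burst: BurstConfig = field(default_factory=BurstConfig)
    discharge: DischargeConfig = field(default_factory=DischargeConfig)
    effects: dict[str, ConditionEffects] = field(default_factory=default_effect_table)
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.n_sites * self.electrodes_per_site


@dataclass
class ChannelTruth:
    """Injected events on one channel (times in seconds)."""

    spike_times_s: np.ndarray  # all spikes, lone and in-burst
    burst_intervals_s: list[tuple[float, float]]
    burst_spike_times_s: list[np.ndarray]
    discharge_times_s: np.ndarray


@dataclass
class GroundTruth:
    channels: dict[str, ChannelTruth]
    condition: str
    config: SimulationConfig

    def spike_rate_hz(self) -> float:
        """Mean injected spike rate across channels."""
        total = sum(t.spike_times_s.size for t in self.channels.values())
        return total / (len(self.channels) * self.config.duration_s)


def resolve_effects(
    condition: str, table: dict[str, ConditionEffects] | None = None
) -> ConditionEffects:
    """Product of the per-factor effects named in a '/'-separated condition
    label, plus any '+'-keyed interaction entries whose factors are all present.

    ``resolve_effects("GLUT1-DS/5mM/Veh")`` multiplies the GLUT1-DS, 5mM and
    Veh entries and, because both of its factors are present, the
    ``GLUT1-DS+5mM`` interaction.
    """
    table = table if table is not None else default_effect_table()
    tokens = [t for t in condition.split("/") if t]
    eff = ConditionEffects()
    for tok in tokens:
        if tok not in table:
            raise KeyError(f"unknown condition factor {tok!r}")
        eff = eff.combine(table[tok])
    for key, entry in table.items():
        if "+" in key and all(part in tokens for part in key.split("+")):
            eff = eff.combine(entry)
    return eff


def make_spike_template(
    fs: float, amplitude_uV: float = 100.0, width_ms: float = 1.0
) -> np.ndarray:
    """Biphasic extracellular spike template (first derivative of a Gaussian).

    Zero-mean by construction, peak |amplitude| as requested, spectral energy
    concentrated in the 600-6,000 Hz band typical of extracellular spikes.
    """
    if fs < 12000:
        raise ValueError("fs must resolve the 6 kHz spike band (>= 12 kHz)")
    n = int(round(width_ms * 1e-3 * fs))
    if n < 6:
        raise ValueError(f"width {width_ms} ms spans only {n} samples at fs={fs}")
    # sigma = width/8 puts the spectral peak (1/(2*pi*sigma)) near 1.3 kHz
    sigma = width_ms * 1e-3 / 8.0
    t = (np.arange(n) - (n - 1) / 2) / fs
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    w = w - w.mean()
    return amplitude_uV * w / np.max(np.abs(w))


def _thin_times(
    candidates: np.ndarray, occupied: np.ndarray, guard_s: float, self_gap_s: float
) -> np.ndarray:
    """Drop candidates within guard_s of occupied times or self_gap_s of an
    already accepted candidate (greedy, earliest first)."""
    kept: list[float] = []
    occupied = np.sort(occupied)
    for t in np.sort(candidates):
        if kept and t - kept[-1] < self_gap_s:
            continue
        if occupied.size:
            k = np.searchsorted(occupied, t)
            near = []
            if k > 0:
                near.append(abs(t - occupied[k - 1]))
            if k < occupied.size:
                near.append(abs(occupied[k] - t))
            if near and min(near) < guard_s:
                continue
        kept.append(t)
    return np.asarray(kept)


def _add_template(signal: np.ndarray, template: np.ndarray, center_idx: int) -> None:
    half = template.size // 2
    start = center_idx - half
    lo, hi = max(start, 0), min(start + template.size, signal.size)
    if lo < hi:
        signal[lo:hi] += template[lo - start : hi - start]


def _gabor(fs: float, freq_hz: float, duration_s: float, amplitude_uV: float,
           phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid (sharp-wave/discharge atom)."""
    n = int(round(duration_s * fs))
    t = (np.arange(n) - (n - 1) / 2) / fs
    envelope = np.exp(-(t**2) / (2 * (duration_s / 6.0) ** 2))
    return amplitude_uV * envelope * np.cos(2 * np.pi * freq_hz * t + phase)


def simulate_channel(
    config: SimulationConfig, condition: str, rng: np.random.Generator
) -> tuple[np.ndarray, ChannelTruth]:
    """One electrode's voltage trace plus the ground truth of injected events.

    Composition: white Gaussian noise + 50 Hz sine + Poisson lone spikes +
    Poisson burst trains (each satisfying the >=5 spikes / <=50 ms rule
    exactly, riding on a 4-40 Hz LFP packet) + Poisson discharge atoms, with
    all rates/amplitudes scaled by the condition's multipliers.
    """
    eff = resolve_effects(condition, config.effects)
    n = int(round(config.duration_s * config.fs))
    t_grid = np.arange(n) / config.fs
    signal = rng.normal(0.0, config.noise_sigma_uV, n)
    if config.line_noise_uV > 0:
        signal += config.line_noise_uV * np.sin(
            2 * np.pi * 50.0 * t_grid + rng.uniform(0, 2 * np.pi)
        )

    template = make_spike_template(
        config.fs, config.spike.amplitude_uV, config.spike.width_ms
    )
    margin = 0.05  # keep events off the very edges

    # --- bursts -----------------------------------------------------------
    isi_lo, isi_hi = (v * 1e-3 * eff.burst_isi for v in config.burst.intra_isi_ms)
    if isi_hi > 0.050:
        raise ValueError(
            f"scaled intra-burst ISI range reaches {isi_hi * 1e3:.1f} ms; the burst "
            "definition requires gaps <= 50 ms"
        )
    if isi_lo < _SPIKE_DEAD_TIME_S:
        raise ValueError(
            f"scaled intra-burst ISI floor {isi_lo * 1e3:.1f} ms is below the "
            "5 ms spike dead-time; bursts would be undetectable"
        )
    n_bursts = rng.poisson(
        config.burst.rate_per_min / 60.0 * eff.burst_rate * config.duration_s
    )
    burst_spike_times: list[np.ndarray] = []
    mean_size = config.burst.spikes_per_burst * eff.burst_size
    max_span = (4 * mean_size) * isi_hi + 0.2  # generous per-burst footprint
    starts = np.sort(rng.uniform(margin, max(config.duration_s - max_span, margin), n_bursts))
    last_end = -np.inf
    for s in starts:
        if s - last_end < 2 * _BURST_GUARD_S:
            continue  # bursts must stay separated to remain distinct events
        n_sp = max(_MIN_BURST_SPIKES, int(rng.poisson(mean_size)))
        isis = rng.uniform(isi_lo, isi_hi, n_sp - 1)
        times = s + np.concatenate([[0.0], np.cumsum(isis)])
        if times[-1] > config.duration_s - margin:
            continue
        burst_spike_times.append(times)
        last_end = times[-1]
        # LFP packet spanning the burst
        span = times[-1] - times[0] + 0.1
        center = (times[0] + times[-1]) / 2
        packet = _gabor(
            config.fs,
            rng.uniform(*config.burst.lfp_freq_hz),
            span,
            config.burst.lfp_amplitude_uV * eff.lfp_amplitude,
            rng.uniform(0, 2 * np.pi),
        )
        _add_template(signal, packet, int(round(center * config.fs)))

    all_burst_spikes = (
        np.concatenate(burst_spike_times) if burst_spike_times else np.empty(0)
    )

    # --- lone spikes ------------------------------------------------------
    n_lone = rng.poisson(config.spike.rate_hz * eff.spike_rate * config.duration_s)
    lone = rng.uniform(margin, config.duration_s - margin, n_lone)
    lone = _thin_times(lone, all_burst_spikes, _BURST_GUARD_S, _SPIKE_DEAD_TIME_S)

    spike_times = np.sort(np.concatenate([lone, all_burst_spikes]))
    for st in spike_times:
        _add_template(signal, template, int(round(st * config.fs)))

    # --- discharges -------------------------------------------------------
    n_disc = rng.poisson(
        config.discharge.rate_per_min / 60.0 * eff.discharge_rate * config.duration_s
    )
    disc = np.sort(rng.uniform(0.5, max(config.duration_s - 0.5, 0.5), n_disc))
    disc = _thin_times(disc, np.empty(0), 0.0, 1.0)  # >= 1 s apart
    for dt in disc:
        # discharge amplitude is deliberately NOT scaled by lfp_amplitude:
        # the genotype power effect lives in the burst LFP packets, and slow
        # atoms must stay below the fast-spike threshold
        atom = _gabor(
            config.fs,
            rng.uniform(*config.discharge.center_freq_hz),
            rng.uniform(*config.discharge.duration_s),
            config.discharge.amplitude_uV,
            rng.uniform(0, 2 * np.pi),
        )
        _add_template(signal, atom, int(round(dt * config.fs)))

    truth = ChannelTruth(
        spike_times_s=spike_times,
        burst_intervals_s=[(float(b[0]), float(b[-1])) for b in burst_spike_times],
        burst_spike_times_s=burst_spike_times,
        discharge_times_s=disc,
    )
    return signal, truth


def _channel_seed(seed: int, condition: str, index: int) -> list[int]:
    return [seed, zlib.crc32(condition.encode()) & 0x7FFFFFFF, index]


def simulate_experiment(
    config: SimulationConfig, condition: str = "healthy/25mM/Veh"
) -> tuple[Recording, GroundTruth]:
    """Simulate one condition arm: 4 sites x 8 electrodes by default.

    Channel streams are seeded from ``(config.seed, condition, channel)``, so
    runs are bit-reproducible and different arms are statistically
    independent.
    """
    channel_ids = [
        f"S{s + 1}-E{e + 1}"
        for s in range(config.n_sites)
        for e in range(config.electrodes_per_site)
    ]
    data = np.empty((len(channel_ids), int(round(config.duration_s * config.fs))),
                    dtype=np.float32)
    truths: dict[str, ChannelTruth] = {}
    for i, cid in enumerate(channel_ids):
        rng = np.random.default_rng(_channel_seed(config.seed, condition, i))
        sig, truth = simulate_channel(config, condition, rng)
        data[i] = sig
        truths[cid] = truth
    site_of_channel = {
        cid: s + 1
        for s in range(config.n_sites)
        for cid in channel_ids[s * config.electrodes_per_site : (s + 1) * config.electrodes_per_site]
    }
    rec = Recording(
        data=data,
        fs=config.fs,
        channel_ids=channel_ids,
        site_of_channel=site_of_channel,
        condition=condition,
    )
    return rec, GroundTruth(channels=truths, condition=condition, config=config)


@dataclass
class DetectionScore:
    precision: float
    recall: float
    f1: float
    n_matched: int


def score_detection(
    truth_times: np.ndarray, detected_times: np.ndarray, tol_s: float = 0.002
) -> DetectionScore:
    """Greedy one-to-one matching of detected to true event times within a
    tolerance; returns precision/recall/F1.

    Both lists must be sorted.  For sorted lists the two-pointer greedy match
    is a maximum matching, so the score is not order-dependent.
    """
    t = np.asarray(truth_times, dtype=float)
    d = np.asarray(detected_times, dtype=float)
    i = j = matched = 0
    while i < t.size and j < d.size:
        dt = d[j] - t[i]
        if abs(dt) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    precision = matched / d.size if d.size else 1.0
    recall = matched / t.size if t.size else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return DetectionScore(precision, recall, f1, matched)
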