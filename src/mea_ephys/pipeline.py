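"""End-to-end orchestration: simulate/load -> filter -> detect -> metrics -> stats.

The pipeline turns each recording into a per-electrode metrics table
(spike rate, burst rate, mean burst duration, discharge rate, mean in-burst
4-40 Hz power), then compares condition arms with the nonparametric tests
and percent-of-baseline summaries used for MEA electrode data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .signal_io import Recording, segment, write_event_table
from .spike_detection import SpikeParams, detect_spikes, spikes_to_event_table
from .burst_detection import (
    BurstParams,
    burst_metrics,
    bursts_to_event_table,
    detect_bursts,
)
from .epileptiform import (
    DischargeParams,
    burst_psd,
    compute_timefreq,
    detect_discharges,
    normalize_timefreq,
    preprocess_lfp,
)
from .filters import decimate_to
from .stats import GroupComparison, kruskal_dunn, mann_whitney, percent_change
from .synthetic_data import SimulationConfig, simulate_experiment

#: metrics computed for every electrode
METRICS = (
    "spike_hz",
    "burst_hz",
    "burst_duration_s",
    "discharge_rate_hz",
    "burst_band_power",
)

#: padding added around each burst before its PSD is taken
BURST_PSD_PAD_S = 0.100


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``recording_paths`` (existing data) or ``simulation`` + ``conditions``
    (synthetic arms) names the inputs.  ``analysis_window_s`` restricts all
    metrics to a half-open window, e.g. ``(0, 120)`` for a first-2-minutes
    analysis.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    conditions: list[str] = field(
        default_factory=lambda: ["healthy/25mM/Veh", "healthy/25mM/KCl", "healthy/25mM/TTX"]
    )
    recording_paths: list[str] | None = None
    analysis_window_s: tuple[float, float] | None = None
    spike_params: SpikeParams = field(default_factory=SpikeParams)
    burst_params: BurstParams = field(default_factory=BurstParams)
    discharge_params: DischargeParams = field(default_factory=DischargeParams)
    baseline_window_s: float = 10.0  # z-scoring baseline = first N s of window
    timefreq_channels: int = 1  # z-maps are per-channel visuals; map this many
    timefreq_fs: float = 100.0
    output_dir: str | None = None


@dataclass
class AnalysisReport:
    """Per-electrode metrics plus provenance; one row per (condition, channel)."""

    metrics: pd.DataFrame
    event_tables: dict[str, pd.DataFrame]
    timefreq_maps: dict[str, "object"]
    provenance: dict

    def condition_values(self, condition: str, metric: str) -> np.ndarray:
        sub = self.metrics[self.metrics["condition"] == condition]
        return sub[metric].dropna().to_numpy()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)

    text = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def analyze_recording(
    rec: Recording,
    spike_params: SpikeParams | None = None,
    burst_params: BurstParams | None = None,
    discharge_params: DischargeParams | None = None,
    analysis_window_s: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect events on every channel and summarise per-electrode metrics.

    Returns ``(metrics, events)``: one metrics row per electrode and the full
    event table (spikes, burst bounds, discharges).  Burst PSD is measured on
    the 4-40 Hz filtered trace over each burst padded by 100 ms.
    """
    spike_params = spike_params or SpikeParams()
    burst_params = burst_params or BurstParams()
    discharge_params = discharge_params or DischargeParams()
    if analysis_window_s is not None:
        rec = segment(rec, *analysis_window_s)
    window = rec.duration_s

    spikes = detect_spikes(rec, spike_params)
    bursts = {
        cid: detect_bursts(
            np.asarray([s.peak_time_s for s in evs]), burst_params, channel_id=cid
        )
        for cid, evs in spikes.items()
    }
    filtered = preprocess_lfp(rec, discharge_params)
    discharges = detect_discharges(filtered, discharge_params)

    rows = []
    for i, cid in enumerate(rec.channel_ids):
        ch_bursts = bursts[cid]
        burst_hz, mean_dur = burst_metrics(ch_bursts, window)
        powers = []
        for b in ch_bursts:
            lo = max(b.start_s - rec.t0 - BURST_PSD_PAD_S, 0.0)
            hi = min(b.end_s - rec.t0 + BURST_PSD_PAD_S, window)
            seg = filtered.data[i][int(lo * rec.fs) : int(hi * rec.fs)]
            if seg.size < int(0.05 * rec.fs):
                continue
            powers.append(
                burst_psd(
                    seg,
                    rec.fs,
                    discharge_params.band_hz,
                    channel_id=cid,
                    burst_start_s=b.start_s,
                ).band_mean_power
            )
        rows.append(
            {
                "condition": rec.condition,
                "channel_id": cid,
                "site": (rec.site_of_channel or {}).get(cid),
                "spike_hz": len(spikes[cid]) / window,
                "burst_hz": burst_hz,
                "burst_duration_s": mean_dur,
                "discharge_rate_hz": len(discharges[cid]) / window,
                "burst_band_power": float(np.mean(powers)) if powers else np.nan,
                "n_spikes": len(spikes[cid]),
                "n_bursts": len(ch_bursts),
                "n_discharges": len(discharges[cid]),
            }
        )

    events = pd.concat(
        [
            spikes_to_event_table(spikes),
            bursts_to_event_table(bursts),
            pd.DataFrame(
                [
                    {
                        "channel_id": cid,
                        "event_type": "discharge",
                        "time_s": e.time_s,
                        "amplitude_uV": e.amplitude_uV,
                        "extra_json": "{}",
                    }
                    for cid, evs in discharges.items()
                    for e in evs
                ],
                columns=["channel_id", "event_type", "time_s", "amplitude_uV", "extra_json"],
            ),
        ],
        ignore_index=True,
    )
    return pd.DataFrame(rows), events


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Full deterministic run over every condition arm (or input recording).

    For each arm: simulate (or load), restrict to the analysis window, detect
    spikes/bursts/discharges, compute per-electrode metrics and a baseline
    z-scored time-frequency map for the first ``timefreq_channels`` channels.
    Writes CSV/JSON artefacts when ``output_dir`` is set.
    """
    from .signal_io import read_recording  # local import: optional path

    recordings: list[Recording] = []
    if config.recording_paths:
        recordings = [read_recording(p) for p in config.recording_paths]
    else:
        for cond in config.conditions:
            rec, _ = simulate_experiment(config.simulation, cond)
            recordings.append(rec)

    metrics_frames, event_tables, tf_maps = [], {}, {}
    for rec in recordings:
        metrics, events = analyze_recording(
            rec,
            config.spike_params,
            config.burst_params,
            config.discharge_params,
            config.analysis_window_s,
        )
        metrics_frames.append(metrics)
        event_tables[rec.condition] = events
        for i in range(min(config.timefreq_channels, rec.n_channels)):
            window_rec = (
                segment(rec, *config.analysis_window_s)
                if config.analysis_window_s
                else rec
            )
            low, lofs = decimate_to(
                window_rec.data[i].astype(float), rec.fs, config.timefreq_fs
            )
            tf = compute_timefreq(low, lofs, band_hz=config.discharge_params.band_hz)
            tf_maps[f"{rec.condition}:{rec.channel_ids[i]}"] = normalize_timefreq(
                tf, (0.0, min(config.baseline_window_s, tf.times_s[-1]))
            )

    report = AnalysisReport(
        metrics=pd.concat(metrics_frames, ignore_index=True),
        event_tables=event_tables,
        timefreq_maps=tf_maps,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.simulation.seed,
            "package_version": __version__,
            "numpy": np.__version__,
        },
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(outdir / "metrics.csv", index=False)
    for cond, events in report.event_tables.items():
        safe = cond.replace("/", "_")
        write_event_table(
            events.sort_values(["channel_id", "event_type", "time_s"]).reset_index(
                drop=True
            ),
            outdir / f"events_{safe}.csv",
        )
    for key, tf in report.timefreq_maps.items():
        safe = key.replace("/", "_").replace(":", "_")
        pd.DataFrame(tf.power, index=tf.times_s, columns=tf.freqs_hz).to_csv(
            outdir / f"timefreq_{safe}.csv"
        )
    (outdir / "report.json").write_text(json.dumps(report.provenance, indent=1))


def compare_conditions(
    report: AnalysisReport,
    metric: str,
    conditions: list[str] | None = None,
) -> GroupComparison:
    """Compare a per-electrode metric across condition arms.

    Two arms route to Mann-Whitney, three or more to Kruskal-Wallis + Dunn.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRICS}")
    conditions = conditions or list(report.metrics["condition"].unique())
    groups = [report.condition_values(c, metric) for c in conditions]
    for cond, g in zip(conditions, groups):
        if g.size == 0:
            raise ValueError(f"no finite {metric} values for condition {cond!r}")
    if len(groups) == 2:
        comp = mann_whitney(groups[0], groups[1])
        comp.group_labels = conditions
        return comp
    return kruskal_dunn(groups, labels=conditions)


def percent_change_table(
    report: AnalysisReport,
    treatment_condition: str,
    baseline_condition: str,
    metrics: tuple[str, ...] = ("spike_hz", "burst_hz", "burst_duration_s"),
) -> pd.DataFrame:
    """Electrode-paired percent-of-baseline values (100 = unchanged) for each
    metric; electrodes are paired by channel id across the two arms."""
    t = report.metrics[report.metrics["condition"] == treatment_condition]
    b = report.metrics[report.metrics["condition"] == baseline_condition]
    merged = t.merge(b, on="channel_id", suffixes=("_treat", "_base"))
    out = {}
    for m in metrics:
        pair = merged[[f"{m}_treat", f"{m}_base"]].dropna()
        out[m] = pd.Series(
            percent_change(pair[f"{m}_treat"].to_numpy(), pair[f"{m}_base"].to_numpy())
        )
    return pd.DataFrame(out)
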