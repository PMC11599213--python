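"""Burst detection on single-electrode spike trains.

A burst is a series of at least ``min_spikes`` consecutive spikes separated by
at most ``max_isi_s`` each (defaults: 5 spikes, 50 ms).  Bursts are maximal
runs under that gap rule, so the decomposition is unique and every spike
belongs to at most one burst.  A gap of exactly 50 ms is inside a burst
(inclusive comparison).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd

from .signal_io import make_event_table

# absolute slack for the gap comparison, so ISIs stored as floats that are
# exactly at the limit (e.g. 0.05) are not rejected by rounding noise
_GAP_TOL = 1e-9


@dataclass
class BurstParams:
    min_spikes: int = 5
    max_isi_s: float = 0.050

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("a burst needs at least 2 spikes")
        if self.max_isi_s <= 0:
            raise ValueError("max_isi_s must be positive")


@dataclass
class Burst:
    channel_id: str
    spike_times_s: np.ndarray
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        """Last spike time minus first spike time."""
        return self.end_s - self.start_s


def detect_bursts(
    spike_times_s: np.ndarray,
    params: BurstParams | None = None,
    channel_id: str = "",
) -> list[Burst]:
    """Group a sorted spike train into maximal bursts.

    Raises if the input times are not strictly increasing.
    """
    params = params or BurstParams()
    t = np.asarray(spike_times_s, dtype=float)
    if t.size == 0:
        return []
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("spike times must be sorted ascending and unique")
    # split where the gap exceeds the maximal interval
    breaks = np.flatnonzero(d > params.max_isi_s + _GAP_TOL)
    bursts: list[Burst] = []
    start = 0
    for b in np.concatenate([breaks, [t.size - 1]]):
        stop = int(b) + 1  # run is t[start:stop]
        if stop - start >= params.min_spikes:
            run = t[start:stop]
            bursts.append(
                Burst(
                    channel_id=channel_id,
                    spike_times_s=run,
                    start_s=float(run[0]),
                    end_s=float(run[-1]),
                    n_spikes=run.size,
                )
            )
        start = stop
    return bursts


def burst_metrics(bursts: list[Burst], window_s: float) -> tuple[float, float]:
    """(burst frequency in Hz, mean burst duration in s) over a window.

    With zero bursts the frequency is 0 and the duration is reported as
    missing (NaN).
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    freq = len(bursts) / window_s
    mean_dur = float(np.mean([b.duration_s for b in bursts])) if bursts else nan
    return freq, mean_dur


def bursts_to_event_table(bursts_by_channel: dict[str, list[Burst]]) -> pd.DataFrame:
    rows = []
    for cid, bursts in bursts_by_channel.items():
        for b in bursts:
            extra = json.dumps({"n_spikes": int(b.n_spikes), "duration_s": b.duration_s})
            rows.append(
                {
                    "channel_id": cid,
                    "event_type": "burst_start",
                    "time_s": b.start_s,
                    "amplitude_uV": nan,
                    "extra_json": extra,
                }
            )
            rows.append(
                {
                    "channel_id": cid,
                    "event_type": "burst_end",
                    "time_s": b.end_s,
                    "amplitude_uV": nan,
                    "extra_json": extra,
                }
            )
    return make_event_table(rows)
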