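"""Recording container and event-table I/O.

A recording is a channels x samples voltage matrix (microvolts) with a JSON
sidecar carrying the sampling rate and channel metadata.  Two on-disk layouts
are supported:

* raw container: ``<base>.json`` sidecar + ``<base>.raw`` little-endian float32,
  sample-major interleaved (frame by frame);
* CSV container: ``<base>.json`` sidecar + ``<base>.csv`` with one column per
  channel, header row of channel labels (intended for small fixtures).

Event tables are plain CSV with columns
``channel_id,event_type,time_s,amplitude_uV,extra_json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_TYPES = ("spike", "burst_start", "burst_end", "discharge")

EVENT_COLUMNS = ["channel_id", "event_type", "time_s", "amplitude_uV", "extra_json"]


class FormatError(ValueError):
    """Sidecar or data file does not follow the container contract."""


@dataclass
class Recording:
    """Multi-channel extracellular voltage recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, voltage in microvolts.
    fs
        Sampling rate in Hz (the acquisition hardware runs at 30 kS/s).
    channel_ids
        One label per channel, e.g. ``"S1-E3"`` for site 1, electrode 3.
    site_of_channel
        Optional mapping channel label -> recording-site number (1-4 for the
        four-site, eight-electrodes-per-site MEA layout).
    condition
        Free-text condition label, e.g. ``"GLUT1-DS/5mM/Veh"``.
    t0
        Absolute start time of the first sample, seconds.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    site_of_channel: dict[str, int] | None = None
    condition: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} data rows"
            )
        if self.site_of_channel is not None:
            sites = set(self.site_of_channel.values())
            if not sites <= {1, 2, 3, 4}:
                raise ValueError(f"site ids must lie in 1..4, got {sorted(sites)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]


def _paths(path: str | Path) -> tuple[Path, Path, Path]:
    base = Path(path)
    if base.suffix in {".json", ".raw", ".csv"}:
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".raw"), base.with_suffix(".csv")


def write_recording(rec: Recording, path: str | Path, fmt: str = "raw") -> None:
    """Write ``rec`` as sidecar + raw float32 (``fmt="raw"``) or CSV (``fmt="csv"``).

    Refuses non-finite data: NaN/inf voltages indicate an upstream bug, not a
    storable signal.
    """
    if rec.data.size and not np.isfinite(rec.data).all():
        raise ValueError("recording contains non-finite samples; refusing to write")
    if fmt not in {"raw", "csv"}:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar, rawfile, csvfile = _paths(path)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_ids": rec.channel_ids,
        "units": "uV",
        "site_of_channel": rec.site_of_channel,
        "condition": rec.condition,
        "t0": rec.t0,
        "format": "raw_float32" if fmt == "raw" else "csv",
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    if fmt == "raw":
        # sample-major: frame of all channels at t, then frame at t+1, ...
        rec.data.T.astype("<f4").tofile(rawfile)
    else:
        pd.DataFrame(rec.data.T.astype(np.float32), columns=rec.channel_ids).to_csv(
            csvfile, index=False
        )


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    sidecar, rawfile, csvfile = _paths(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "n_channels"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required field {key!r}")
    n_channels = int(meta["n_channels"])
    fmt = meta.get("format", "raw_float32")
    if fmt == "csv":
        frame = pd.read_csv(csvfile)
        data = frame.to_numpy(dtype=np.float32).T
        channel_ids = meta.get("channel_ids") or list(frame.columns)
    else:
        flat = np.fromfile(rawfile, dtype="<f4")
        if n_channels > 0 and flat.size % n_channels:
            raise FormatError(
                f"{rawfile}: {flat.size} samples not divisible by {n_channels} channels"
            )
        n_samples = flat.size // n_channels if n_channels else 0
        data = flat.reshape(n_samples, n_channels).T
        channel_ids = meta.get("channel_ids") or [f"ch{i}" for i in range(n_channels)]
    if data.shape[0] != n_channels:
        raise FormatError(
            f"sidecar declares {n_channels} channels, data has {data.shape[0]}"
        )
    site = meta.get("site_of_channel")
    if site is not None:
        site = {str(k): int(v) for k, v in site.items()}
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_ids=[str(c) for c in channel_ids],
        site_of_channel=site,
        condition=meta.get("condition", ""),
        t0=float(meta.get("t0", 0.0)),
    )


def segment(rec: Recording, t_start_s: float, t_end_s: float) -> Recording:
    """Half-open window ``[t_start, t_end)`` relative to the recording start.

    ``t0`` is advanced so event times computed on the segment remain absolute.
    """
    if not (0.0 <= t_start_s < t_end_s <= rec.duration_s + 0.5 / rec.fs):
        raise ValueError(
            f"window [{t_start_s}, {t_end_s}) outside recording of {rec.duration_s:.6g} s"
        )
    i0 = int(round(t_start_s * rec.fs))
    i1 = int(round(t_end_s * rec.fs))
    return replace(rec, data=rec.data[:, i0:i1], t0=rec.t0 + t_start_s)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def make_event_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """Empty or populated event table with the canonical column order."""
    frame = pd.DataFrame(rows or [], columns=EVENT_COLUMNS)
    return frame[EVENT_COLUMNS]


def validate_event_table(table: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"event table lacks columns {missing}")
    bad = set(table["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise FormatError(f"unknown event types {sorted(bad)}")
    if len(table) and (table["time_s"] < 0).any():
        raise FormatError("negative event times")
    for (_, _), sub in table.groupby(["channel_id", "event_type"], sort=False):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise FormatError("event times decrease within a channel/type")


def write_event_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_event_table(table)
    table[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"channel_id": str, "event_type": str})
    if "extra_json" in table.columns:
        table["extra_json"] = table["extra_json"].fillna("{}")
    validate_event_table(table)
    return table
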