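"""IIR filter design and application for the discharge-detection path.

The local-field-potential preprocessing chain is a 50 Hz notch (biquad,
Q = 30) followed by a second-order Chebyshev type-I band-pass (4-40 Hz,
0.5 dB passband ripple), both applied forward-backward so event timing is
preserved.  A separate multi-stage decimator takes the 30 kHz stream down to
100 Hz for the wavelet time-frequency map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps


@dataclass
class FilterSpec:
    """A designed IIR filter: transfer-function coefficients plus the design
    parameters that produced them (kept for provenance logs)."""

    kind: str  # "notch" | "cheby1_bandpass"
    b: np.ndarray
    a: np.ndarray
    fs: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a[0] != 1.0:
            self.b = self.b / self.a[0]
            self.a = self.a / self.a[0]

    def is_stable(self) -> bool:
        """All poles strictly inside the unit circle."""
        if len(self.a) == 1:
            return True
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "b": self.b.tolist(),
                "a": self.a.tolist(),
                "fs": self.fs,
                "params": self.params,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        d = json.loads(text)
        return cls(kind=d["kind"], b=d["b"], a=d["a"], fs=d["fs"], params=d["params"])


def design_notch(fs: float, f0_hz: float = 50.0, q: float = 30.0) -> FilterSpec:
    """Second-order IIR notch at ``f0_hz`` (default: 50 Hz line noise).

    Q = f0 / bandwidth; Q = 30 gives a ~1.7 Hz-wide notch at 50 Hz, removing
    mains interference without touching neighbouring frequencies.
    """
    if not 0 < f0_hz < fs / 2:
        raise ValueError(f"notch frequency {f0_hz} Hz must lie below Nyquist {fs / 2} Hz")
    if q <= 0:
        raise ValueError("quality factor must be positive")
    b, a = sps.iirnotch(f0_hz, q, fs=fs)
    return FilterSpec("notch", b, a, fs, {"f0_hz": f0_hz, "Q": q})


def design_cheby1_bandpass(
    fs: float,
    order: int = 2,
    ripple_db: float = 0.5,
    band_hz: tuple[float, float] = (4.0, 40.0),
) -> FilterSpec:
    """Chebyshev type-I band-pass (design order ``order``; the band transform
    doubles the pole count, so order 2 yields a 4-pole filter, the convention
    of the standard design routines)."""
    low, high = band_hz
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band {band_hz} for fs={fs}")
    b, a = sps.cheby1(order, ripple_db, [low, high], btype="bandpass", fs=fs)
    return FilterSpec(
        "cheby1_bandpass",
        b,
        a,
        fs,
        {"order": order, "ripple_db": ripple_db, "band_hz": list(band_hz)},
    )


def apply_zero_phase(spec: FilterSpec, x: np.ndarray) -> np.ndarray:
    """Forward-backward (zero-phase) filtering along the last axis.

    Effective magnitude response is |H|^2 and net phase is zero, so peaks do
    not shift in time.  Edges use odd-reflection padding of length
    3*(max(len(a), len(b)) - 1).
    """
    x = np.asarray(x)
    padlen = 3 * (max(len(spec.a), len(spec.b)) - 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    return sps.filtfilt(spec.b, spec.a, x, axis=-1, padtype="odd", padlen=padlen)


def frequency_response(spec: FilterSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Complex gain H(e^{j 2 pi f / fs}) evaluated from the coefficients."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    _, h = sps.freqz(spec.b, spec.a, worN=2 * np.pi * freqs_hz / spec.fs)
    return h


def _stage_factors(factor: int, max_stage: int = 13) -> list[int]:
    """Split ``factor`` into stages each <= max_stage (largest divisors first)."""
    stages: list[int] = []
    remaining = factor
    while remaining > 1:
        for q in range(min(max_stage, remaining), 1, -1):
            if remaining % q == 0:
                stages.append(q)
                remaining //= q
                break
        else:  # prime > max_stage
            raise ValueError(
                f"decimation factor {factor} has a prime factor above {max_stage}"
            )
    return stages


def decimate_to(
    x: np.ndarray, fs: float, target_fs: float = 100.0
) -> tuple[np.ndarray, float]:
    """Anti-aliased multi-stage decimation (e.g. 30 kHz -> 100 Hz = 10 x 5 x 6).

    Each stage applies an 8th-order low-pass (zero-phase) before keeping every
    q-th sample; no single stage exceeds a factor of 13, which keeps the IIR
    anti-alias filters numerically safe.
    """
    factor = fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {fs} is not an integer multiple of target {target_fs}")
    factor = int(round(factor))
    if factor == 1:
        return np.asarray(x, dtype=float), float(target_fs)
    y = np.asarray(x, dtype=float)
    for q in _stage_factors(factor):
        # 8th-order Chebyshev-I anti-alias low-pass at 0.8 x the new Nyquist;
        # 0.01 dB ripple keeps the zero-phase (squared-magnitude) passband
        # droop of the whole cascade well under 1%.  Even-order Chebyshev-I
        # sits at the ripple trough at DC, so renormalize to exact unit DC
        # gain (constants must pass through a decimator unchanged).
        b, a = sps.cheby1(8, 0.01, 0.8 / q)
        b = b * (np.sum(a) / np.sum(b))
        y = sps.decimate(y, q, ftype=sps.dlti(b, a), zero_phase=True, axis=-1)
    return y, float(target_fs)
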