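"""Preprocessing chain: band-pass filtering, average reference, electrode-array
selection and sliding-window epoching.

The filter is a zero-phase forward-backward Butterworth band-pass.  Zero-phase
filtering matters here: the travelling-wave statistic depends on cross-channel
phase relations, and any phase-distorting filter would bias the apparent
propagation direction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .core_io import ElectrodeArray, Recording


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window epoching: 1 s windows advancing by 0.5 s by default."""

    length_s: float = 1.0
    step_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError(
                f"need 0 < step_s <= length_s, got step={self.step_s}, "
                f"length={self.length_s}"
            )

    def n_windows(self, duration_s: float, fs: float) -> int:
        n_len = _exact_samples(self.length_s, fs, "window length")
        n_step = _exact_samples(self.step_s, fs, "window step")
        n_total = int(round(duration_s * fs))
        if n_total < n_len:
            raise ValueError("recording shorter than one window")
        return (n_total - n_len) // n_step + 1


def _exact_samples(seconds: float, fs: float, what: str) -> int:
    """Seconds → samples, rejecting non-integer products (no silent rounding)."""
    n = seconds * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} of {seconds}s is not a whole number of samples "
                         f"at fs={fs}")
    return int(round(n))


def bandpass(recording: Recording, low_hz: float = 1.0,
             high_hz: float = 45.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass applied independently per channel.

    ``order`` is the per-pass filter order; the forward-backward application
    doubles the effective attenuation and cancels the phase response.
    """
    nyq = recording.fs / 2
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={recording.fs} "
            f"(Nyquist {nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(recording.labels, recording.fs, filtered, recording.t0)


def rereference_average(recording: Recording) -> Recording:
    """Re-reference to the instantaneous average of all electrodes."""
    if recording.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return Recording(recording.labels, recording.fs, data, recording.t0)


def select_array(recording: Recording, array: ElectrodeArray) -> Recording:
    """Extract and order the channels of one propagation axis (posterior first)."""
    idx = [recording.index_of(label) for label in array.labels]
    return Recording(array.labels, recording.fs, recording.data[idx],
                     recording.t0)


def slide_windows(recording: Recording, spec: WindowSpec = WindowSpec()):
    """Cut the recording into overlapping windows; returns a list of WaveMap.

    Windows start at ``t0, t0+step, ...``; a window that would overrun the end
    of the signal is dropped (no padding).  No detrending or tapering is
    applied — the spatially/temporally constant components are excluded later
    at the quadrant-maximum stage instead.
    """
    from .wave_quant import WaveMap

    n_len = _exact_samples(spec.length_s, recording.fs, "window length")
    n_step = _exact_samples(spec.step_s, recording.fs, "window step")
    if recording.n_samples < n_len:
        raise ValueError(
            f"recording of {recording.duration}s shorter than one "
            f"{spec.length_s}s window"
        )
    maps = []
    for start in range(0, recording.n_samples - n_len + 1, n_step):
        maps.append(WaveMap(
            data=recording.data[:, start:start + n_len],
            fs=recording.fs,
            t_start=recording.t0 + start / recording.fs,
        ))
    return maps


def reject_amplitude(maps, threshold_uv: float):
    """Drop windows containing any sample above ``threshold_uv`` in magnitude.

    An automatic stand-in for manual artifact screening.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    return [m for m in maps if np.abs(m.data).max() <= threshold_uv]


def preprocess(recording: Recording, low_hz: float = 1.0, high_hz: float = 45.0,
               rereference: bool = True) -> Recording:
    """Standard chain: band-pass 1–45 Hz then average reference."""
    out = bandpass(recording, low_hz, high_hz)
    if rereference:
        out = rereference_average(out)
    return out
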