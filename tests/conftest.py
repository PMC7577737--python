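"""Shared fixtures: deterministic RNG, canonical test signals, and minimal
on-disk EEG files in vendor formats (generated programmatically)."""

from __future__ import annotations



import numpy as np
import pytest

from eegwaves.core_io import Recording
from eegwaves.wave_quant import WaveMap


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_plane_map(fs: float = 1000.0, n_elec: int = 5, temporal_hz: float = 10.0,
                   cpe: float = 0.2, duration_s: float = 1.0,
                   noise: float = 0.0, seed: int = 0) -> WaveMap:
    """Forward (posterior→anterior) plane wave map, optional white noise."""
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.arange(n_elec)
    data = np.cos(2 * np.pi * temporal_hz * t[None, :]
                  - 2 * np.pi * cpe * x[:, None])
    if noise > 0:
        data = data + noise * np.random.default_rng(seed).standard_normal(data.shape)
    return WaveMap(data, fs)


@pytest.fixture()
def forward_map() -> WaveMap:
    return make_plane_map()


@pytest.fixture()
def uniform_map() -> WaveMap:
    t = np.arange(1000) / 1000.0
    row = np.cos(2 * np.pi * 10.0 * t)
    return WaveMap(np.tile(row, (5, 1)), 1000.0)


# ---------------------------------------------------------------------------
# vendor-format writers (fixtures are generated, never stored)


def write_minimal_edf(path, recording: Recording) -> None:
    """Write a Recording as a minimal single-record EDF file.

    Physical range is set to ±32767 µV with 1 µV/bit so that integer-valued
    microvolt data round-trips exactly.
    """
    ns = recording.n_channels
    n_samp = recording.n_samples
    dur = n_samp / recording.fs

    def pad(value: str, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad("1", 8), pad(f"{dur:g}", 8), pad(str(ns), 4),
    ])
    header += b"".join(pad(l, 16) for l in recording.labels)
    header += b"".join(pad("EEG", 80) for _ in range(ns))
    header += b"".join(pad("uV", 8) for _ in range(ns))
    header += b"".join(pad("-32767", 8) for _ in range(ns))   # physical min
    header += b"".join(pad("32767", 8) for _ in range(ns))    # physical max
    header += b"".join(pad("-32767", 8) for _ in range(ns))   # digital min
    header += b"".join(pad("32767", 8) for _ in range(ns))    # digital max
    header += b"".join(pad("", 80) for _ in range(ns))
    header += b"".join(pad(str(n_samp), 8) for _ in range(ns))
    header += b"".join(pad("", 32) for _ in range(ns))
    digital = np.round(recording.data).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for ch in range(ns):
            fh.write(digital[ch].tobytes())


def write_minimal_brainvision(basename, recording: Recording) -> None:
    """Write .vhdr/.vmrk/.eeg files (IEEE float32, multiplexed, µV)."""
    vhdr = basename.with_suffix(".vhdr")
    vmrk = basename.with_suffix(".vmrk")
    eeg = basename.with_suffix(".eeg")
    interval_us = 1e6 / recording.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.labels, start=1):
        lines.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n", encoding="utf-8")
    eeg.write_bytes(recording.data.T.astype("<f4").tobytes())
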