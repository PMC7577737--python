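"""Data containers and I/O for multichannel EEG recordings and study tables.

The central container is :class:`Recording`: a channels × samples matrix in
microvolts with an explicit sampling rate and a time origin ``t0`` expressed in
seconds relative to drug injection (negative = pre-injection, sample ``i`` sits
at ``t0 + i / fs``).  Recordings can be read from BrainVision or EDF files (via
:mod:`mne`) or from this package's own HDF5 container, which round-trips
bit-exactly and is the format the synthetic-study generator writes.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("placebo", "dmt")


class IntegrityError(ValueError):
    """A container violates one of its structural invariants."""


def _norm_label(label: str) -> str:
    """Canonical channel-name key: case-insensitive, whitespace-stripped."""
    return label.strip().lower()


@dataclasses.dataclass(frozen=True)
class Recording:
    """Labeled multichannel signal in microvolts.

    Parameters
    ----------
    labels
        Ordered channel names; one per data row, unique after normalisation.
    fs
        Sampling rate in Hz, strictly positive.
    data
        ``(n_channels, n_samples)`` real matrix in microvolts.
    t0
        Start time in seconds relative to injection (negative = pre-injection).
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise IntegrityError(f"data must be 2-D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        if len(self.labels) == 0:
            raise IntegrityError("recording must have at least one channel")
        if len(self.labels) != data.shape[0]:
            raise IntegrityError(
                f"{len(self.labels)} labels but {data.shape[0]} data rows"
            )
        keys = [_norm_label(l) for l in self.labels]
        if len(set(keys)) != len(keys):
            raise IntegrityError("channel labels are not unique")
        if not self.fs > 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(data).all():
            raise IntegrityError("recording data contains non-finite samples")
        if not np.isfinite(self.t0):
            raise IntegrityError("t0 must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def index_of(self, label: str) -> int:
        """Row index of ``label`` (case-insensitive, whitespace-stripped)."""
        key = _norm_label(label)
        for i, l in enumerate(self.labels):
            if _norm_label(l) == key:
                return i
        raise KeyError(f"channel {label!r} not present in recording")

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to injection."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclasses.dataclass(frozen=True)
class ElectrodeArray:
    """An ordered 1-D propagation axis through the montage.

    ``labels[0]`` is the most posterior electrode (or leftmost, for the
    lateral control axis) and the last label the most anterior.  Waves moving
    toward increasing index are "forward" on this axis.
    """

    labels: tuple[str, ...]
    axis_kind: str = "midline"

    _KINDS = ("midline", "diagonal_right_to_left", "diagonal_left_to_right", "lateral")

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.labels) < 3:
            raise IntegrityError("electrode array needs at least 3 electrodes")
        keys = [_norm_label(l) for l in self.labels]
        if len(set(keys)) != len(keys):
            raise IntegrityError("electrode array labels are not distinct")
        if self.axis_kind not in self._KINDS:
            raise IntegrityError(f"unknown axis kind {self.axis_kind!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def reversed(self) -> "ElectrodeArray":
        return ElectrodeArray(tuple(reversed(self.labels)), self.axis_kind)


#: Posterior→anterior midline axis used for the primary analysis.
MIDLINE = ElectrodeArray(("Oz", "POz", "Pz", "Cz", "FCz"), "midline")
#: Posterior-right → anterior-left diagonal axis.
DIAGONAL_RL = ElectrodeArray(("O2", "P4", "CP2", "FC1", "F3"), "diagonal_right_to_left")
#: Posterior-left → anterior-right diagonal axis.
DIAGONAL_LR = ElectrodeArray(("O1", "P3", "CP1", "FC2", "F4"), "diagonal_left_to_right")
#: Left→right central axis; a null control for anterior–posterior propagation.
LATERAL = ElectrodeArray(("T7", "C3", "Cz", "C4", "T8"), "lateral")

NAMED_ARRAYS: dict[str, ElectrodeArray] = {
    "midline": MIDLINE,
    "diag-rl": DIAGONAL_RL,
    "diag-lr": DIAGONAL_LR,
    "lateral": LATERAL,
}


@dataclasses.dataclass
class RatingsTable:
    """Per-minute subjective intensity ratings and end-of-session VAS items.

    ``intensity`` has columns ``subject, minute, intensity`` (minute 1..20
    post-injection); ``vas`` has columns ``subject, item, score``.
    """

    intensity: pd.DataFrame
    vas: pd.DataFrame

    def __post_init__(self) -> None:
        for frame, cols in ((self.intensity, {"subject", "minute", "intensity"}),
                            (self.vas, {"subject", "item", "score"})):
            missing = cols - set(frame.columns)
            if missing:
                raise IntegrityError(f"ratings table missing columns {sorted(missing)}")
        dup = self.intensity.duplicated(subset=["subject", "minute"])
        if dup.any():
            raise IntegrityError("duplicate (subject, minute) intensity entries")
        for frame, col in ((self.intensity, "intensity"), (self.vas, "score")):
            if not np.isfinite(frame[col].to_numpy(dtype=float)).all():
                raise IntegrityError(f"non-finite {col} values")

    def intensity_of(self, subject: str) -> pd.Series:
        """Minute-indexed intensity series for one subject."""
        sub = self.intensity[self.intensity["subject"] == subject]
        return sub.set_index("minute")["intensity"].sort_index()


@dataclasses.dataclass
class StudyDataset:
    """Subjects × {placebo, dmt} sessions plus the drug-session ratings.

    Recordings may be stored eagerly or behind zero-argument loader callables
    so that a full study never has to be memory-resident at once.
    """

    subjects: list[str]
    sessions: dict[tuple[str, str], "Recording | Callable[[], Recording]"]
    ratings: RatingsTable | None = None
    doses_mg: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for subject in self.subjects:
            for condition in CONDITIONS:
                if (subject, condition) not in self.sessions:
                    raise IntegrityError(
                        f"subject {subject!r} is missing the {condition!r} session"
                    )
        for (subject, condition) in self.sessions:
            if condition not in CONDITIONS:
                raise IntegrityError(f"unknown condition {condition!r}")
            if subject not in self.subjects:
                raise IntegrityError(f"session for unknown subject {subject!r}")

    def get_recording(self, subject: str, condition: str) -> Recording:
        entry = self.sessions[(subject, condition)]
        return entry() if callable(entry) else entry

    def iter_sessions(self) -> Iterator[tuple[str, str]]:
        for subject in self.subjects:
            for condition in CONDITIONS:
                yield subject, condition


# ---------------------------------------------------------------------------
# Recording I/O


def write_recording(recording: Recording, path: "str | Path") -> None:
    """Write a Recording to the package's HDF5 container (bit-exact)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = recording.fs
        f.attrs["t0"] = recording.t0
        f.attrs["unit"] = "uV"
        f.create_dataset("labels", data=np.array(recording.labels, dtype=object),
                         dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("data", data=recording.data)


def _read_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        labels = tuple(l.decode() if isinstance(l, bytes) else str(l)
                       for l in f["labels"][()])
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
        unit = f.attrs.get("unit", "uV")
        if isinstance(unit, bytes):
            unit = unit.decode()
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise IntegrityError(
            f"{path}: {len(labels)} labels but data shape {data.shape}"
        )
    if unit not in ("uV", "µV"):
        scale = {"V": 1e6, "mV": 1e3, "nV": 1e-3}.get(str(unit))
        if scale is None:
            raise IntegrityError(f"{path}: unknown unit {unit!r}")
        logger.info("converting %s from %s to uV (x%g)", path, unit, scale)
        data = data * scale
    return Recording(labels, fs, data, t0)


def _read_mne(path: Path, reader, t0: float) -> Recording:
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; exact conversion to uV
    logger.info("read %s via mne: %d channels at %g Hz (V -> uV)",
                path, data.shape[0], raw.info["sfreq"])
    return Recording(tuple(raw.ch_names), float(raw.info["sfreq"]), data, t0)


def read_recording(path: "str | Path", format: str | None = None,
                   t0: float = 0.0) -> Recording:
    """Read a Recording from ``brainvision``, ``edf`` or ``container`` format.

    ``format=None`` infers the format from the file suffix.  ``t0`` overrides
    the time origin for formats that do not store one (BrainVision, EDF).
    No resampling or filtering is applied.
    """
    import mne.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".vhdr": "brainvision", ".edf": "edf",
                  ".h5": "container", ".hdf5": "container"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "container":
        return _read_container(path)
    if format == "brainvision":
        return _read_mne(path, mne.io.read_raw_brainvision, t0)
    if format == "edf":
        return _read_mne(path, mne.io.read_raw_edf, t0)
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Tabular I/O


def write_results_table(rows: "pd.DataFrame | Sequence[Mapping]",
                        path: "str | Path") -> None:
    """Write a results table as delimited text at full float precision."""
    if not isinstance(rows, pd.DataFrame):
        rows = list(rows)
        if len(rows) == 0:
            raise ValueError("results table is empty")
        cols = set(rows[0].keys())
        if any(set(r.keys()) != cols for r in rows):
            raise ValueError("heterogeneous rows in results table")
        rows = pd.DataFrame(rows)
    if rows.empty:
        raise ValueError("results table is empty")
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_ratings(ratings: RatingsTable, directory: "str | Path") -> None:
    directory = Path(directory)
    write_results_table(ratings.intensity, directory / "intensity.tsv")
    write_results_table(ratings.vas, directory / "vas.tsv")


def read_ratings(directory: "str | Path") -> RatingsTable:
    directory = Path(directory)
    return RatingsTable(
        intensity=read_results_table(directory / "intensity.tsv"),
        vas=read_results_table(directory / "vas.tsv"),
    )


def write_study(dataset: StudyDataset, directory: "str | Path") -> None:
    """Persist a study: one container file per session plus rating tables."""
    directory = Path(directory)
    (directory / "sessions").mkdir(parents=True, exist_ok=True)
    for subject, condition in dataset.iter_sessions():
        rec = dataset.get_recording(subject, condition)
        write_recording(rec, directory / "sessions" / f"{subject}_{condition}.h5")
    if dataset.ratings is not None:
        write_ratings(dataset.ratings, directory)
    if dataset.doses_mg:
        write_results_table(
            pd.DataFrame([{"subject": s, "dose_mg": d}
                          for s, d in dataset.doses_mg.items()]),
            directory / "doses.tsv")


def read_study(directory: "str | Path") -> StudyDataset:
    """Load a study written by :func:`write_study` (recordings lazily)."""
    import functools

    directory = Path(directory)
    sessions: dict[tuple[str, str], Callable[[], Recording]] = {}
    subjects = set()
    for path in sorted((directory / "sessions").glob("*.h5")):
        subject, condition = path.stem.rsplit("_", 1)
        subjects.add(subject)
        sessions[(subject, condition)] = functools.partial(
            read_recording, path, "container")
    ratings = None
    if (directory / "intensity.tsv").exists():
        ratings = read_ratings(directory)
    doses = {}
    if (directory / "doses.tsv").exists():
        table = read_results_table(directory / "doses.tsv")
        doses = dict(zip(table["subject"], table["dose_mg"]))
    return StudyDataset(subjects=sorted(subjects), sessions=sessions,
                        ratings=ratings, doses_mg=doses)
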