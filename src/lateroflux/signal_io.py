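"""Reading, writing and windowing of bilateral perfusion, RR and EGG recordings.

Laser-Doppler flowmetry (LDF) traces are delimited-text exports (canonical
dialect: tab-separated, one header line, time in seconds, perfusion in
arbitrary perfusion units, PU).  RR-interval series are one- or two-column
text.  Electrogastrogram (EGG) recordings are 8-channel EDF or delimited
text.  Session metadata (subject, temperature group, stimulus time, file
paths) lives in a YAML sidecar.

The analysis windows are four consecutive 10-min blocks: ``Pre`` is the last
10 min of baseline ending at the stimulus, ``Post1``-``Post3`` tile the 30 min
after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

GROUPS = ("4C", "10C", "30C")
PHASE_NAMES = ("Pre", "Post1", "Post2", "Post3")
WINDOW_S = 600.0
BASELINE_MIN_S = 900.0
POST_MIN_S = 1800.0

_DELIMS = ("\t", ",", ";")


class FormatError(ValueError):
    """Raised when an input file does not match the declared format."""


class CoverageError(ValueError):
    """Raised when a session does not cover a required analysis window."""


@dataclass
class PerfusionRecording:
    """One-side LDF perfusion trace.

    Parameters
    ----------
    samples : array of perfusion values (PU)
    fs : sampling rate in Hz (64 for the PeriFlux protocol)
    side : "left" or "right"
    subject_id : opaque subject identifier
    """

    samples: np.ndarray
    fs: float = 64.0
    side: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BilateralSession:
    """Aligned left/right LDF recordings with stimulus time and group label."""

    left: PerfusionRecording
    right: PerfusionRecording
    stimulus_time: float
    group: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.left.fs != self.right.fs:
            raise ValueError("left/right sampling rates differ")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.stimulus_time < 0:
            raise ValueError("stimulus_time must be >= 0")
        n = min(self.left.samples.size, self.right.samples.size)
        if self.left.samples.size != self.right.samples.size:
            # align by truncating the longer side
            self.left.samples = self.left.samples[:n]
            self.right.samples = self.right.samples[:n]
        if not self.subject_id:
            self.subject_id = self.left.subject_id or self.right.subject_id

    @property
    def fs(self) -> float:
        return self.left.fs

    @property
    def duration_s(self) -> float:
        return self.left.samples.size / self.fs


@dataclass(frozen=True)
class PhaseWindow:
    """A named 10-min analysis window, in seconds from record start."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValueError(f"window name must be one of {PHASE_NAMES}")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EGGRecording:
    """8-channel cutaneous electrogastrogram, channels x samples, in µV."""

    channels: np.ndarray
    fs: float
    phase: str = "pre"
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != 8:
            raise FormatError(
                f"EGG recording must have exactly 8 channels, got {self.channels.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        if self.labels is None:
            self.labels = [f"EGG{i + 1}" for i in range(8)]
        self.labels = list(self.labels)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CohortDesign:
    """Subject-to-group assignment plus basic anthropometrics."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"design table missing column {col!r}")
        if self.table["subject_id"].duplicated().any():
            raise FormatError("each subject must appear in exactly one group")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown groups in design table: {sorted(bad)}")

    def group_of(self, subject_id: str) -> str:
        row = self.table.loc[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return str(row["group"].iloc[0])


@dataclass(frozen=True)
class ColumnSpec:
    """Declares which columns of a delimited text file hold time and signal.

    ``time`` / ``value`` are 0-based column indices.  ``time`` may be None for
    files without a time column, in which case ``fs`` must be given.
    ``time_unit`` is "s" or "ms".
    """

    time: int | None = 0
    value: int = 1
    time_unit: str = "s"
    fs: float | None = None

    def __post_init__(self) -> None:
        if self.time_unit not in ("s", "ms"):
            raise ValueError("time_unit must be 's' or 'ms'")
        if self.time is None and self.fs is None:
            raise ValueError("fs is required when no time column is declared")


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else None


def _numeric_rows(path: Path, min_cols: int) -> np.ndarray:
    """Parse a delimited text file, skipping non-numeric (header) rows."""
    rows = []
    delim = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = line.split(delim) if delim else line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue  # header or annotation row
            if len(vals) >= min_cols:
                rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no numeric data rows found")
    width = min(len(r) for r in rows)
    return np.asarray([r[:width] for r in rows], dtype=float)


def read_perfusion_text(
    path: str | Path,
    column_spec: ColumnSpec = ColumnSpec(),
    side: str = "left",
    subject_id: str = "",
) -> PerfusionRecording:
    """Read a one-side LDF trace from delimited text.

    The delimiter is auto-detected among tab/comma/semicolon; non-numeric rows
    (headers) are skipped.  The sampling rate is inferred from the median time
    step unless ``column_spec.fs`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = column_spec
    min_cols = 1 + max(spec.value, spec.time if spec.time is not None else 0)
    data = _numeric_rows(path, min_cols)
    values = data[:, spec.value]
    fs = spec.fs
    if spec.time is not None:
        t = data[:, spec.time]
        if spec.time_unit == "ms":
            t = t / 1000.0
        dt = np.diff(t)
        if t.size >= 2 and np.any(dt <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
        if fs is None:
            if t.size < 2:
                raise FormatError(f"{path}: cannot infer fs from a single row")
            fs = 1.0 / float(np.median(dt))
    return PerfusionRecording(values, fs=float(fs), side=side, subject_id=subject_id)


def write_perfusion_text(rec: PerfusionRecording, path: str | Path) -> None:
    """Write the canonical dialect: tab-separated, header, time in s."""
    np.savetxt(path, np.column_stack([rec.times, rec.samples]),
               fmt=["%.10g", "%.17g"], delimiter="\t",
               header="time_s\tperfusion_pu", comments="")


def read_rr_text(path: str | Path) -> np.ndarray:
    """Read RR intervals (ms) from one-column or two-column (time, RR) text."""
    data = _numeric_rows(Path(path), 1)
    intervals = data[:, -1] if data.shape[1] >= 2 else data[:, 0]
    if np.any(intervals <= 0):
        raise FormatError(f"{path}: RR intervals must be positive")
    return intervals


def write_rr_text(intervals: np.ndarray, path: str | Path) -> None:
    intervals = np.asarray(intervals, dtype=float)
    times = np.cumsum(intervals) / 1000.0
    np.savetxt(path, np.column_stack([times, intervals]),
               fmt=["%.10g", "%.17g"], delimiter="\t",
               header="time_s\trr_ms", comments="")


def read_egg(path: str | Path, fs: float | None = None, phase: str = "pre") -> EGGRecording:
    """Read an 8-channel EGG recording from EDF or delimited text.

    EDF files carry their own sampling rate and channel labels (read via mne);
    text files need ``fs``.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        if data.shape[0] != 8:
            raise FormatError(f"{path}: expected 8 EGG channels, got {data.shape[0]}")
        # mne rescales EDF voltage channels to SI volts; store µV
        return EGGRecording(data * 1e6, fs=float(raw.info["sfreq"]), phase=phase,
                            labels=list(raw.ch_names))
    data = _numeric_rows(path, 1)
    if data.shape[1] != 8:
        raise FormatError(f"{path}: expected 8 EGG channels, got {data.shape[1]}")
    if fs is None:
        raise ValueError("fs is required for text EGG input")
    return EGGRecording(data.T, fs=fs, phase=phase)


def write_egg_text(rec: EGGRecording, path: str | Path) -> None:
    header = "\t".join(rec.labels)
    np.savetxt(path, rec.channels.T, fmt="%.10g", delimiter="\t",
               header=header, comments="")


def write_egg_edf(rec: EGGRecording, path: str | Path) -> None:
    from ._edf import write_edf

    write_edf(path, rec.channels, rec.fs, labels=rec.labels, unit="uV")


def phase_windows(stimulus_time: float) -> list[PhaseWindow]:
    """The four 10-min windows around a stimulus: Pre and Post1-Post3."""
    wins = [PhaseWindow("Pre", stimulus_time - WINDOW_S, stimulus_time)]
    for k in range(1, 4):
        wins.append(PhaseWindow(f"Post{k}",
                                stimulus_time + (k - 1) * WINDOW_S,
                                stimulus_time + k * WINDOW_S))
    return wins


def segment_windows(session: BilateralSession) -> list[tuple[PhaseWindow, np.ndarray, np.ndarray]]:
    """Cut a session into the four analysis windows.

    Each segment has exactly ``600 * fs`` samples (trailing partial samples are
    truncated).  Raises :class:`CoverageError` naming the first window the
    session does not cover.
    """
    fs = session.fs
    n = session.left.samples.size
    nwin = int(round(WINDOW_S * fs))
    out = []
    for win in phase_windows(session.stimulus_time):
        i0 = int(round(win.start * fs))
        i1 = i0 + nwin
        if i0 < 0 or i1 > n:
            raise CoverageError(
                f"session covers [0, {n / fs:.1f}] s; window {win.name} needs "
                f"[{win.start:.1f}, {win.end:.1f}] s"
            )
        out.append((win, session.left.samples[i0:i1], session.right.samples[i0:i1]))
    return out


# --------------------------------------------------------------------------
# Session sidecars and cohort layout


def write_session_sidecar(path: str | Path, subject_id: str, group: str,
                          stimulus_time_s: float, files: dict) -> None:
    doc = {
        "subject_id": subject_id,
        "group": group,
        "stimulus_time_s": float(stimulus_time_s),
        "files": {k: str(v) for k, v in files.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_session_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("subject_id", "group", "stimulus_time_s", "files"):
        if key not in doc:
            raise FormatError(f"{path}: sidecar missing key {key!r}")
    return doc


def load_session(sidecar_path: str | Path,
                 column_spec: ColumnSpec = ColumnSpec()) -> BilateralSession:
    """Load the bilateral LDF session described by a YAML sidecar."""
    sidecar_path = Path(sidecar_path)
    doc = read_session_sidecar(sidecar_path)
    base = sidecar_path.parent
    sid = str(doc["subject_id"])
    left = read_perfusion_text(base / doc["files"]["left"], column_spec,
                               side="left", subject_id=sid)
    right = read_perfusion_text(base / doc["files"]["right"], column_spec,
                                side="right", subject_id=sid)
    return BilateralSession(left, right, stimulus_time=float(doc["stimulus_time_s"]),
                            group=str(doc["group"]), subject_id=sid)


def read_design_table(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t")
    return CohortDesign(df)


def write_design_table(design: CohortDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
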