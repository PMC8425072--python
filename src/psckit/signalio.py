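"""Text-format I/O for voltage-clamp recordings and event lists.

Two plain-text formats form the on-disk contract of the toolkit:

* **recording** — tab-delimited, no header, rectangular; each *column* is one
  sweep, each row one sample; values in amperes (A) or picoamperes (pA).
* **unit file** — the persisted per-cell event list consumed by the retrieval
  layer: one line per event with three tab-separated columns
  ``time_s  amplitude_pa  selected`` (no header). Event times are *absolute*
  (sweep offset + in-sweep time) so inter-event intervals can be computed
  across the whole record.

A five-column "whole data" export tags every event with its unit-file name
and the search pattern that retrieved it. Binary acquisition formats (ABF)
are handled by an optional adapter that delegates to ``pyabf`` when that
library is installed.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalIOError",
    "FormatError",
    "ValidationError",
    "Recording",
    "UnitRecord",
    "read_text_recording",
    "write_text_recording",
    "read_unit_file",
    "write_unit_file",
    "write_whole_data",
    "read_episodic_recording",
    "append_log",
]

PA_PER_A = 1e12


class SignalIOError(Exception):
    """Base class for I/O contract violations."""


class FormatError(SignalIOError):
    """Malformed on-disk data (ragged rows, non-numeric cells, ...)."""


class ValidationError(SignalIOError):
    """In-memory object violates a format invariant."""


@dataclass
class Recording:
    """A multi-sweep current recording, stored in pA.

    ``sweeps`` is a ``(n_sweeps, n_samples)`` float array. Indexing is
    zero-based throughout; the absolute time of sample ``j`` of sweep ``i``
    is ``i * sweep_duration_s + j / sampling_rate_hz``.
    """

    sampling_rate_hz: float
    sweep_duration_s: float
    sweeps: np.ndarray
    source_path: str = ""
    unit_original: str = "pA"

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.sweep_duration_s <= 0:
            raise ValidationError("sweep_duration_s must be positive")
        if not np.all(np.isfinite(self.sweeps)):
            raise ValidationError("recording contains non-finite samples")
        expected = int(round(self.sampling_rate_hz * self.sweep_duration_s))
        if self.sweeps.shape[1] != expected:
            raise ValidationError(
                f"sweep length {self.sweeps.shape[1]} != "
                f"round(rate*duration) = {expected}"
            )

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    def time_of(self, sweep_index: int, sample_index: int) -> float:
        """Absolute time (s) of a (sweep, sample) pair, zero-based."""
        return sweep_index * self.sweep_duration_s + sample_index / self.sampling_rate_hz


@dataclass
class UnitRecord:
    """Per-cell event list: absolute times (s), amplitudes (pA), 0/1 flags."""

    name: str
    times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes_pa: np.ndarray = field(default_factory=lambda: np.empty(0))
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)
        self.selected = np.asarray(self.selected, dtype=int)

    @property
    def n_events(self) -> int:
        return self.times_s.size

    def validate(self) -> None:
        n = self.n_events
        if not (self.amplitudes_pa.size == n and self.selected.size == n):
            raise ValidationError(f"unit '{self.name}': column lengths differ")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValidationError(f"unit '{self.name}': event times not strictly increasing")
        if np.any(self.amplitudes_pa < 0):
            raise ValidationError(f"unit '{self.name}': negative amplitude")
        if not np.all(np.isin(self.selected, (0, 1))):
            raise ValidationError(f"unit '{self.name}': selection index outside {{0,1}}")
        sel = np.flatnonzero(self.selected == 1)
        if sel.size and not np.array_equal(sel, np.arange(sel[0], sel[0] + sel.size)):
            raise ValidationError(f"unit '{self.name}': selected events are not contiguous")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "amplitude_pa": self.amplitudes_pa,
                "selected": self.selected,
            }
        )

    def __eq__(self, other: object) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, UnitRecord):
            return NotImplemented
        return (
            self.name == other.name
            and np.array_equal(self.times_s, other.times_s)
            and np.array_equal(self.amplitudes_pa, other.amplitudes_pa)
            and np.array_equal(self.selected, other.selected)
        )


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(x))


def read_text_recording(
    path: str | os.PathLike,
    sampling_rate_hz: float,
    sweep_duration_s: float,
    unit: str = "pA",
) -> Recording:
    """Read a tab-delimited, header-less recording (sweeps column-wise).

    ``unit`` must be ``"A"`` or ``"pA"``; amperes are converted to pA by an
    exact factor of 1e12, pA values pass through unchanged.
    """
    if unit not in ("A", "pA"):
        raise ValidationError(f"unit must be 'A' or 'pA', got {unit!r}")
    if sampling_rate_hz <= 0 or sweep_duration_s <= 0:
        raise ValidationError("sampling rate and sweep duration must be positive")
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=r"\s+", header=None, dtype=float, engine="c",
            na_filter=False, float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty recording file") from exc
    except (pd.errors.ParserError, ValueError):
        _diagnose_text_recording(path)  # raises with a line-level message
        raise  # pragma: no cover - diagnosis always raises
    values = frame.to_numpy()
    if unit == "A":
        values = values * PA_PER_A
    return Recording(
        sampling_rate_hz=sampling_rate_hz,
        sweep_duration_s=sweep_duration_s,
        sweeps=values.T,
        source_path=str(path),
        unit_original=unit,
    )


def _diagnose_text_recording(path: Path) -> None:
    """Scan line by line to name the first offending line of a bad file."""
    ncols = None
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} values, expected {ncols}"
                )
            for tok in fields:
                try:
                    float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric value {tok!r}"
                    ) from None
    raise FormatError(f"{path}: unreadable recording file")


def write_text_recording(recording: Recording, path: str | os.PathLike) -> None:
    """Write a recording back out in the column-wise text format (pA)."""
    data = recording.sweeps.T
    with open(path, "w", newline="\n") as fh:
        for row in data:
            fh.write("\t".join(_fmt(v) for v in row))
            fh.write("\n")


def write_unit_file(record: UnitRecord, path: str | os.PathLike) -> None:
    """Persist an event list as the 3-column tab-delimited unit file."""
    record.validate()
    with open(path, "w", newline="\n") as fh:
        for t, a, s in zip(record.times_s, record.amplitudes_pa, record.selected):
            fh.write(f"{_fmt(t)}\t{_fmt(a)}\t{int(s)}\n")


def read_unit_file(path: str | os.PathLike) -> UnitRecord:
    """Read and validate a unit file; the record name is the file stem."""
    path = Path(path)
    times: list[float] = []
    amps: list[float] = []
    sel: list[int] = []
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 3"
                )
            try:
                t, a = float(fields[0]), float(fields[1])
                s_float = float(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from None
            if s_float not in (0.0, 1.0):
                raise ValidationError(
                    f"{path}: line {lineno}: selection index {fields[2]} not in {{0,1}}"
                )
            times.append(t)
            amps.append(a)
            sel.append(int(s_float))
    record = UnitRecord(path.stem, np.array(times), np.array(amps), np.array(sel, dtype=int))
    record.validate()
    return record


def write_whole_data(
    records: Sequence[UnitRecord],
    patterns: Mapping[str, str],
    path: str | os.PathLike,
) -> None:
    """Export all retrieved events to one 5-column table with a header.

    Each event line carries ``time_s, amplitude_pa, selected`` plus the name
    of its unit file and the search pattern that retrieved it (looked up by
    record name in ``patterns``).
    """
    if not records:
        raise ValidationError("write_whole_data: no unit records to export")
    with open(path, "w", newline="\n") as fh:
        fh.write("time_s\tamplitude_pa\tselected\tunit_file\tsearch_pattern\n")
        for rec in records:
            pattern = patterns.get(rec.name, "")
            for t, a, s in zip(rec.times_s, rec.amplitudes_pa, rec.selected):
                fh.write(f"{_fmt(t)}\t{_fmt(a)}\t{int(s)}\t{rec.name}\t{pattern}\n")


def read_episodic_recording(path: str | os.PathLike) -> Recording:
    """Optional adapter: load an episodic-mode ABF file via ``pyabf``.

    The text formats are the core contract; this adapter only maps sweep
    geometry from the vendor header. Gap-free (single very long sweep) files
    and sampling rates above 20 kHz are refused (recommended sampling rate:
    10-20 kHz).
    """
    path = Path(path)
    if path.suffix.lower() != ".abf":
        raise FormatError(
            f"{path}: unsupported acquisition format; only episodic ABF is "
            "handled by this adapter (use the text recording format otherwise)"
        )
    try:
        import pyabf  # type: ignore
    except ImportError as exc:
        raise SignalIOError(
            "reading ABF files requires the optional 'pyabf' dependency "
            "(pip install psckit[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    if abf.sweepCount <= 1:
        raise FormatError(
            f"{path}: not an episodic multi-sweep file; gap-free mode is not supported"
        )
    if abf.dataRate > 20000:
        raise FormatError(
            f"{path}: sampling rate {abf.dataRate} Hz exceeds 20 kHz "
            "(recommended sampling rate: 10-20 kHz)"
        )
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        sweeps.append(np.asarray(abf.sweepY, dtype=float))
    return Recording(
        sampling_rate_hz=float(abf.dataRate),
        sweep_duration_s=len(sweeps[0]) / float(abf.dataRate),
        sweeps=np.vstack(sweeps),
        source_path=str(path),
        unit_original="pA",
    )


def append_log(path: str | os.PathLike, message: str) -> None:
    """Append one time-stamped line to a plain-text analysis log."""
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(path, "a", newline="\n") as fh:
        fh.write(f"{stamp}\t{message}\n")
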