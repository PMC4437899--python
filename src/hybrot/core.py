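"""MEA geometry, spike-data containers, and tabular file I/O.

The electrode array modeled here is the standard 8x8 grid with the four
corner positions absent (60 substrate electrodes), one of which — row 5,
column 1 — is wired as ground, leaving 59 recording electrodes.  Electrodes
are addressed by a canonical 1-based label ``"r<row>c<col>"``; the
two-digit vendor-style label (column*10 + row, e.g. ``"18"`` for column 1,
row 8) is accepted anywhere a label is parsed.

Spike data are kept at electrode level (no unit sorting): a :class:`Raster`
is a time-sorted table of (electrode, time) events plus the stimulation
marks delivered during the session.  On disk both live as plain TSV.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np

__all__ = [
    "ConfigurationError",
    "RasterFormatError",
    "ProtocolFailure",
    "MEAGeometry",
    "SpikeEvent",
    "Raster",
    "StimulusCommand",
    "make_geometry",
    "parse_electrode",
    "electrode_label",
    "read_raster",
    "write_raster",
]

CORNERS = frozenset({(1, 1), (1, 8), (8, 1), (8, 8)})


class ConfigurationError(ValueError):
    """Invalid configuration (unknown layout, bad parameter set)."""


class RasterFormatError(ValueError):
    """Malformed spike/stimulation table; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ProtocolFailure(RuntimeError):
    """The experimental protocol could not proceed (e.g. unresponsive culture)."""


_LABEL_RE = re.compile(r"^r(\d+)c(\d+)$")


def parse_electrode(label: str | tuple[int, int]) -> tuple[int, int]:
    """Parse an electrode label into (row, col), both 1-based.

    Accepts the canonical ``"r5c1"`` form, a ``(row, col)`` tuple, or the
    vendor two-digit form ``"15"`` meaning column 1, row 5.
    """
    if isinstance(label, tuple):
        r, c = int(label[0]), int(label[1])
        return r, c
    s = str(label).strip().lower()
    m = _LABEL_RE.match(s)
    if m:
        return int(m.group(1)), int(m.group(2))
    if s.isdigit() and len(s) == 2:
        col, row = int(s[0]), int(s[1])
        return row, col
    raise ConfigurationError(f"unrecognized electrode label: {label!r}")


def electrode_label(row: int, col: int) -> str:
    return f"r{row}c{col}"


@dataclass(frozen=True)
class MEAGeometry:
    """8x8-minus-corners electrode grid with a ground electrode and quadrants.

    Quadrants split the grid between rows 4/5 and columns 4/5:
    quadrant 1 = rows 1-4 x cols 1-4, 2 = rows 1-4 x cols 5-8,
    3 = rows 5-8 x cols 1-4, 4 = rows 5-8 x cols 5-8.
    """

    rows: int = 8
    cols: int = 8
    excluded: frozenset[tuple[int, int]] = CORNERS
    ground: tuple[int, int] = (5, 1)
    electrode_pitch: float = 200.0  # µm

    def __post_init__(self):
        if self.ground in self.excluded:
            raise ConfigurationError("ground electrode cannot be an excluded corner")

    @property
    def grid_electrodes(self) -> list[tuple[int, int]]:
        """All substrate electrodes (ground included), row-major order."""
        return [
            (r, c)
            for r in range(1, self.rows + 1)
            for c in range(1, self.cols + 1)
            if (r, c) not in self.excluded
        ]

    @property
    def recording_electrodes(self) -> list[str]:
        """Labels of the 59 recording electrodes (ground excluded)."""
        return [
            electrode_label(r, c) for (r, c) in self.grid_electrodes if (r, c) != self.ground
        ]

    def is_recording(self, electrode: str | tuple[int, int]) -> bool:
        rc = parse_electrode(electrode)
        return (
            1 <= rc[0] <= self.rows
            and 1 <= rc[1] <= self.cols
            and rc not in self.excluded
            and rc != self.ground
        )

    def quadrant_of(self, electrode: str | tuple[int, int]) -> int:
        """Quadrant id of any grid position (the ground electrode included)."""
        r, c = parse_electrode(electrode)
        if not (1 <= r <= self.rows and 1 <= c <= self.cols):
            raise ConfigurationError(f"position off the grid: {(r, c)}")
        half_r = self.rows // 2
        half_c = self.cols // 2
        return (1 if r <= half_r else 3) + (0 if c <= half_c else 1)

    def quadrant_electrodes(self, quadrant: int, recording_only: bool = True) -> list[str]:
        out = []
        for rc in self.grid_electrodes:
            if recording_only and rc == self.ground:
                continue
            if self.quadrant_of(rc) == quadrant:
                out.append(electrode_label(*rc))
        return out

    def position(self, electrode: str | tuple[int, int]) -> tuple[float, float]:
        """Planar position of an electrode in µm; (0, 0) at row 1, col 1."""
        r, c = parse_electrode(electrode)
        return ((c - 1) * self.electrode_pitch, (r - 1) * self.electrode_pitch)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.rows,
                "cols": self.cols,
                "excluded": sorted(self.excluded),
                "ground": list(self.ground),
                "electrode_pitch_um": self.electrode_pitch,
                "recording_electrodes": self.recording_electrodes,
            },
            indent=2,
        )


_LAYOUTS = {"mcs_8x8": MEAGeometry}


def make_geometry(layout_name: str = "mcs_8x8", **overrides) -> MEAGeometry:
    """Build a named electrode layout; only ``"mcs_8x8"`` is defined."""
    try:
        cls = _LAYOUTS[layout_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown layout {layout_name!r}; known: {sorted(_LAYOUTS)}"
        ) from None
    return cls(**overrides)


class SpikeEvent(NamedTuple):
    electrode: str
    time: float  # seconds


@dataclass(frozen=True)
class StimulusCommand:
    """A biphasic pair-pulse stimulus delivered at one electrode.

    Defaults follow the sensory-coding stimulus used throughout: ±230 mV,
    negative phase first, 1.5 ms phase duration, two pulses 50 ms apart.
    """

    electrode: str
    amplitude: float = 230.0  # mV
    negative_first: bool = True
    phase_duration: float = 1.5  # ms
    pulse_count: int = 2
    inter_pulse_interval: float = 50.0  # ms

    def __post_init__(self):
        object.__setattr__(self, "electrode", electrode_label(*parse_electrode(self.electrode)))
        if self.amplitude <= 0:
            raise ConfigurationError("stimulus amplitude must be positive")
        if self.pulse_count < 1:
            raise ConfigurationError("pulse_count must be >= 1")
        if self.pulse_count > 1 and self.inter_pulse_interval <= self.phase_duration:
            raise ConfigurationError(
                "inter_pulse_interval must exceed phase_duration for multi-pulse stimuli"
            )

    def pulse_times(self, t0: float = 0.0) -> list[float]:
        """Absolute onset times (s) of the individual pulses for an onset t0."""
        return [t0 + k * self.inter_pulse_interval / 1000.0 for k in range(self.pulse_count)]


# Times are serialized at microsecond precision; quantize on construction so a
# write/read round-trip is exact.
_TIME_DECIMALS = 6


@dataclass
class Raster:
    """Electrode-level spike events for one recording session.

    ``electrodes[i]``/``times[i]`` give the i-th spike; times are sorted
    non-decreasing. ``stim_marks`` holds (time_s, electrode) for each stimulus
    command delivered, and ``pulse_times`` the expanded individual pulse onsets
    (in-memory convenience; not serialized separately from the marks).
    """

    duration: float
    electrodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    stim_marks: list[tuple[float, str]] = field(default_factory=list)
    pulse_times: list[float] = field(default_factory=list)
    geometry: MEAGeometry = field(default_factory=make_geometry)

    def __post_init__(self):
        self.electrodes = np.asarray(self.electrodes, dtype=object)
        self.times = np.round(np.asarray(self.times, dtype=float), _TIME_DECIMALS)
        self.validate()

    def validate(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if len(self.electrodes) != len(self.times):
            raise ValueError("electrodes and times must have equal length")
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted non-decreasing")
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        ground = electrode_label(*self.geometry.ground)
        for e in set(self.electrodes.tolist()):
            if e == ground:
                raise ValueError(f"spike recorded on ground electrode {ground}")
            if not self.geometry.is_recording(e):
                raise ValueError(f"spike on non-recording electrode {e}")
        for t, _e in self.stim_marks:
            if not 0 <= t <= self.duration:
                raise ValueError("stimulation mark outside session duration")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def events(self) -> Iterator[SpikeEvent]:
        return (SpikeEvent(e, t) for e, t in zip(self.electrodes, self.times))

    def spikes_of(self, electrode: str) -> np.ndarray:
        label = electrode_label(*parse_electrode(electrode))
        return self.times[self.electrodes == label]

    def active_electrodes(self) -> set[str]:
        return set(self.electrodes.tolist())

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, Raster):
            return NotImplemented
        return (
            self.duration == other.duration
            and np.array_equal(self.electrodes, other.electrodes)
            and np.array_equal(self.times, other.times)
            and self.stim_marks == other.stim_marks
        )


def _stim_path(path: Path) -> Path:
    return path.with_name(path.stem + ".stim" + path.suffix)


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write a raster as TSV (electrode, time_s) plus a companion stim-mark table.

    The duration is carried in a ``# duration_s=`` comment ahead of the header.
    Times are printed at microsecond precision, which the in-memory container
    also enforces, so write∘read is lossless.
    """
    path = Path(path)
    raster.validate()
    with open(path, "w") as fh:
        fh.write(f"# duration_s={raster.duration:.6f}\n")
        fh.write("electrode\ttime_s\n")
        for e, t in zip(raster.electrodes, raster.times):
            fh.write(f"{e}\t{t:.6f}\n")
    with open(_stim_path(path), "w") as fh:
        fh.write("time_s\telectrode\n")
        for t, e in raster.stim_marks:
            fh.write(f"{t:.6f}\t{e}\n")


def read_raster(path: str | Path, geometry: MEAGeometry | None = None) -> Raster:
    """Read a spike TSV (and its companion stim table, if present)."""
    path = Path(path)
    geometry = geometry or make_geometry()
    duration = None
    electrodes: list[str] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*duration_s\s*=\s*([0-9.eE+-]+)", line)
            if m:
                duration = float(m.group(1))
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols[:2] != ["electrode", "time_s"]:
                raise RasterFormatError(
                    f"expected header 'electrode\\ttime_s', got {line!r}", lineno
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise RasterFormatError(f"expected 2 tab-separated fields, got {len(parts)}", lineno)
        try:
            rc = parse_electrode(parts[0])
            t = float(parts[1])
        except (ConfigurationError, ValueError) as exc:
            raise RasterFormatError(str(exc), lineno) from exc
        label = electrode_label(*rc)
        if rc == geometry.ground:
            raise RasterFormatError(f"spike on ground electrode {label}", lineno)
        if not geometry.is_recording(rc):
            raise RasterFormatError(f"not a recording electrode: {label}", lineno)
        if times and t < times[-1]:
            raise RasterFormatError("spike times not sorted non-decreasing", lineno)
        electrodes.append(label)
        times.append(t)
    if not header_seen:
        raise RasterFormatError("missing header line 'electrode\\ttime_s'", 1)
    if duration is None:
        duration = times[-1] if times else 0.0
    stim_marks: list[tuple[float, str]] = []
    sp = _stim_path(path)
    if sp.exists():
        with open(sp) as fh:
            stim_lines = fh.readlines()
        for lineno, line in enumerate(stim_lines, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "time_s\telectrode":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RasterFormatError(
                    f"expected 2 tab-separated fields in stim table, got {len(parts)}", lineno
                )
            stim_marks.append((float(parts[0]), electrode_label(*parse_electrode(parts[1]))))
    return Raster(
        duration=duration,
        electrodes=np.array(electrodes, dtype=object),
        times=np.array(times, dtype=float),
        stim_marks=stim_marks,
        geometry=geometry,
    )
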