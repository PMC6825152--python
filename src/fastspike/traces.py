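"""Core containers for patch-clamp sweeps and their on-disk representation.

A :class:`Trace` is a uniformly sampled signal (membrane voltage in
current clamp, membrane current in voltage clamp).  A :class:`Sweep`
pairs a trace with the rectangular stimulus step that elicited it, and a
:class:`SweepSet` collects the stimulus family recorded from one cell —
the unit every analysis in this package operates on.

Units are fixed package-wide: time in milliseconds, voltage in
millivolts, current in picoamperes.  Sample ``i`` of a trace occurs at
``t0 + i * dt``; no module re-derives time any other way.

The native on-disk dialect is deliberately plain: one two-column CSV
(``time_ms``, value) per sweep plus a single JSON sidecar per sweep set
carrying cell id, recording mode, unit and the stimulus table.  The
files diff cleanly and round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trace",
    "StimulusStep",
    "Sweep",
    "SweepSet",
    "read_sweep_set",
    "write_sweep_set",
    "read_trace",
    "write_trace",
]

VALID_UNITS = ("mV", "pA")
VALID_MODES = ("current_clamp", "voltage_clamp")


@dataclass
class Trace:
    """Uniformly sampled signal.

    Parameters
    ----------
    dt : float
        Sampling interval, ms. Must be positive.
    samples : ndarray
        Signal values; at least two samples.
    unit : str
        ``"mV"`` or ``"pA"``.
    t0 : float
        Time of the first sample, ms.
    """

    dt: float
    samples: np.ndarray
    unit: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples in one dimension")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i*dt`` in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def span(self) -> float:
        """Duration from first to last sample, ms."""
        return self.dt * (self.n - 1)

    def index_at(self, t: float, clip: bool = False) -> int:
        """Index of the sample nearest to time ``t`` (ms)."""
        i = int(round((t - self.t0) / self.dt))
        if clip:
            return min(max(i, 0), self.n - 1)
        if not 0 <= i < self.n:
            raise ValueError(f"time {t} ms outside trace [{self.t0}, {self.t0 + self.span}]")
        return i

    def slice(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples in the half-open window ``[t_start, t_stop)`` (ms)."""
        if t_stop <= t_start:
            raise ValueError(f"empty window [{t_start}, {t_stop})")
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt - 1e-9)))
        i1 = min(self.n, int(np.ceil((t_stop - self.t0) / self.dt - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"window [{t_start}, {t_stop}) contains no samples")
        return self.samples[i0:i1]


@dataclass
class StimulusStep:
    """Rectangular current (or command) step: amplitude pA, onset/duration ms."""

    amplitude: float
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("stimulus onset must be non-negative")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Sweep:
    """One stimulus-response pair."""

    trace: Trace
    stimulus: StimulusStep
    sweep_id: str = ""

    def __post_init__(self) -> None:
        end = self.trace.t0 + self.trace.span
        if self.stimulus.onset < self.trace.t0 - 1e-9 or self.stimulus.offset > end + 1e-9:
            raise ValueError(
                f"stimulus window [{self.stimulus.onset}, {self.stimulus.offset}] ms "
                f"lies outside trace [{self.trace.t0}, {end}] ms"
            )


@dataclass
class SweepSet:
    """A family of stimulus-aligned sweeps from one cell.

    All sweeps must share sampling interval and unit, and stimulus
    amplitudes must be unique within the set so that a sweep is
    addressable by its step amplitude.
    """

    cell_id: str
    sweeps: list[Sweep]
    mode: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {VALID_MODES}")
        if not self.sweeps:
            raise ValueError("a sweep set needs at least one sweep")
        dts = {s.trace.dt for s in self.sweeps}
        if len(dts) > 1:
            raise ValueError(f"inconsistent sampling across sweeps: dt values {sorted(dts)}")
        units = {s.trace.unit for s in self.sweeps}
        if len(units) > 1:
            raise ValueError(f"inconsistent units across sweeps: {sorted(units)}")
        amps = [s.stimulus.amplitude for s in self.sweeps]
        if len(set(amps)) != len(amps):
            raise ValueError("stimulus amplitudes must be unique within a sweep set")

    @property
    def dt(self) -> float:
        return self.sweeps[0].trace.dt

    @property
    def unit(self) -> str:
        return self.sweeps[0].trace.unit

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([s.stimulus.amplitude for s in self.sweeps])

    def sweep_at(self, amplitude: float, tol: float = 1e-6) -> Sweep:
        for s in self.sweeps:
            if abs(s.stimulus.amplitude - amplitude) <= tol:
                return s
        raise KeyError(f"no sweep at {amplitude} pA in cell {self.cell_id!r}")

    def sorted_by_amplitude(self) -> list[Sweep]:
        return sorted(self.sweeps, key=lambda s: s.stimulus.amplitude)


# ---------------------------------------------------------------------------
# Native dialect I/O


def write_sweep_set(sweep_set: SweepSet, path: str | Path) -> Path:
    """Write a sweep set to ``path`` in the native dialect.

    Creates ``path`` as a directory containing one ``<sweep_id>.csv``
    per sweep (columns ``time_ms``, value) and a ``sweepset.json``
    sidecar with cell id, mode, unit, the stimulus table and any
    user metadata (preserved verbatim).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sw in enumerate(sweep_set.sweeps):
        sid = sw.sweep_id or f"sweep_{i:03d}"
        fname = f"{sid}.csv"
        t = sw.trace
        value_col = "voltage_mV" if t.unit == "mV" else "current_pA"
        arr = np.column_stack([t.times, t.samples])
        header = f"time_ms,{value_col}"
        np.savetxt(path / fname, arr, delimiter=",", header=header, comments="",
                   fmt="%.17g")
        entries.append(
            {
                "sweep_id": sid,
                "file": fname,
                "stimulus": {
                    "amplitude_pA": sw.stimulus.amplitude,
                    "onset_ms": sw.stimulus.onset,
                    "duration_ms": sw.stimulus.duration,
                },
            }
        )
    sidecar = {
        "cell_id": sweep_set.cell_id,
        "mode": sweep_set.mode,
        "unit": sweep_set.unit,
        "dt_ms": sweep_set.dt,
        "sweeps": entries,
        "metadata": sweep_set.metadata,
    }
    with open(path / "sweepset.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def read_sweep_set(path: str | Path, format_hint: str | None = None) -> SweepSet:
    """Read a sweep set written by :func:`write_sweep_set`.

    ``format_hint`` may name an optional adapter (``"abf"``, ``"nwb"``);
    no adapter ships by default, so those hints raise a clear error
    rather than guessing at file contents.
    """
    path = Path(path)
    if format_hint not in (None, "native"):
        raise NotImplementedError(
            f"no reader adapter installed for format {format_hint!r}; "
            "only the native CSV+JSON dialect is supported"
        )
    sidecar_path = path / "sweepset.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("cell_id", "mode", "unit", "dt_ms", "sweeps"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required field {key!r}")
    unit = sidecar["unit"]
    if unit not in VALID_UNITS:
        raise ValueError(f"unknown unit string {unit!r} in sidecar")
    dt = float(sidecar["dt_ms"])
    sweeps = []
    for entry in sidecar["sweeps"]:
        arr = np.loadtxt(path / entry["file"], delimiter=",", skiprows=1)
        times, values = arr[:, 0], arr[:, 1]
        step = np.diff(times)
        if step.size and not np.allclose(step, dt, rtol=1e-9, atol=1e-9):
            raise ValueError(
                f"inconsistent sampling in {entry['file']}: time column does not "
                f"match sidecar dt {dt} ms"
            )
        stim = entry["stimulus"]
        sweeps.append(
            Sweep(
                trace=Trace(dt=dt, samples=values, unit=unit, t0=float(times[0])),
                stimulus=StimulusStep(
                    amplitude=float(stim["amplitude_pA"]),
                    onset=float(stim["onset_ms"]),
                    duration=float(stim["duration_ms"]),
                ),
                sweep_id=entry["sweep_id"],
            )
        )
    return SweepSet(
        cell_id=sidecar["cell_id"],
        sweeps=sweeps,
        mode=sidecar["mode"],
        metadata=sidecar.get("metadata", {}),
    )


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a bare trace as a two-column CSV (time_ms, value)."""
    path = Path(path)
    value_col = "voltage_mV" if trace.unit == "mV" else "current_pA"
    arr = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, arr, delimiter=",", header=f"time_ms,{value_col}",
               comments="", fmt="%.17g")
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a two-column CSV trace; the unit comes from the value header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(header) != 2 or header[0] != "time_ms":
        raise ValueError(f"{path}: expected header 'time_ms,<value>'")
    unit = {"voltage_mV": "mV", "current_pA": "pA"}.get(header[1])
    if unit is None:
        raise ValueError(f"{path}: unknown unit column {header[1]!r}")
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    times, values = arr[:, 0], arr[:, 1]
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling")
    return Trace(dt=float(dts[0]), samples=values, unit=unit, t0=float(times[0]))
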