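"""Data model and I/O for MEA spike recordings, module maps and protocols.

Conventions used throughout the package:

* All times are seconds (float); a recording starts at t = 0 unless the
  file declares otherwise.
* Bins and analysis windows are half-open ``[a, b)``.
* Delimited spike tables are comma-separated UTF-8 with a single header
  line ``electrode_id,time_s``; session metadata travels in ``#``-prefixed
  ``key=value`` lines before the header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import yaml

__all__ = [
    "SpikeTrain",
    "RecordingSession",
    "ModuleMap",
    "TraceBlock",
    "ValidationError",
    "FormatError",
    "CONTROL_LABEL",
    "read_spike_table",
    "write_session",
    "read_module_map",
    "write_module_map",
    "read_trace_block",
    "write_trace_block",
    "slice_session",
]

#: Reserved module label marking control electrodes (unconnected networks).
CONTROL_LABEL = "CTRL"


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An input file does not conform to the expected layout."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps for one electrode.

    Parameters
    ----------
    electrode_id : str
        Electrode label, e.g. ``"ch1"``.
    timestamps : numpy.ndarray
        Strictly increasing spike times in seconds, all within
        ``[t_start, t_stop)``.
    t_start, t_stop : float
        Recording interval bounds in seconds.
    """

    electrode_id: str
    timestamps: np.ndarray
    t_start: float = 0.0
    t_stop: float = 0.0

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if not self.t_stop > self.t_start:
            raise ValidationError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        if ts.ndim != 1:
            raise ValidationError("timestamps must be a 1-D sequence")
        if ts.size:
            if np.any(np.diff(ts) <= 0):
                raise ValidationError(
                    f"electrode {self.electrode_id!r}: timestamps must be "
                    "strictly increasing with no duplicates"
                )
            if ts[0] < self.t_start or ts[-1] >= self.t_stop:
                raise ValidationError(
                    f"electrode {self.electrode_id!r}: timestamps outside "
                    f"[{self.t_start}, {self.t_stop})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def mean_rate(self) -> float:
        """Mean firing rate in Hz over the recording interval."""
        return self.n_spikes / self.duration


@dataclass
class RecordingSession:
    """A set of spike trains sharing one recording interval.

    ``trains`` is keyed by electrode id; every train must carry identical
    ``[t_start, t_stop)`` bounds.
    """

    trains: dict[str, SpikeTrain]
    sampling_rate: float | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValidationError("session must contain at least one electrode")
        bounds = {(tr.t_start, tr.t_stop) for tr in self.trains.values()}
        if len(bounds) != 1:
            raise ValidationError(f"trains disagree on recording interval: {bounds}")
        for eid, tr in self.trains.items():
            if eid != tr.electrode_id:
                raise ValidationError(
                    f"key {eid!r} does not match train electrode {tr.electrode_id!r}"
                )

    @property
    def t_start(self) -> float:
        return next(iter(self.trains.values())).t_start

    @property
    def t_stop(self) -> float:
        return next(iter(self.trains.values())).t_stop

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def electrode_ids(self) -> list[str]:
        return sorted(self.trains)

    def total_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())


@dataclass
class ModuleMap:
    """Assignment of electrodes to named network modules.

    Control electrodes (in unconnected networks on the same array) carry
    the reserved :data:`CONTROL_LABEL`.  Electrodes listed in ``excluded``
    are dropped from every analysis.
    """

    assignment: dict[str, str]
    control_label: str = CONTROL_LABEL
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValidationError("module map contains no modules")
        overlap = set(self.assignment) & set(self.excluded)
        if overlap:
            raise ValidationError(
                f"electrodes both mapped and excluded: {sorted(overlap)}"
            )

    @property
    def modules(self) -> list[str]:
        """Non-control module labels, sorted."""
        return sorted({m for m in self.assignment.values() if m != self.control_label})

    def module_of(self, electrode_id: str) -> str | None:
        return self.assignment.get(electrode_id)

    def is_control(self, electrode_id: str) -> bool:
        return self.assignment.get(electrode_id) == self.control_label

    def electrodes_in(self, module: str) -> list[str]:
        return sorted(e for e, m in self.assignment.items() if m == module)

    def unknown_electrodes(self, session: RecordingSession) -> list[str]:
        """Session electrodes neither mapped nor explicitly excluded."""
        known = set(self.assignment) | set(self.excluded)
        return sorted(set(session.trains) - known)


@dataclass
class TraceBlock:
    """Raw multichannel voltage traces (microvolts), channels x samples."""

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} trace rows"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

_TIME_FMT = "%.9f"  # delimited round trip is exact to 1 ns


def _build_session(
    per_electrode: Mapping[str, Iterable[float]],
    t_start: float,
    t_stop: float,
    sampling_rate: float | None,
    annotations: dict | None,
) -> RecordingSession:
    trains = {}
    for eid in per_electrode:
        ts = np.sort(np.asarray(list(per_electrode[eid]), dtype=float))
        if ts.size and np.any(np.diff(ts) == 0):
            raise ValidationError(f"electrode {eid!r}: duplicate timestamps")
        trains[eid] = SpikeTrain(eid, ts, t_start, t_stop)
    return RecordingSession(trains, sampling_rate, dict(annotations or {}))


def read_spike_table(
    path: str | Path,
    format: str = "auto",
    t_start: float | None = None,
    t_stop: float | None = None,
    electrodes: Sequence[str] | None = None,
) -> RecordingSession:
    """Read a spike timestamp table into a :class:`RecordingSession`.

    Timestamps are sorted per electrode on read; duplicate timestamps on
    one electrode raise :class:`ValidationError` naming the electrode.
    ``t_start``/``t_stop`` override any values declared in the file;
    ``electrodes`` declares electrodes that must appear in the session even
    if they fired no spikes.
    """
    path = Path(path)
    if format == "auto":
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "delimited"
    if format == "hdf5":
        return _read_spike_hdf5(path, t_start, t_stop, electrodes)
    if format == "delimited":
        return _read_spike_csv(path, t_start, t_stop, electrodes)
    raise ValueError(f"unknown format {format!r}")


def _read_spike_csv(path, t_start, t_stop, electrodes):
    meta: dict[str, str] = {}
    header = None
    rows: list[tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:2] != ["electrode_id", "time_s"]:
                    raise FormatError(
                        f"{path}: expected header 'electrode_id,time_s', "
                        f"got {','.join(header)!r}"
                    )
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed row {line!r}")
            rows.append((parts[0].strip(), float(parts[1])))
    if header is None:
        raise FormatError(f"{path}: missing header line")

    if t_start is None:
        t_start = float(meta.get("t_start", 0.0))
    if t_stop is None:
        if "t_stop" not in meta:
            raise FormatError(f"{path}: t_stop neither declared in file nor supplied")
        t_stop = float(meta["t_stop"])
    declared = [e for e in meta.get("electrodes", "").split(";") if e]
    per: dict[str, list[float]] = {e: [] for e in declared}
    for e in electrodes or []:
        per.setdefault(e, [])
    for eid, t in rows:
        per.setdefault(eid, []).append(t)
    if not per:
        raise FormatError(f"{path}: no electrodes declared and no spike rows")
    sr = float(meta["sampling_rate"]) if "sampling_rate" in meta else None
    return _build_session(per, t_start, t_stop, sr, {"source": str(path)})


def _read_spike_hdf5(path, t_start, t_stop, electrodes):
    with h5py.File(path, "r") as f:
        if t_start is None:
            t_start = float(f.attrs["t_start"])
        if t_stop is None:
            t_stop = float(f.attrs["t_stop"])
        sr = float(f.attrs["sampling_rate"]) if "sampling_rate" in f.attrs else None
        grp = f["trains"]
        per = {eid: np.asarray(grp[eid][()], dtype=float) for eid in grp}
    for e in electrodes or []:
        per.setdefault(e, np.empty(0))
    return _build_session(per, t_start, t_stop, sr, {"source": str(path)})


def write_session(
    session: RecordingSession, path: str | Path, format: str = "auto"
) -> Path:
    """Write a session so that :func:`read_spike_table` round-trips it.

    HDF5 round trips are bit-identical; delimited text is exact to the
    fixed decimal precision of the writer (9 decimal places).
    """
    path = Path(path)
    if format == "auto":
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "delimited"
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["t_start"] = session.t_start
            f.attrs["t_stop"] = session.t_stop
            if session.sampling_rate is not None:
                f.attrs["sampling_rate"] = session.sampling_rate
            grp = f.create_group("trains")
            for eid in session.electrode_ids:
                grp.create_dataset(eid, data=session.trains[eid].timestamps)
        return path
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# t_start={session.t_start!r}\n")
        fh.write(f"# t_stop={session.t_stop!r}\n")
        if session.sampling_rate is not None:
            fh.write(f"# sampling_rate={session.sampling_rate!r}\n")
        fh.write(f"# electrodes={';'.join(session.electrode_ids)}\n")
        fh.write("electrode_id,time_s\n")
        for eid in session.electrode_ids:
            for t in session.trains[eid].timestamps:
                fh.write(f"{eid},{_TIME_FMT % t}\n")
    return path


def slice_session(
    session: RecordingSession, t_start: float, t_stop: float
) -> RecordingSession:
    """Restrict a session to the sub-window ``[t_start, t_stop)``.

    Timestamps keep their absolute values; only the interval bounds and
    the spike content change.
    """
    if not session.t_start <= t_start < t_stop <= session.t_stop:
        raise ValidationError(
            f"window [{t_start}, {t_stop}) outside recording "
            f"[{session.t_start}, {session.t_stop})"
        )
    trains = {}
    for eid, tr in session.trains.items():
        ts = tr.timestamps
        trains[eid] = SpikeTrain(
            eid, ts[(ts >= t_start) & (ts < t_stop)], t_start, t_stop
        )
    return RecordingSession(trains, session.sampling_rate, dict(session.annotations))


# ---------------------------------------------------------------------------
# Module maps and config files
# ---------------------------------------------------------------------------


def _load_config(path: Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if Path(path).suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_module_map(path: str | Path) -> ModuleMap:
    """Read an electrode-to-module map from a YAML or JSON config.

    Accepted layouts: a flat mapping ``{module: [electrodes]}``, or a
    mapping with keys ``modules`` (same flat mapping), optional
    ``control`` (list of control electrodes) and ``excluded``.
    """
    raw = _load_config(Path(path))
    if not isinstance(raw, dict) or not raw:
        raise ValidationError(f"{path}: module map is empty or not a mapping")
    if "modules" in raw:
        modules = dict(raw["modules"] or {})
        for e in raw.get("control", []) or []:
            modules.setdefault(CONTROL_LABEL, [])
            modules[CONTROL_LABEL] = list(modules[CONTROL_LABEL]) + [e]
        excluded = frozenset(raw.get("excluded", []) or [])
    else:
        modules = raw
        excluded = frozenset()
    if not modules:
        raise ValidationError(f"{path}: no modules defined")
    assignment: dict[str, str] = {}
    for module, members in modules.items():
        for e in members or []:
            if e in assignment:
                raise ValidationError(
                    f"electrode {e!r} assigned to both "
                    f"{assignment[e]!r} and {module!r}"
                )
            assignment[str(e)] = str(module)
    return ModuleMap(assignment, excluded=excluded)


def write_module_map(mmap: ModuleMap, path: str | Path) -> Path:
    modules: dict[str, list[str]] = {}
    for e, m in sorted(mmap.assignment.items()):
        modules.setdefault(m, []).append(e)
    doc = {"modules": modules}
    if mmap.excluded:
        doc["excluded"] = sorted(mmap.excluded)
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Raw traces
# ---------------------------------------------------------------------------


def read_trace_block(path: str | Path) -> TraceBlock:
    with h5py.File(path, "r") as f:
        samples = np.asarray(f["samples"][()], dtype=float)
        sr = float(f.attrs["sampling_rate"])
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_ids"][()]]
    return TraceBlock(samples, sr, ids)


def write_trace_block(block: TraceBlock, path: str | Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=block.samples)
        f.attrs["sampling_rate"] = block.sampling_rate
        f.create_dataset(
            "channel_ids", data=np.array(block.channel_ids, dtype=h5py.string_dtype())
        )
    return Path(path)
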