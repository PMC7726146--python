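"""Burst and synchronized-event detection, association and propagation.

A *burst* is a maximal run of successive spikes on one electrode with
every inter-spike gap at or below 200 ms.  A *synchronized bursting
event* (SBE) is a time window in which bursts overlap on two or more
electrodes; overlap is closed-interval (touching endpoints count) and
transitive, so chains of overlapping bursts merge into a single event.
An *inter-network synchronized event* (SE) is an SBE whose participants
span two or more network modules.  The association degree of an electrode
is the fraction of its spikes that fall inside SE windows, and the
propagation direction of an SE orders the participating modules by their
first spike time inside the event.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_core import ModuleMap, RecordingSession, SpikeTrain, ValidationError

__all__ = [
    "Burst",
    "SyncEvent",
    "PropagationLabel",
    "detect_bursts",
    "session_bursts",
    "detect_sbes",
    "classify_ses",
    "association_degree",
    "propagation_direction",
    "propagation_proportions",
    "detect_session_events",
]

DEFAULT_ISI_THRESHOLD = 0.2
DEFAULT_MIN_SPIKES = 3
DEFAULT_TIE_TOLERANCE = 0.001


@dataclass(frozen=True)
class Burst:
    """A run of spikes on one electrode with gaps <= the ISI threshold."""

    electrode_id: str
    start: float
    end: float
    spike_count: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("burst end precedes start")


@dataclass
class SyncEvent:
    """A synchronized window; ``kind`` is ``"SBE"`` or ``"SE"``.

    The window spans the union of the participating burst intervals (and
    is extended by counted single spikes under the single-spike rule).
    """

    start: float
    end: float
    electrodes: frozenset[str]
    kind: str = "SBE"
    modules: frozenset[str] = frozenset()
    first_spike_times: dict[str, float] = field(default_factory=dict)

    @property
    def window(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass(frozen=True)
class PropagationLabel:
    """Module ordering of one SE by first-spike time, or ``ambiguous``."""

    sequence: tuple[str, ...]
    first_spikes: tuple[tuple[str, float], ...]
    ambiguous: bool = False


def detect_bursts(
    train: SpikeTrain,
    isi_threshold: float = DEFAULT_ISI_THRESHOLD,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> list[Burst]:
    """Detect bursts as maximal runs of spikes with gaps <= ``isi_threshold``.

    A gap exactly equal to the threshold keeps the run together ("within"
    is inclusive).  Runs with fewer than ``min_spikes`` spikes are
    discarded.  The burst window is ``[first spike, last spike]``.
    """
    if isi_threshold <= 0:
        raise ValidationError("isi_threshold must be positive")
    if min_spikes < 2:
        raise ValidationError("min_spikes must be >= 2")
    ts = train.timestamps
    if ts.size < min_spikes:
        return []
    breaks = np.flatnonzero(np.diff(ts) > isi_threshold) + 1
    bursts = []
    for run in np.split(ts, breaks):
        if run.size >= min_spikes:
            bursts.append(
                Burst(train.electrode_id, float(run[0]), float(run[-1]), int(run.size))
            )
    return bursts


def session_bursts(
    session: RecordingSession,
    isi_threshold: float = DEFAULT_ISI_THRESHOLD,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    electrodes: list[str] | None = None,
) -> list[Burst]:
    out: list[Burst] = []
    for eid in electrodes if electrodes is not None else session.electrode_ids:
        out.extend(detect_bursts(session.trains[eid], isi_threshold, min_spikes))
    return out


def detect_sbes(bursts: list[Burst]) -> list[SyncEvent]:
    """Group overlapping bursts into synchronized bursting events.

    Burst intervals are treated as closed, so touching endpoints overlap,
    and overlap is merged transitively: a chain of pairwise-overlapping
    bursts forms one event.  Connected components whose bursts span at
    least two electrodes become SBEs; the event window is the union span
    of the component's burst intervals.
    """
    if not bursts:
        return []
    ordered = sorted(bursts, key=lambda b: (b.start, b.end, b.electrode_id))
    events: list[SyncEvent] = []
    cur = [ordered[0]]
    cur_end = ordered[0].end
    for b in ordered[1:]:
        if b.start <= cur_end:  # closed-interval overlap (touching counts)
            cur.append(b)
            cur_end = max(cur_end, b.end)
        else:
            events.extend(_component_to_sbe(cur))
            cur, cur_end = [b], b.end
    events.extend(_component_to_sbe(cur))
    return events


def _component_to_sbe(component: list[Burst]) -> list[SyncEvent]:
    electrodes = frozenset(b.electrode_id for b in component)
    if len(electrodes) < 2:
        return []
    return [
        SyncEvent(
            start=min(b.start for b in component),
            end=max(b.end for b in component),
            electrodes=electrodes,
            kind="SBE",
        )
    ]


def classify_ses(
    sbes: list[SyncEvent],
    mmap: ModuleMap,
    session: RecordingSession | None = None,
    single_spike_rule: bool = False,
) -> list[SyncEvent]:
    """Promote SBEs to inter-network synchronized events (SEs).

    An SBE is an SE when its participating electrodes span two or more
    non-control modules.  With ``single_spike_rule`` on (used for
    two-electrode-per-network layouts), a single-module SBE is also
    promoted when any electrode of another module fires at least one
    spike inside the SBE window; that electrode joins the participants.
    """
    if single_spike_rule and session is None:
        raise ValidationError("single_spike_rule requires the session's spike trains")
    ses = []
    for ev in sbes:
        electrodes = set(ev.electrodes)
        modules = {
            mmap.module_of(e)
            for e in electrodes
            if mmap.module_of(e) is not None and not mmap.is_control(e)
        }
        if len(modules) < 2 and single_spike_rule:
            for eid, train in session.trains.items():
                if eid in electrodes or mmap.is_control(eid):
                    continue
                m = mmap.module_of(eid)
                if m is None or m in modules:
                    continue
                ts = train.timestamps
                if np.any((ts >= ev.start) & (ts <= ev.end)):
                    electrodes.add(eid)
                    modules.add(m)
        if len(modules) >= 2:
            ses.append(
                SyncEvent(
                    start=ev.start,
                    end=ev.end,
                    electrodes=frozenset(electrodes),
                    kind="SE",
                    modules=frozenset(modules),
                )
            )
    return ses


def _merged_windows(events: list[SyncEvent]) -> list[tuple[float, float]]:
    ivals = sorted((ev.start, ev.end) for ev in events)
    merged: list[tuple[float, float]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def association_degree(
    session: RecordingSession, ses: list[SyncEvent]
) -> dict[str, float]:
    """Fraction of each electrode's spikes that fall inside SE windows.

    Windows are merged first; membership is closed (a spike at a window
    endpoint participates, matching the burst windows that bound it).
    Electrodes with zero spikes map to NaN.
    """
    windows = _merged_windows(ses)
    out: dict[str, float] = {}
    for eid in session.electrode_ids:
        ts = session.trains[eid].timestamps
        if ts.size == 0:
            out[eid] = math.nan
            continue
        inside = 0
        for s, e in windows:
            inside += int(
                np.searchsorted(ts, e, side="right") - np.searchsorted(ts, s, side="left")
            )
        out[eid] = inside / ts.size
    return out


def propagation_direction(
    se: SyncEvent,
    mmap: ModuleMap,
    session: RecordingSession,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> PropagationLabel:
    """Order the modules of an SE by their first spike time in the window.

    Each module's first-spike time is the minimum over its participating
    electrodes' spikes inside the (closed) event window.  If the two
    earliest modules are separated by less than ``tie_tolerance`` the
    event is labeled ambiguous and excluded from direction tallies.
    """
    if se.kind != "SE":
        raise ValidationError("propagation direction is defined for SEs only")
    firsts: dict[str, float] = {}
    for eid in se.electrodes:
        m = mmap.module_of(eid)
        if m is None or mmap.is_control(eid):
            continue
        ts = session.trains[eid].timestamps
        inside = ts[(ts >= se.start) & (ts <= se.end)]
        if inside.size:
            t0 = float(inside[0])
            if m not in firsts or t0 < firsts[m]:
                firsts[m] = t0
    order = sorted(firsts, key=firsts.get)
    ambiguous = (
        len(order) >= 2 and firsts[order[1]] - firsts[order[0]] < tie_tolerance
    )
    return PropagationLabel(
        sequence=tuple(order),
        first_spikes=tuple(sorted(firsts.items(), key=lambda kv: kv[1])),
        ambiguous=ambiguous,
    )


def propagation_proportions(labels: list[PropagationLabel]) -> dict[tuple[str, ...], float]:
    """Fraction of unambiguous SEs per distinct module sequence."""
    usable = [lab for lab in labels if not lab.ambiguous and len(lab.sequence) >= 2]
    if not usable:
        raise ValidationError("no unambiguous propagation labels")
    counts = Counter(lab.sequence for lab in usable)
    total = sum(counts.values())
    return {seq: c / total for seq, c in counts.items()}


def detect_session_events(
    session: RecordingSession,
    mmap: ModuleMap,
    isi_threshold: float = DEFAULT_ISI_THRESHOLD,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    single_spike_rule: bool = False,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    electrodes: list[str] | None = None,
):
    """Run the full event chain: bursts -> SBEs -> SEs -> labels.

    Returns ``(sbes, ses, association, labels)`` where ``association``
    maps electrode ids to SE participation fractions and ``labels`` holds
    one :class:`PropagationLabel` per SE.
    """
    if electrodes is None:
        electrodes = [
            e for e in session.electrode_ids
            if e not in mmap.excluded and mmap.module_of(e) is not None
        ]
    bursts = session_bursts(session, isi_threshold, min_spikes, electrodes)
    sbes = detect_sbes(bursts)
    ses = classify_ses(sbes, mmap, session, single_spike_rule)
    assoc = association_degree(session, ses)
    labels = [propagation_direction(se, mmap, session, tie_tolerance) for se in ses]
    return sbes, ses, assoc, labels
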