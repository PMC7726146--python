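"""Peri-stimulus time histograms and evoked-response statistics.

Electrical-stimulation trials (e.g. 20 pulses delivered every 3 s) are
summarized by PSTHs over a 50 ms post-stimulus window and by the
response probability — the fraction of trials with at least one spike in
a response window.  Responses in the early window (< 10 ms) reflect
direct/antidromic activation within the stimulated network; responses in
the late 15-35 ms window indicate synaptic propagation from another
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import SpikeTrain, ValidationError

__all__ = [
    "StimTrialSet",
    "PSTH",
    "build_psth",
    "mean_psth",
    "response_probability",
    "early_late_split",
]

DEFAULT_WINDOW = 0.05
DEFAULT_BLANK = 0.002
EARLY_WINDOW = (0.0, 0.010)
LATE_WINDOW = (0.015, 0.035)


@dataclass(frozen=True)
class StimTrialSet:
    """A train of stimulation pulses on one electrode."""

    stim_electrode: str
    stim_times: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.stim_times, dtype=float)
        object.__setattr__(self, "stim_times", st)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValidationError("stim_times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return int(self.stim_times.size)


@dataclass
class PSTH:
    """Post-stimulus spike counts per bin over ``[0, window)``.

    Bins fully inside the artifact blank are masked (reported, not
    silently zero).  ``rate`` normalizes counts by trials x bin width.
    """

    electrode_id: str
    bin_width: float
    counts: np.ndarray
    n_trials: int
    window: float
    blank: float

    @property
    def edges(self) -> np.ndarray:
        return self.bin_width * np.arange(self.counts.size + 1)

    @property
    def masked(self) -> np.ndarray:
        """Boolean per bin: True where the bin lies inside the blank."""
        return self.edges[1:] <= self.blank + 1e-12

    @property
    def rate(self) -> np.ndarray:
        return self.counts / (self.n_trials * self.bin_width)

    def total_count(self) -> int:
        return int(self.counts.sum())


def build_psth(
    train: SpikeTrain,
    stim_times,
    bin_width: float = 0.001,
    window: float = DEFAULT_WINDOW,
    blank: float = DEFAULT_BLANK,
) -> PSTH:
    """Histogram spike times relative to the preceding stimulus.

    Spikes are re-referenced to the nearest preceding stimulus and
    counted over the half-open ``(blank, window)`` interval into
    half-open bins covering ``[0, window)``; bins inside the blank stay
    masked.  Consecutive stimuli closer than ``window`` raise an error.
    """
    stim = np.sort(np.asarray(list(stim_times), dtype=float))
    if stim.size == 0:
        raise ValidationError("no stimulus times")
    if stim.size > 1 and np.min(np.diff(stim)) < window:
        raise ValidationError("analysis windows of consecutive stimuli overlap")
    if blank < 0 or window <= blank:
        raise ValidationError("need 0 <= blank < window")
    n_bins = int(math.ceil(window / bin_width - 1e-9))
    counts = np.zeros(n_bins)
    ts = train.timestamps
    idx = np.searchsorted(stim, ts, side="right") - 1
    ok = idx >= 0
    rel = ts[ok] - stim[idx[ok]]
    rel = rel[(rel > blank) & (rel < window)]
    # snap keeps spikes at exact decimal bin edges in the opening bin
    b = np.floor(rel / bin_width + 1e-9).astype(int)
    np.add.at(counts, np.clip(b, 0, n_bins - 1), 1)
    return PSTH(train.electrode_id, bin_width, counts, int(stim.size), window, blank)


def mean_psth(psths: list[PSTH]) -> PSTH:
    """Average PSTH over recording electrodes (equal bin grids)."""
    if not psths:
        raise ValidationError("no PSTHs to average")
    grids = {(p.bin_width, p.counts.size, p.n_trials, p.blank) for p in psths}
    if len(grids) != 1:
        raise ValidationError("PSTHs on mismatched grids")
    counts = np.mean([p.counts for p in psths], axis=0)
    p0 = psths[0]
    return PSTH("mean", p0.bin_width, counts, p0.n_trials, p0.window, p0.blank)


def response_probability(
    train: SpikeTrain, stim_times, response_window: tuple[float, float] = LATE_WINDOW
) -> float:
    """Fraction of trials with >= 1 spike in ``[a, b)`` post-stimulus."""
    a, b = response_window
    if b <= a:
        raise ValidationError("response window must have positive duration")
    stim = np.sort(np.asarray(list(stim_times), dtype=float))
    if stim.size == 0:
        raise ValidationError("no stimulus times")
    if stim.size > 1 and np.min(np.diff(stim)) < b:
        raise ValidationError("response windows of consecutive stimuli overlap")
    ts = train.timestamps
    hits = 0
    for t in stim:
        lo = np.searchsorted(ts, t + a, side="left")
        hi = np.searchsorted(ts, t + b, side="left")
        hits += int(hi > lo)
    return hits / stim.size


def early_late_split(
    psth: PSTH,
    early: tuple[float, float] = EARLY_WINDOW,
    late: tuple[float, float] = LATE_WINDOW,
) -> dict[str, float]:
    """Summed PSTH rate in the early (< 10 ms) and late (15-35 ms) windows.

    Bin edges must align with the window boundaries.  The early sum flags
    direct/antidromic responses in the stimulated network; the late sum
    flags inter-network synaptic propagation.
    """
    edges = psth.edges
    for bound in (*early, *late):
        if not np.any(np.isclose(edges, bound, atol=1e-9)):
            raise ValidationError(
                f"window boundary {bound} s does not align with bin edges"
            )

    def _sum(win):
        a, b = win
        sel = (edges[:-1] >= a - 1e-12) & (edges[1:] <= b + 1e-12) & ~psth.masked
        return float(psth.rate[sel].sum() * psth.bin_width)

    return {"early": _sum(early), "late": _sum(late)}
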