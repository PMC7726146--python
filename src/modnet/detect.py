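"""Threshold-based spike detection from extracellular voltage traces.

Spikes are extracted as negative threshold crossings at ``-k_sd`` times the
background noise SD, the convention used for multi-unit MEA recordings.
The noise SD is by default estimated with the median absolute deviation
(MAD / 0.6745), which is insensitive to the spikes themselves; the plain
sample SD is available for comparison.  Stimulation artifacts are handled
by blanking a short window after each stimulus rather than by spike
sorting, so every analysis stays at the electrode (multi-unit) level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_core import SpikeTrain, TraceBlock, ValidationError

__all__ = [
    "DetectionParams",
    "DegenerateSignalError",
    "estimate_noise_sd",
    "detect_spikes",
    "detect_session",
    "blank_stimulus_artifacts",
    "bandpass_filter",
]


class DegenerateSignalError(ValueError):
    """The trace carries no resolvable noise (e.g. constant signal)."""


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection parameters.

    k_sd : float
        Threshold multiplier; spikes are crossings below ``-k_sd * sigma``
        where sigma is the background noise SD.  Default 6.
    dead_time : float
        Seconds after a detection during which further crossings are
        ignored, preventing one waveform from being counted several times.
        Default 1 ms.
    noise_estimator : {"robust_mad", "global_sd"}
        How sigma is computed.
    """

    k_sd: float = 6.0
    dead_time: float = 0.001
    noise_estimator: str = "robust_mad"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValidationError("k_sd must be positive")
        if self.dead_time < 0:
            raise ValidationError("dead_time must be non-negative")
        if self.noise_estimator not in {"robust_mad", "global_sd"}:
            raise ValidationError(f"unknown noise estimator {self.noise_estimator!r}")


def estimate_noise_sd(trace: np.ndarray, estimator: str = "robust_mad") -> float:
    """Estimate the background noise SD (microvolts) of a single channel.

    ``robust_mad`` returns ``median(|x - median(x)|) / 0.6745``, the MAD
    scaled to be consistent with the SD of Gaussian noise; ``global_sd``
    returns the plain sample SD, which is inflated by large spikes.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValidationError(f"trace too short for noise estimation ({x.size} samples)")
    if estimator == "robust_mad":
        sd = float(np.median(np.abs(x - np.median(x))) / 0.6745)
    elif estimator == "global_sd":
        sd = float(np.std(x))
    else:
        raise ValidationError(f"unknown noise estimator {estimator!r}")
    if sd == 0.0:
        raise DegenerateSignalError("zero noise SD: trace is (locally) constant")
    return sd


def detect_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    params: DetectionParams = DetectionParams(),
    electrode_id: str = "ch",
) -> SpikeTrain:
    """Detect spikes as negative threshold crossings on one channel.

    A spike timestamp is the first sample strictly below
    ``-k_sd * sigma``, i.e. the crossing sample index divided by the
    sampling rate.  Crossings within ``dead_time`` of the previous
    detection are discarded.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    x = np.asarray(trace, dtype=float)
    sigma = estimate_noise_sd(x, params.noise_estimator)
    threshold = -params.k_sd * sigma

    below = x < threshold
    # first sample of each below-threshold excursion
    crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    times = crossings / sampling_rate
    if times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= params.dead_time:
                kept.append(t)
        times = np.array(kept)
    t_stop = x.size / sampling_rate
    return SpikeTrain(electrode_id, times, 0.0, t_stop)


def detect_session(
    block: TraceBlock, params: DetectionParams = DetectionParams()
):
    """Run :func:`detect_spikes` on every channel of a trace block."""
    from .io_core import RecordingSession

    trains = {
        cid: detect_spikes(block.samples[i], block.sampling_rate, params, cid)
        for i, cid in enumerate(block.channel_ids)
    }
    return RecordingSession(trains, sampling_rate=block.sampling_rate)


def blank_stimulus_artifacts(
    train: SpikeTrain, stim_times, blank_window: float = 0.002
) -> SpikeTrain:
    """Remove spikes falling in ``[t_stim, t_stim + blank_window)``.

    Stands in for sorting-based artifact rejection: electrical artifacts
    are locked to the stimulus, so a short post-stimulus blank removes
    them deterministically.
    """
    if blank_window < 0:
        raise ValidationError("blank_window must be non-negative")
    stim = np.sort(np.asarray(list(stim_times), dtype=float))
    if stim.size == 0 or train.n_spikes == 0:
        return train
    ts = train.timestamps
    idx = np.searchsorted(stim, ts, side="right") - 1
    prev = np.where(idx >= 0, stim[np.clip(idx, 0, None)], -np.inf)
    keep = ~((ts >= prev) & (ts < prev + blank_window))
    return SpikeTrain(train.electrode_id, ts[keep], train.t_start, train.t_stop)


def bandpass_filter(
    trace: np.ndarray,
    sampling_rate: float,
    low: float = 150.0,
    high: float = 4000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (150-4000 Hz default).

    Optional: MEA amplifiers usually apply this band in hardware; the
    helper is provided for wide-band traces.
    """
    sos = signal.butter(
        order, [low, high], btype="bandpass", fs=sampling_rate, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))
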