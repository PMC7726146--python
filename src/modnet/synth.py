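"""Synthetic modular bursting networks with exported ground truth.

The generator emulates the statistical structure the analyses assume:
each module produces population bursts as a Poisson event process, every
burst recruits a random subset of the module's electrodes which fire a
Poisson number of spikes spread over the burst window, and directed
couplings let a burst in one module trigger a burst in another after a
truncated-Gaussian delay, with per-burst probability ``p``.  Suppression
epochs thin the target module's spike generation (bursts, background,
and the triggering of coupled modules) by a power-dependent factor, and
electrical stimulation evokes delayed spikes with a per-trial response
probability.  All randomness derives from one seed, and every generated
spike is attributable to background, a burst, or an evoked response.

Propagation is modeled at the burst-event level (trigger + delay), not
with synaptic dynamics: the analyses only see spike times, and this
yields exact ground truth for propagation-direction and influence
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    CONTROL_LABEL,
    ModuleMap,
    RecordingSession,
    SpikeTrain,
    TraceBlock,
    ValidationError,
)
from .modulation import ModulationEpoch

__all__ = [
    "ModuleSpec",
    "Coupling",
    "SimConfig",
    "BurstEvent",
    "SimGroundTruth",
    "SessionBundle",
    "simulate_module_bursts",
    "couple_modules",
    "apply_suppression",
    "generate_session",
    "make_suppression_protocol",
    "asymmetric_pair_config",
    "coupled_pair_config",
    "uncoupled_pair_config",
    "spike_waveform",
    "render_noise_traces",
    "evoked_session",
    "DEFAULT_SUPPRESSION_FACTORS",
]

#: Power density (mW/mm^2) -> rate-scaling factor during the epoch.
#: Matches a monotone suppression curve reaching full suppression at the
#: highest level.
DEFAULT_SUPPRESSION_FACTORS = {30.0: 0.9, 80.0: 0.65, 140.0: 0.4, 200.0: 0.15, 243.0: 0.0}

_MAX_CHAIN_DEPTH = 60


@dataclass(frozen=True)
class ModuleSpec:
    """One network module of the simulated culture.

    ``burst_rate`` is the module's *total* population-burst rate
    (events/min) including bursts triggered through couplings;
    ``driven_fraction`` is the fraction of that total expected to be
    triggered by source modules, so the intrinsic Poisson rate is
    ``burst_rate * (1 - driven_fraction)``.
    """

    label: str
    n_electrodes: int = 4
    background_rate: float = 0.1  # Hz per electrode
    burst_rate: float = 12.0  # events/min, total
    burst_duration: float = 0.2  # s; <= the 200 ms ISI threshold so a
    # burst can never split under burst detection
    spikes_per_burst: float = 10.0  # mean per participating electrode
    participation: float = 0.9  # per-electrode recruitment probability
    driven_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValidationError(f"module {self.label}: need >= 1 electrode")
        if not 0 <= self.participation <= 1:
            raise ValidationError(f"module {self.label}: participation not in [0,1]")
        if not 0 <= self.driven_fraction <= 1:
            raise ValidationError(f"module {self.label}: driven_fraction not in [0,1]")
        if min(self.background_rate, self.burst_rate) < 0 or self.burst_duration <= 0:
            raise ValidationError(f"module {self.label}: invalid rates/duration")


@dataclass(frozen=True)
class Coupling:
    """Directed burst coupling: each source burst triggers a target burst
    with probability ``probability`` after a positive Gaussian delay."""

    source: str
    target: str
    probability: float
    delay_mean: float = 0.03
    delay_sd: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValidationError("coupling probability must be in [0,1]")
        if self.delay_mean <= 0 or self.delay_sd < 0:
            raise ValidationError("delays must be positive")


@dataclass
class SimConfig:
    """Full generator configuration; ``seed`` fixes all randomness."""

    modules: list[ModuleSpec]
    couplings: list[Coupling] = field(default_factory=list)
    duration: float = 600.0
    seed: int = 0
    suppression_factors: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPRESSION_FACTORS)
    )
    ablation_time: float | None = None  # couplings inactive from this time on

    def __post_init__(self) -> None:
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate module labels")
        for c in self.couplings:
            if c.source not in labels or c.target not in labels:
                raise ValidationError(f"coupling references unknown module: {c}")
        for p, f in self.suppression_factors.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"suppression factor at {p} not in [0,1]")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    def module(self, label: str) -> ModuleSpec:
        for m in self.modules:
            if m.label == label:
                return m
        raise KeyError(label)

    def electrode_ids(self, label: str) -> list[str]:
        m = self.module(label)
        return [f"{label}_e{i+1}" for i in range(m.n_electrodes)]

    def module_map(self) -> ModuleMap:
        assignment = {
            e: m.label for m in self.modules for e in self.electrode_ids(m.label)
        }
        return ModuleMap(assignment)


@dataclass
class BurstEvent:
    """Ground-truth record of one population burst.

    ``suppressed`` marks a burst whose onset fell in a suppression epoch
    and failed the factor coin: it does not trigger coupled modules, and
    its spikes are (like all spikes) thinned at emission time.
    """

    burst_id: int
    module: str
    onset: float
    triggered_by: int | None = None  # source burst id, None if intrinsic
    delay: float = 0.0
    suppressed: bool = False
    depth: int = 0

    @property
    def intrinsic(self) -> bool:
        return self.triggered_by is None


@dataclass
class SimGroundTruth:
    """Hidden parameters and per-event provenance of a generated session."""

    bursts: list[BurstEvent]
    spike_categories: dict[str, int]  # background / burst / evoked counts
    driven_fraction_realized: dict[str, float]
    epoch_factors: list[tuple[ModulationEpoch, float]] = field(default_factory=list)
    evoked_times: dict[str, list[float]] = field(default_factory=dict)
    injected_times: dict[str, list[float]] = field(default_factory=dict)

    def surviving_bursts(self, module: str | None = None) -> list[BurstEvent]:
        return [
            b
            for b in self.bursts
            if not b.suppressed and (module is None or b.module == module)
        ]


@dataclass
class SessionBundle:
    """Everything the analyses need about one synthetic recording."""

    session: RecordingSession
    module_map: ModuleMap
    epochs: list[ModulationEpoch]
    ground_truth: SimGroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Burst-event generation
# ---------------------------------------------------------------------------


def _intrinsic_onsets(rate_per_min: float, duration: float, rng) -> np.ndarray:
    n = rng.poisson(rate_per_min / 60.0 * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_module_bursts(
    spec: ModuleSpec, duration: float, rng: np.random.Generator
) -> list[BurstEvent]:
    """Intrinsic population-burst onsets for one module.

    Onsets form a Poisson process at the module's intrinsic rate,
    ``burst_rate * (1 - driven_fraction)`` events/min.
    """
    rate = spec.burst_rate * (1.0 - spec.driven_fraction)
    return [
        BurstEvent(-1, spec.label, float(t))
        for t in _intrinsic_onsets(rate, duration, rng)
    ]


def couple_modules(
    source_bursts: list[BurstEvent],
    coupling: Coupling,
    rng: np.random.Generator,
    duration: float,
) -> list[BurstEvent]:
    """Triggered target bursts for one coupling (provenance recorded)."""
    out = []
    for b in source_bursts:
        if rng.random() < coupling.probability:
            delay = _positive_normal(coupling.delay_mean, coupling.delay_sd, rng)
            onset = b.onset + delay
            if onset < duration:
                out.append(
                    BurstEvent(-1, coupling.target, onset, b.burst_id, delay, depth=b.depth + 1)
                )
    return out


def _positive_normal(mean: float, sd: float, rng) -> float:
    for _ in range(100):
        d = rng.normal(mean, sd)
        if d > 0:
            return float(d)
    return mean  # pathological sd; fall back to the mean


def _epoch_factor(
    module: str, t: float, epochs, factors: dict[float, float]
) -> float:
    for ep in epochs:
        if ep.target_module == module and ep.stim_window[0] <= t < ep.stim_window[1]:
            return factors[ep.power_density]
    return 1.0


class _FactorLookup:
    """Vectorized time -> suppression factor per module."""

    def __init__(self, epochs, factors: dict[float, float]):
        self._by_module: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list] = {}
        for ep in epochs:
            grouped.setdefault(ep.target_module, []).append(ep)
        for mod, eps in grouped.items():
            eps = sorted(eps, key=lambda e: e.stim_window[0])
            self._by_module[mod] = (
                np.array([e.stim_window[0] for e in eps]),
                np.array([e.stim_window[1] for e in eps]),
                np.array([factors[e.power_density] for e in eps]),
            )

    def factors(self, module: str, times: np.ndarray) -> np.ndarray:
        if module not in self._by_module or times.size == 0:
            return np.ones(times.size)
        starts, ends, fac = self._by_module[module]
        idx = np.searchsorted(starts, times, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        inside = (idx >= 0) & (times < ends[idx_c])
        return np.where(inside, fac[idx_c], 1.0)

    def factor(self, module: str, t: float) -> float:
        return float(self.factors(module, np.array([t]))[0])


def _generate_burst_events(
    config: SimConfig,
    epochs: list[ModulationEpoch],
    rng: np.random.Generator,
) -> list[BurstEvent]:
    """Event-driven burst cascade with suppression and ablation applied.

    Bursts are processed in onset order; a surviving burst triggers its
    couplings, a suppressed burst does not (so suppression of a source
    module propagates to the bursts it would have driven).
    """
    import heapq

    by_source: dict[str, list[Coupling]] = {}
    for c in config.couplings:
        by_source.setdefault(c.source, []).append(c)

    lookup = _FactorLookup(epochs, config.suppression_factors)
    heap: list[tuple[float, int, BurstEvent]] = []
    counter = 0
    for m in config.modules:
        for b in simulate_module_bursts(m, config.duration, rng):
            heapq.heappush(heap, (b.onset, counter, b))
            counter += 1

    done: list[BurstEvent] = []
    next_id = 0
    while heap:
        _, _, b = heapq.heappop(heap)
        b.burst_id = next_id
        next_id += 1
        factor = lookup.factor(b.module, b.onset)
        if factor < 1.0 and rng.random() >= factor:
            b.suppressed = True
        done.append(b)
        if b.suppressed or b.depth >= _MAX_CHAIN_DEPTH:
            continue
        if config.ablation_time is not None and b.onset >= config.ablation_time:
            continue
        for c in by_source.get(b.module, []):
            for child in couple_modules([b], c, rng, config.duration):
                heapq.heappush(heap, (child.onset, counter, child))
                counter += 1
    return done


def apply_suppression(
    train: SpikeTrain,
    epochs: list[ModulationEpoch],
    factor_for: dict[float, float],
    module: str,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Thin a spike train inside suppression epochs targeting ``module``.

    Each spike inside an epoch window survives independently with the
    epoch's rate-scaling factor (per-spike thinning).
    """
    ts = train.timestamps
    keep = np.ones(ts.size, dtype=bool)
    for i, t in enumerate(ts):
        f = _epoch_factor(module, float(t), epochs, factor_for)
        if f < 1.0 and rng.random() >= f:
            keep[i] = False
    return SpikeTrain(train.electrode_id, ts[keep], train.t_start, train.t_stop)


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def generate_session(
    config: SimConfig,
    epochs: list[ModulationEpoch] | None = None,
) -> SessionBundle:
    """Generate a fully reproducible synthetic recording session.

    Identical ``config.seed`` (and epochs) give identical sessions.
    Returns the session, its module map, the applied suppression epochs
    and the ground truth (burst provenance, spike categories, realized
    driven fractions).
    """
    epochs = list(epochs or [])
    for ep in epochs:
        if ep.stim_window[1] > config.duration:
            raise ValidationError("protocol epoch extends past session duration")
    _check_epoch_disjoint(epochs)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    bursts = _generate_burst_events(config, epochs, rng)
    lookup = _FactorLookup(epochs, config.suppression_factors)

    spikes: dict[str, list[np.ndarray]] = {
        e: [] for m in config.modules for e in config.electrode_ids(m.label)
    }
    n_burst_spikes = 0
    for b in bursts:
        spec = config.module(b.module)
        for e in config.electrode_ids(b.module):
            if rng.random() >= spec.participation:
                continue
            n = 1 + rng.poisson(max(spec.spikes_per_burst - 1.0, 0.0))
            tt = b.onset + np.sort(rng.uniform(0.0, spec.burst_duration, size=n))
            tt = tt[tt < config.duration]
            # suppression thins firing at the time of each spike, so a
            # burst straddling an epoch boundary is cut, not spared
            fac = lookup.factors(b.module, tt)
            tt = tt[rng.random(tt.size) < fac]
            spikes[e].append(tt)
            n_burst_spikes += tt.size

    n_background = 0
    for m in config.modules:
        for e in config.electrode_ids(m.label):
            bg = _intrinsic_onsets(m.background_rate * 60.0, config.duration, rng)
            fac = lookup.factors(m.label, bg)
            bg = bg[rng.random(bg.size) < fac]
            spikes[e].append(bg)
            n_background += bg.size

    trains = {}
    for e, parts in spikes.items():
        ts = np.unique(np.concatenate(parts)) if parts else np.empty(0)
        trains[e] = SpikeTrain(e, ts, 0.0, config.duration)

    driven = {}
    for m in config.modules:
        mb = [b for b in bursts if b.module == m.label and not b.suppressed]
        driven[m.label] = (
            sum(not b.intrinsic for b in mb) / len(mb) if mb else math.nan
        )
    truth = SimGroundTruth(
        bursts=bursts,
        spike_categories={
            "background": int(n_background),
            "burst": int(n_burst_spikes),
            "evoked": 0,
        },
        driven_fraction_realized=driven,
        epoch_factors=[(ep, config.suppression_factors[ep.power_density]) for ep in epochs],
    )
    session = RecordingSession(trains, annotations={"seed": config.seed})
    return SessionBundle(session, config.module_map(), epochs, truth, config)


def _check_epoch_disjoint(epochs: list[ModulationEpoch]) -> None:
    by_mod: dict[str, list[tuple[float, float]]] = {}
    for ep in epochs:
        by_mod.setdefault(ep.target_module, []).append(ep.stim_window)
    for mod, wins in by_mod.items():
        wins = sorted(wins)
        for (a0, a1), (b0, _) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ValidationError(f"overlapping suppression epochs for {mod}")


def make_suppression_protocol(
    target: str,
    powers: list[float] | None = None,
    n_trials: int = 5,
    stim_duration: float = 60.0,
    start: float = 70.0,
    gap: float = 10.0,
) -> list[ModulationEpoch]:
    """Trial schedule: for each power density, ``n_trials`` epochs.

    Each trial slot holds a baseline window (stim duration, immediately
    before), the stimulation window and a recovery window, separated by
    ``gap`` seconds.  Trials at the same power share a trial index range.
    """
    powers = sorted(powers or DEFAULT_SUPPRESSION_FACTORS)
    slot = 3 * stim_duration + gap
    epochs = []
    t = start
    for power in powers:
        for trial in range(n_trials):
            on = t + stim_duration
            epochs.append(
                ModulationEpoch(
                    target_module=target,
                    power_density=power,
                    stim_window=(on, on + stim_duration),
                    trial_index=trial,
                )
            )
            t += slot
    return epochs


def protocol_duration(epochs: list[ModulationEpoch], tail: float = 10.0) -> float:
    return max(ep.recovery_window[1] for ep in epochs) + tail


# ---------------------------------------------------------------------------
# Canned configurations
# ---------------------------------------------------------------------------


def asymmetric_pair_config(
    seed: int = 0,
    duration: float = 600.0,
    driven_fraction_follower: float = 1.0,
    driven_fraction_driver: float = 0.6,
    follower_rate: float = 27.0,
    driver_rate: float = 30.0,
    n_electrodes: int = 4,
    with_control: bool = True,
    delay_mean: float = 0.03,
    delay_sd: float = 0.005,
) -> SimConfig:
    """Two bidirectionally coupled modules with asymmetric dependence.

    ``N1`` (the follower) has no intrinsic bursts when
    ``driven_fraction_follower = 1``: all its activity is driven by
    ``N2``.  ``N2`` (the driver) generates intrinsic bursts and is
    additionally driven by echo bursts from ``N1`` so that its driven
    fraction matches ``driven_fraction_driver`` in expectation.  Coupling
    probabilities are solved from the stationary burst-rate balance
    ``p(src->tgt) = driven_fraction(tgt) * rate(tgt) / rate(src)``.
    """
    p_drive = driven_fraction_follower * follower_rate / driver_rate
    p_echo = driven_fraction_driver * driver_rate / follower_rate
    if not (0 <= p_drive <= 1 and 0 <= p_echo <= 1):
        raise ValidationError("requested driven fractions need probability > 1")
    modules = [
        ModuleSpec("N1", n_electrodes, burst_rate=follower_rate,
                   driven_fraction=driven_fraction_follower),
        ModuleSpec("N2", n_electrodes, burst_rate=driver_rate,
                   driven_fraction=driven_fraction_driver),
    ]
    couplings = [
        Coupling("N2", "N1", p_drive, delay_mean, delay_sd),
        Coupling("N1", "N2", p_echo, delay_mean, delay_sd),
    ]
    if with_control:
        modules.append(ModuleSpec(CONTROL_LABEL, n_electrodes, burst_rate=30.0))
    return SimConfig(modules, couplings, duration, seed)


def coupled_pair_config(
    probability: float,
    seed: int = 0,
    duration: float = 600.0,
    n_electrodes: int = 4,
    ablation_time: float | None = None,
    delay_mean: float = 0.03,
    delay_sd: float = 0.005,
) -> SimConfig:
    """Two intrinsically bursting modules with a one-way ``N2 -> N1`` drive.

    Both modules keep their own 12 events/min intrinsic bursting; each
    ``N2`` burst additionally triggers an ``N1`` burst with the given
    probability.  With ``ablation_time`` set, the coupling is severed
    from that time on (the structural-disconnection scenario); with
    ``probability = 0`` this is the uncoupled null model.
    """
    modules = [
        ModuleSpec("N1", n_electrodes, burst_rate=12.0),
        ModuleSpec("N2", n_electrodes, burst_rate=12.0),
    ]
    couplings = (
        [Coupling("N2", "N1", probability, delay_mean, delay_sd)]
        if probability > 0
        else []
    )
    return SimConfig(modules, couplings, duration, seed, ablation_time=ablation_time)


def uncoupled_pair_config(
    seed: int = 0, duration: float = 600.0, n_electrodes: int = 4
) -> SimConfig:
    """Two independent bursting modules (no coupling): the null model."""
    return coupled_pair_config(0.0, seed, duration, n_electrodes)


# ---------------------------------------------------------------------------
# Raw traces and evoked responses
# ---------------------------------------------------------------------------


def spike_waveform(sampling_rate: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic 1 ms spike template, negative phase leading.

    Returns ``(template, trough_index)``: a 0.4 ms negative half-sine of
    depth ``-amplitude`` followed by a 0.6 ms positive half-sine of 30 %
    of the amplitude.  The spike time refers to the trough sample.
    """
    n_neg = max(int(round(0.0004 * sampling_rate)), 2)
    n_pos = max(int(round(0.0006 * sampling_rate)), 2)
    neg = -amplitude * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = 0.3 * amplitude * np.sin(np.pi * np.arange(n_pos) / n_pos)
    template = np.concatenate([neg, pos])
    return template, int(np.argmin(template))


def render_noise_traces(
    trains: dict[str, SpikeTrain],
    sampling_rate: float = 25000.0,
    noise_sd: float = 10.0,
    amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[TraceBlock, dict[str, np.ndarray]]:
    """Render spike trains into noisy voltage traces.

    Gaussian noise of SD ``noise_sd`` microvolts plus the biphasic
    template inserted at each spike time (trough aligned to the spike
    timestamp; overlapping templates add).  Returns the trace block and
    the per-channel injected trough times (the detection ground truth).
    """
    if not trains:
        raise ValidationError("no spike trains to render")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    any_train = next(iter(trains.values()))
    n_samples = int(round(any_train.duration * sampling_rate))
    template, trough = spike_waveform(sampling_rate, amplitude)
    ids = sorted(trains)
    samples = np.empty((len(ids), n_samples))
    injected: dict[str, np.ndarray] = {}
    for i, eid in enumerate(ids):
        x = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else np.zeros(n_samples)
        times = []
        for t in trains[eid].timestamps:
            start = int(round((t - trains[eid].t_start) * sampling_rate)) - trough
            if start < 0 or start + template.size > n_samples:
                continue
            x[start : start + template.size] += template
            times.append((start + trough) / sampling_rate)
        samples[i] = x
        injected[eid] = np.asarray(times)
    return TraceBlock(samples, sampling_rate, ids), injected


def evoked_session(
    config: SimConfig,
    stim_times,
    responding_module: str,
    response_probability: float = 0.8,
    delay_mean: float = 0.02,
    delay_sd: float = 0.003,
    seed: int | None = None,
) -> SessionBundle:
    """Background activity plus stimulus-evoked spikes in one module.

    Per trial, the responding module fires with ``response_probability``;
    when it does, each of its electrodes emits one spike at the stimulus
    time plus a positive Gaussian delay (independent jitter per
    electrode).  Other modules carry only their background activity, so
    the evoked structure is the sole stimulus-locked signal.
    """
    stim = np.sort(np.asarray(list(stim_times), dtype=float))
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    spikes: dict[str, list[float]] = {
        e: [] for m in config.modules for e in config.electrode_ids(m.label)
    }
    n_background = 0
    for m in config.modules:
        for e in config.electrode_ids(m.label):
            bg = _intrinsic_onsets(m.background_rate * 60.0, config.duration, rng)
            spikes[e].extend(bg.tolist())
            n_background += bg.size
    evoked: dict[str, list[float]] = {}
    n_evoked = 0
    for t in stim:
        if rng.random() >= response_probability:
            continue
        for e in config.electrode_ids(responding_module):
            d = _positive_normal(delay_mean, delay_sd, rng)
            ts = float(t + d)
            if ts < config.duration:
                spikes[e].append(ts)
                evoked.setdefault(e, []).append(ts)
                n_evoked += 1
    trains = {
        e: SpikeTrain(e, np.unique(np.asarray(v)), 0.0, config.duration)
        for e, v in spikes.items()
    }
    truth = SimGroundTruth(
        bursts=[],
        spike_categories={"background": int(n_background), "burst": 0, "evoked": int(n_evoked)},
        driven_fraction_realized={},
        evoked_times=evoked,
    )
    return SessionBundle(
        RecordingSession(trains), config.module_map(), [], truth, config
    )
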