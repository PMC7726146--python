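"""Suppression-epoch rate changes and network-to-network influence.

The influence of module A on module B, written ``I[A -> B]``, is the
magnitude (percent) of B's baseline firing-rate change measured while A
is fully suppressed — operationally, at the highest power-density level
of A's suppression curve, subject to A itself reaching at least 90 %
suppression there.  Module rates pool spikes over member electrodes;
significance against control electrodes uses an exact two-sided
Mann-Whitney test (exhaustive enumeration for small samples, mid-rank
ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ModuleMap, RecordingSession, ValidationError, _load_config

__all__ = [
    "ModulationEpoch",
    "RateChangeCurve",
    "InfluenceEntry",
    "read_protocol",
    "write_protocol",
    "rate_change",
    "suppression_curve",
    "influence",
    "influence_matrix",
    "mann_whitney_exact",
]

FULL_SUPPRESSION_PCT = -90.0


@dataclass(frozen=True)
class ModulationEpoch:
    """One suppression trial: baseline, stimulation and recovery windows.

    ``power_density`` (mW/mm^2) is carried as opaque metadata.  If the
    baseline/recovery windows are not given they default to a window of
    the stimulation's duration immediately before/after it.
    """

    target_module: str
    power_density: float
    stim_window: tuple[float, float]
    baseline_window: tuple[float, float] = None
    recovery_window: tuple[float, float] = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        on, off = self.stim_window
        if off <= on:
            raise ValidationError("stim window must have positive duration")
        dur = off - on
        if self.baseline_window is None:
            object.__setattr__(self, "baseline_window", (on - dur, on))
        if self.recovery_window is None:
            object.__setattr__(self, "recovery_window", (off, off + dur))
        b0, b1 = self.baseline_window
        r0, r1 = self.recovery_window
        if not (b0 < b1 <= on < off <= r0 < r1):
            raise ValidationError(
                "windows must be disjoint and ordered baseline < stim < recovery"
            )


@dataclass
class RateChangeCurve:
    """Per (observed module, power density): percent rate change over trials.

    ``trials`` has columns ``observed, power, trial, pct_change``; the
    ``summary`` frame aggregates mean, SD and n per (observed, power).
    """

    target_module: str
    trials: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        g = self.trials.dropna(subset=["pct_change"]).groupby(["observed", "power"])
        out = g["pct_change"].agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"count": "n_trials"})

    @property
    def powers(self) -> list[float]:
        return sorted(self.trials["power"].unique())

    def mean_change(self, observed: str, power: float) -> float:
        sel = self.trials[
            (self.trials["observed"] == observed) & (self.trials["power"] == power)
        ]["pct_change"].dropna()
        return float(sel.mean()) if len(sel) else math.nan

    def trial_changes(self, observed: str, power: float) -> np.ndarray:
        sel = self.trials[
            (self.trials["observed"] == observed) & (self.trials["power"] == power)
        ]["pct_change"].dropna()
        return sel.to_numpy()


@dataclass
class InfluenceEntry:
    """One ordered-pair entry of the influence matrix (percent)."""

    source: str
    target: str
    influence: float  # |target change| at source's max-suppression power
    source_suppression: float  # source's mean change at max power (percent)
    defined: bool
    max_power: float


def read_protocol(path: str | Path) -> list[ModulationEpoch]:
    """Read a suppression protocol (YAML/JSON list of epochs).

    Each record: ``{target, power_mw_mm2, on_s, off_s, trial}`` with
    optional ``baseline_s``/``recovery_s`` two-element windows.
    """
    raw = _load_config(Path(path))
    if isinstance(raw, dict):
        raw = raw.get("epochs", [])
    epochs = []
    for rec in raw or []:
        epochs.append(
            ModulationEpoch(
                target_module=str(rec["target"]),
                power_density=float(rec["power_mw_mm2"]),
                stim_window=(float(rec["on_s"]), float(rec["off_s"])),
                baseline_window=tuple(rec["baseline_s"]) if "baseline_s" in rec else None,
                recovery_window=tuple(rec["recovery_s"]) if "recovery_s" in rec else None,
                trial_index=int(rec.get("trial", 0)),
            )
        )
    return epochs


def write_protocol(epochs: list[ModulationEpoch], path: str | Path) -> Path:
    import yaml

    recs = [
        {
            "target": e.target_module,
            "power_mw_mm2": float(e.power_density),
            "on_s": float(e.stim_window[0]),
            "off_s": float(e.stim_window[1]),
            "baseline_s": [float(x) for x in e.baseline_window],
            "recovery_s": [float(x) for x in e.recovery_window],
            "trial": int(e.trial_index),
        }
        for e in epochs
    ]
    Path(path).write_text(yaml.safe_dump({"epochs": recs}), encoding="utf-8")
    return Path(path)


def _window_rate(session, electrodes, window) -> float:
    a, b = window
    total = 0
    for eid in electrodes:
        ts = session.trains[eid].timestamps
        total += int(np.searchsorted(ts, b) - np.searchsorted(ts, a))
    return total / (b - a)


def rate_change(
    session: RecordingSession,
    epoch: ModulationEpoch,
    mmap: ModuleMap,
    electrodes: list[str] | None = None,
    per_electrode: bool = False,
) -> dict:
    """Percent rate change during one epoch, per module (and electrode).

    Module rate pools spikes over member electrodes per window duration;
    percent change = 100 * (during - baseline) / baseline, NaN when the
    baseline rate is zero.  Recovery-window changes are reported alongside
    for reversibility checks.
    """
    b0, b1 = epoch.baseline_window
    r0, r1 = epoch.recovery_window
    if b0 < session.t_start or r1 > session.t_stop:
        raise ValidationError("epoch windows extend outside the recording")
    if electrodes is None:
        electrodes = [
            e for e in session.electrode_ids
            if mmap.module_of(e) is not None and e not in mmap.excluded
        ]
    groups: dict[str, list[str]] = {}
    for e in electrodes:
        groups.setdefault(mmap.module_of(e), []).append(e)
    out: dict = {"module": {}, "recovery": {}}
    if per_electrode:
        out["electrode"] = {}
    for module, members in groups.items():
        base = _window_rate(session, members, epoch.baseline_window)
        during = _window_rate(session, members, epoch.stim_window)
        recov = _window_rate(session, members, epoch.recovery_window)
        out["module"][module] = (
            100.0 * (during - base) / base if base > 0 else math.nan
        )
        out["recovery"][module] = (
            100.0 * (recov - base) / base if base > 0 else math.nan
        )
        if per_electrode:
            for e in members:
                eb = _window_rate(session, [e], epoch.baseline_window)
                ed = _window_rate(session, [e], epoch.stim_window)
                out["electrode"][e] = 100.0 * (ed - eb) / eb if eb > 0 else math.nan
    return out


def suppression_curve(
    session: RecordingSession,
    epochs: list[ModulationEpoch],
    mmap: ModuleMap,
    target_module: str | None = None,
) -> RateChangeCurve:
    """Build the rate-change-vs-power curve from a set of trials.

    All epochs must share one target module (pass ``target_module`` to
    filter a mixed protocol).  Every mapped module — including the
    control group — is an observed series in the result.
    """
    if target_module is not None:
        epochs = [e for e in epochs if e.target_module == target_module]
    if not epochs:
        raise ValidationError("no epochs for the requested target")
    targets = {e.target_module for e in epochs}
    if len(targets) != 1:
        raise ValidationError(f"epochs target multiple modules: {sorted(targets)}")
    rows = []
    for ep in epochs:
        rc = rate_change(session, ep, mmap)
        for module, pct in rc["module"].items():
            rows.append(
                {
                    "observed": module,
                    "power": ep.power_density,
                    "trial": ep.trial_index,
                    "pct_change": pct,
                }
            )
    return RateChangeCurve(next(iter(targets)), pd.DataFrame(rows))


def influence(
    curve: RateChangeCurve,
    target: str,
    full_suppression_pct: float = FULL_SUPPRESSION_PCT,
) -> InfluenceEntry:
    """Network-to-network influence of the curve's target module on ``target``.

    Defined as the magnitude of ``target``'s mean percent change at the
    source's maximum power level, provided the source itself reaches the
    full-suppression criterion (mean change <= ``full_suppression_pct``)
    there; otherwise the entry is undefined and reports the achieved
    suppression.
    """
    source = curve.target_module
    max_power = curve.powers[-1]
    src_change = curve.mean_change(source, max_power)
    tgt_change = curve.mean_change(target, max_power)
    defined = (not math.isnan(src_change)) and src_change <= full_suppression_pct
    return InfluenceEntry(
        source=source,
        target=target,
        influence=abs(tgt_change) if defined else math.nan,
        source_suppression=src_change,
        defined=defined,
        max_power=max_power,
    )


def influence_matrix(
    curves: dict[str, RateChangeCurve],
    modules: list[str] | None = None,
    full_suppression_pct: float = FULL_SUPPRESSION_PCT,
) -> dict[tuple[str, str], InfluenceEntry]:
    """All ordered-pair influences from per-source suppression curves."""
    if modules is None:
        modules = sorted(curves)
    out = {}
    for src, curve in curves.items():
        for tgt in modules:
            if tgt == src:
                continue
            out[(src, tgt)] = influence(curve, tgt, full_suppression_pct)
    return out


def mann_whitney_exact(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Mann-Whitney U p-value, exact for small samples.

    For ``max(n1, n2) <= exact_max_n`` the null distribution of U is
    enumerated exhaustively over all C(n1+n2, n1) group assignments of
    the mid-ranked pooled sample (ties handled by mid-ranks), and
    p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|).  Larger samples fall back
    to the normal approximation with tie correction.  Two identical
    samples give p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 3 or n2 < 3:
        raise ValidationError("need at least 3 observations per group")
    if max(n1, n2) > exact_max_n:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    center = n1 * n2 / 2.0
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    obs_dev = abs(u_obs - center)
    total = 0
    extreme = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum()) - offset
        total += 1
        if abs(u - center) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total
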