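"""Config-driven orchestration: connectivity, events, influence, PSTH.

Each stage produces a JSON-serializable report; :func:`run_full` composes
the stages and adds a run manifest (parameters, seed, version) so that an
identical config reproduces byte-identical reports.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import __version__
from .io_core import ModuleMap, RecordingSession, ValidationError
from . import events as ev
from . import modulation as mo
from . import rates as ra
from . import stimresp as sr

__all__ = [
    "DEFAULTS",
    "run_connectivity",
    "run_events",
    "run_influence",
    "run_psth",
    "run_full",
    "write_report",
]

#: Documented analysis defaults (seconds / Hz), the parameter ledger every
#: stage reads unless the config overrides it.
DEFAULTS = {
    "bin_width": 0.1,
    "kernel_bins": 5,
    "kernel_sigma": 1.25,
    "min_rate": 0.05,
    "isi_threshold": 0.2,
    "min_spikes": 3,
    "single_spike_rule": False,
    "tie_tolerance": 0.001,
    "psth_bin": 0.001,
    "psth_window": 0.05,
    "psth_blank": 0.002,
    "alpha": 0.01,
    "full_suppression_pct": -90.0,
}


def _params(overrides: dict | None) -> dict:
    p = dict(DEFAULTS)
    p.update(overrides or {})
    return p


def _clean(x):
    """Make a report JSON-serializable with NaN -> None."""
    if isinstance(x, dict):
        return {str(k): _clean(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_clean(v) for v in x]
    if isinstance(x, (np.floating, float)):
        xf = float(x)
        return None if math.isnan(xf) else xf
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _clean(x.tolist())
    return x


def run_connectivity(
    session: RecordingSession, mmap: ModuleMap, overrides: dict | None = None
) -> dict:
    """Correlation matrix plus intra-/inter-CC summary for one session."""
    p = _params(overrides)
    matrix = ra.session_matrix(
        session,
        bin_width=p["bin_width"],
        kernel_bins=p["kernel_bins"],
        sigma=p["kernel_sigma"],
        min_rate=p["min_rate"],
    )
    summary = ra.cc_summary(matrix, mmap)
    return _clean(
        {
            "electrodes": matrix.electrode_ids,
            "matrix": matrix.matrix,
            "intra_cc": summary.intra_per_module,
            "inter_cc": {"-".join(k): v for k, v in summary.inter_per_pair.items()},
            "intra_cc_overall": summary.intra_overall,
            "inter_cc_overall": summary.inter_overall,
            "control_cross_cc": summary.control_cross_mean,
            "control_intra_cc": summary.control_intra_mean,
        }
    )


def run_events(
    session: RecordingSession, mmap: ModuleMap, overrides: dict | None = None
) -> dict:
    """Burst/SBE/SE detection with association and propagation tallies."""
    p = _params(overrides)
    sbes, ses, assoc, labels = ev.detect_session_events(
        session,
        mmap,
        isi_threshold=p["isi_threshold"],
        min_spikes=p["min_spikes"],
        single_spike_rule=p["single_spike_rule"],
        tie_tolerance=p["tie_tolerance"],
    )
    by_module: dict[str, list[float]] = {}
    for e, frac in assoc.items():
        m = mmap.module_of(e)
        if m is not None and not mmap.is_control(e) and not math.isnan(frac):
            by_module.setdefault(m, []).append(frac)
    props = (
        {"->".join(k): v for k, v in ev.propagation_proportions(labels).items()}
        if any(not l.ambiguous and len(l.sequence) >= 2 for l in labels)
        else {}
    )
    return _clean(
        {
            "n_sbe": len(sbes),
            "n_se": len(ses),
            "se_windows": [[s.start, s.end] for s in ses],
            "association_per_electrode": assoc,
            "association_per_module": {m: float(np.mean(v)) for m, v in by_module.items()},
            "propagation_proportions": props,
            "n_ambiguous": sum(l.ambiguous for l in labels),
        }
    )


def run_influence(
    session: RecordingSession,
    mmap: ModuleMap,
    epochs: list[mo.ModulationEpoch],
    overrides: dict | None = None,
) -> dict:
    """Suppression curves, influence matrix, and control-group tests."""
    p = _params(overrides)
    targets = sorted({e.target_module for e in epochs})
    curves = {
        t: mo.suppression_curve(session, epochs, mmap, target_module=t)
        for t in targets
    }
    infl = mo.influence_matrix(
        curves, modules=mmap.modules, full_suppression_pct=p["full_suppression_pct"]
    )
    report: dict = {"curves": {}, "influence": {}, "tests": {}}
    for t, curve in curves.items():
        report["curves"][t] = curve.summary.to_dict(orient="records")
        ctrl_label = mmap.control_label
        max_p = curve.powers[-1]
        for observed in curve.trials["observed"].unique():
            if observed in (t, ctrl_label):
                continue
            a = curve.trial_changes(observed, max_p)
            b = curve.trial_changes(ctrl_label, max_p)
            if a.size >= 3 and b.size >= 3:
                report["tests"][f"{t}:{observed}_vs_ctrl"] = mo.mann_whitney_exact(a, b)
    for (src, tgt), entry in infl.items():
        report["influence"][f"{src}->{tgt}"] = {
            "influence_pct": entry.influence,
            "source_suppression_pct": entry.source_suppression,
            "defined": entry.defined,
            "max_power": entry.max_power,
        }
    return _clean(report)


def run_psth(
    session: RecordingSession,
    stim: sr.StimTrialSet,
    mmap: ModuleMap,
    overrides: dict | None = None,
) -> dict:
    """PSTHs and response probabilities per recording electrode/module.

    The stimulated electrode is excluded from recording-side summaries.
    """
    p = _params(overrides)
    report: dict = {"per_electrode": {}, "per_module": {}}
    by_module: dict[str, list[sr.PSTH]] = {}
    for eid in session.electrode_ids:
        if eid == stim.stim_electrode or eid in mmap.excluded:
            continue
        psth = sr.build_psth(
            session.trains[eid],
            stim.stim_times,
            bin_width=p["psth_bin"],
            window=p["psth_window"],
            blank=p["psth_blank"],
        )
        prob = sr.response_probability(session.trains[eid], stim.stim_times)
        report["per_electrode"][eid] = {
            "counts": psth.counts,
            "response_probability": prob,
        }
        m = mmap.module_of(eid)
        if m is not None:
            by_module.setdefault(m, []).append(psth)
    for m, ps in by_module.items():
        mean = sr.mean_psth(ps)
        report["per_module"][m] = {
            "mean_counts": mean.counts,
            **sr.early_late_split(mean),
        }
    return _clean(report)


def run_full(
    session: RecordingSession,
    mmap: ModuleMap,
    epochs: list[mo.ModulationEpoch] | None = None,
    stim: sr.StimTrialSet | None = None,
    overrides: dict | None = None,
    seed: int | None = None,
) -> dict:
    """All stages on one session; stage failures are isolated.

    Stages without inputs (no protocol, no stimulation log) are skipped
    with a warning entry rather than aborting the run.
    """
    p = _params(overrides)
    report: dict = {
        "manifest": {
            "version": __version__,
            "seed": seed,
            "parameters": p,
            "n_electrodes": len(session.trains),
            "duration_s": session.duration,
        },
        "stages": {},
        "warnings": [],
    }
    stages = [("connectivity", lambda: run_connectivity(session, mmap, overrides)),
              ("events", lambda: run_events(session, mmap, overrides))]
    if epochs:
        stages.append(("influence", lambda: run_influence(session, mmap, epochs, overrides)))
    else:
        report["warnings"].append("influence stage skipped: no protocol epochs")
    if stim is not None:
        stages.append(("psth", lambda: run_psth(session, stim, mmap, overrides)))
    else:
        report["warnings"].append("psth stage skipped: no stimulation log")
    for name, fn in stages:
        try:
            report["stages"][name] = fn()
        except (ValidationError, ValueError) as exc:  # isolate stage failures
            report["stages"][name] = {"error": str(exc)}
            report["warnings"].append(f"{name} stage failed: {exc}")
    return report


def write_report(report: dict, path: str | Path) -> Path:
    """Write a report as deterministic JSON (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(report, sort_keys=True, indent=1, allow_nan=False) + "\n",
        encoding="utf-8",
    )
    return path
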