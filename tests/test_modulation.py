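import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modnet.io_core import ModuleMap, ValidationError
from modnet.modulation import (
    ModulationEpoch,
    RateChangeCurve,
    influence,
    mann_whitney_exact,
    rate_change,
    read_protocol,
    suppression_curve,
    write_protocol,
)

from conftest import make_session


def _epoch(on=30.0, off=40.0, power=243.0, target="N1", trial=0):
    return ModulationEpoch(target, power, (on, off), trial_index=trial)


@pytest.fixture
def simple_map():
    return ModuleMap({"a1": "N1", "a2": "N1", "b1": "N2", "c1": "CTRL"})


def periodic(rate_hz, start, stop):
    """Evenly spaced spikes at an exact rate over [start, stop)."""
    n = int(round(rate_hz * (stop - start)))
    return (start + (np.arange(n) + 0.5) * (stop - start) / n) if n else []


class TestEpochWindows:
    def test_default_baseline_and_recovery_flank_the_stim(self):
        ep = _epoch(30.0, 40.0)
        assert ep.baseline_window == (20.0, 30.0)
        assert ep.recovery_window == (40.0, 50.0)

    def test_misordered_windows_rejected(self):
        with pytest.raises(ValidationError):
            ModulationEpoch("N1", 30.0, (10.0, 20.0), baseline_window=(15.0, 25.0))

    def test_protocol_round_trip(self, tmp_path):
        epochs = [_epoch(30, 40, 30.0, "N1", 0), _epoch(80, 90, 243.0, "N1", 1)]
        p = write_protocol(epochs, tmp_path / "prot.yaml")
        assert read_protocol(p) == epochs


class TestRateChange:
    def test_equal_rates_give_zero_change(self, simple_map):
        spikes = {
            "a1": periodic(10, 20, 50),
            "a2": [],
            "b1": periodic(5, 20, 50),
            "c1": periodic(2, 20, 50),
        }
        rc = rate_change(make_session(spikes, 60.0), _epoch(), simple_map)
        assert rc["module"]["N1"] == pytest.approx(0.0)
        assert rc["module"]["N2"] == pytest.approx(0.0)

    def test_silenced_module_reads_minus_100(self, simple_map):
        spikes = {
            "a1": periodic(10, 20, 30),  # baseline only, silent during stim
            "a2": [],
            "b1": periodic(5, 20, 50),
            "c1": [],
        }
        rc = rate_change(make_session(spikes, 60.0), _epoch(), simple_map)
        assert rc["module"]["N1"] == pytest.approx(-100.0)

    def test_zero_baseline_is_undefined(self, simple_map):
        spikes = {"a1": periodic(10, 30, 40), "a2": [], "b1": [0.5], "c1": []}
        rc = rate_change(make_session(spikes, 60.0), _epoch(), simple_map)
        assert math.isnan(rc["module"]["N1"])

    def test_matches_direct_window_counts(self, simple_map):
        rng = np.random.default_rng(0)
        for _ in range(30):
            spikes = {
                e: np.unique(rng.uniform(0, 60, size=rng.integers(5, 300)))
                for e in ("a1", "a2", "b1", "c1")
            }
            session = make_session(spikes, 60.0)
            ep = _epoch()
            rc = rate_change(session, ep, simple_map)
            for module, members in [("N1", ("a1", "a2")), ("N2", ("b1",))]:
                base = sum(
                    np.sum((spikes[e] >= 20) & (spikes[e] < 30)) for e in members
                ) / 10.0
                dur = sum(
                    np.sum((spikes[e] >= 30) & (spikes[e] < 40)) for e in members
                ) / 10.0
                expected = 100.0 * (dur - base) / base
                assert rc["module"][module] == pytest.approx(expected)

    def test_percent_change_is_scale_invariant(self, simple_map):
        spikes = {"a1": periodic(8, 20, 35), "a2": [], "b1": periodic(3, 20, 50), "c1": []}
        doubled = {
            e: np.sort(np.concatenate([np.asarray(v), np.asarray(v) + 1e-4]))
            for e, v in spikes.items() if len(v)
        }
        doubled.update({e: [] for e in spikes if not len(spikes[e])})
        rc1 = rate_change(make_session(spikes, 60.0), _epoch(), simple_map)
        rc2 = rate_change(make_session(doubled, 60.0), _epoch(), simple_map)
        assert rc1["module"]["N1"] == pytest.approx(rc2["module"]["N1"])

    def test_epoch_outside_recording_rejected(self, simple_map):
        with pytest.raises(ValidationError):
            rate_change(make_session({"a1": [1.0]}, 45.0), _epoch(), simple_map)


class TestSuppressionCurve:
    def test_identical_trials_have_zero_sd(self, simple_map):
        spikes = {"a1": [], "a2": [], "b1": [], "c1": []}
        epochs = []
        for trial in range(5):
            on = 30.0 + 40.0 * trial
            epochs.append(_epoch(on, on + 10.0, 243.0, "N1", trial))
            # 10 Hz baseline, 5 Hz during: -50 % every trial
            spikes["a1"] = np.concatenate(
                [spikes["a1"], periodic(10, on - 10, on), periodic(5, on, on + 10)]
            )
        spikes["a1"] = np.unique(spikes["a1"])
        curve = suppression_curve(make_session(spikes, 250.0), epochs, simple_map)
        row = curve.summary
        sel = row[(row["observed"] == "N1") & (row["power"] == 243.0)].iloc[0]
        assert sel["mean"] == pytest.approx(-50.0)
        assert sel["std"] == pytest.approx(0.0)
        assert sel["n_trials"] == 5

    def test_control_group_curve_stays_near_zero(self):
        from modnet import synth

        changes = []
        for seed in range(10):
            epochs = synth.make_suppression_protocol("N1", n_trials=3)
            cfg = synth.asymmetric_pair_config(
                seed=seed, duration=synth.protocol_duration(epochs)
            )
            bundle = synth.generate_session(cfg, epochs)
            curve = suppression_curve(bundle.session, epochs, bundle.module_map)
            changes.extend(curve.mean_change("CTRL", p) for p in curve.powers)
        assert abs(float(np.mean(changes))) < 10.0

    def test_mixed_targets_rejected_without_filter(self, simple_map):
        session = make_session({"a1": periodic(5, 0, 250), "a2": [], "b1": [], "c1": []}, 250.0)
        epochs = [_epoch(30, 40, 30.0, "N1"), _epoch(80, 90, 30.0, "N2")]
        with pytest.raises(ValidationError):
            suppression_curve(session, epochs, simple_map)
        curve = suppression_curve(session, epochs, simple_map, target_module="N1")
        assert curve.target_module == "N1"


class TestInfluence:
    def _curve(self, src_change, tgt_change, source="N1"):
        rows = []
        for power in (30.0, 243.0):
            for trial in range(5):
                rows.append({"observed": source, "power": power, "trial": trial,
                             "pct_change": src_change if power == 243.0 else -10.0})
                rows.append({"observed": "N2", "power": power, "trial": trial,
                             "pct_change": tgt_change if power == 243.0 else 0.0})
        return RateChangeCurve(source, pd.DataFrame(rows))

    def test_influence_is_magnitude_of_target_change(self):
        entry = influence(self._curve(-97.0, -62.0), "N2")
        assert entry.defined
        assert entry.influence == pytest.approx(62.0)

    def test_unchanged_target_gives_zero_influence(self):
        assert influence(self._curve(-95.0, 0.0), "N2").influence == 0.0

    def test_insufficient_source_suppression_is_undefined(self):
        entry = influence(self._curve(-70.0, -62.0), "N2")
        assert not entry.defined
        assert math.isnan(entry.influence)
        assert entry.source_suppression == pytest.approx(-70.0)


def brute_force_mw_p(x, y):
    """Independent enumeration: two-sided tail of the U distribution."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(x)
    center = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    devs = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        devs.append(abs(u - center))
    devs = np.asarray(devs)
    return float(np.mean(devs >= abs(u_obs - center) - 1e-12))


class TestMannWhitney:
    def test_complete_separation_n5_gives_2_over_252(self):
        p = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_exact([3, 3, 3], [3, 3, 3]) == pytest.approx(1.0)

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n1, n2 = rng.integers(3, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.uniform(-2, 2), size=n2)
            ours = mann_whitney_exact(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref))

    def test_agrees_with_enumeration_under_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n1, n2 = rng.integers(3, 7, size=2)
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            assert mann_whitney_exact(x, y) == pytest.approx(brute_force_mw_p(x, y))

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            mann_whitney_exact(rng.normal(size=5), rng.normal(size=5)) < 0.01
            for _ in range(1000)
        )
        assert rejections / 1000 <= 0.03

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([1, 2], [3, 4, 5])
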