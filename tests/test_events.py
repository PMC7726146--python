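import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modnet.events import (
    Burst,
    PropagationLabel,
    association_degree,
    classify_ses,
    detect_bursts,
    detect_sbes,
    propagation_direction,
    propagation_proportions,
)
from modnet.io_core import ModuleMap, ValidationError

from conftest import make_session, make_train


def brute_force_bursts(times, isi, min_spikes):
    """Exhaustive gap scan: split wherever consecutive gap exceeds isi."""
    runs, cur = [], []
    for t in times:
        if cur and t - cur[-1] > isi:
            runs.append(cur)
            cur = []
        cur.append(t)
    if cur:
        runs.append(cur)
    return [(r[0], r[-1], len(r)) for r in runs if len(r) >= min_spikes]


def brute_force_sbes(bursts):
    """O(n^2) closed-interval overlap graph + connected components."""
    n = len(bursts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = bursts[i], bursts[j]
        if a.start <= b.end and b.start <= a.end:
            parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(bursts[i])
    out = []
    for comp in comps.values():
        electrodes = {b.electrode_id for b in comp}
        if len(electrodes) >= 2:
            out.append(
                (min(b.start for b in comp), max(b.end for b in comp), frozenset(electrodes))
            )
    return sorted(out)


class TestDetectBursts:
    def test_two_bursts_split_by_long_gap(self):
        train = make_train([0.0, 0.1, 0.2, 1.0, 1.05, 1.1], 2.0)
        bursts = detect_bursts(train, 0.2, min_spikes=3)
        assert [(b.start, b.end) for b in bursts] == [(0.0, 0.2), (1.0, 1.1)]

    def test_single_spike_is_not_a_burst(self):
        assert detect_bursts(make_train([0.5], 1.0), 0.2, 2) == []

    def test_gap_equal_to_threshold_stays_in_burst(self):
        bursts = detect_bursts(make_train([0.0, 0.2, 0.4], 1.0), 0.2, 3)
        assert len(bursts) == 1
        assert bursts[0].spike_count == 3

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(0, 99), min_size=0, max_size=60),
        st.floats(0.05, 1.0),
        st.integers(2, 5),
    )
    def test_matches_exhaustive_gap_scan(self, times, isi, min_spikes):
        times = sorted(set(round(t, 4) for t in times))
        bursts = detect_bursts(make_train(times, 100.0), isi, min_spikes)
        expected = brute_force_bursts(times, isi, min_spikes)
        assert [(b.start, b.end, b.spike_count) for b in bursts] == expected


class TestDetectSBEs:
    def test_overlapping_pair_forms_one_event(self):
        sbes = detect_sbes(
            [Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.1, 0.3, 3)]
        )
        assert len(sbes) == 1
        assert sbes[0].window == (0.0, 0.3)
        assert sbes[0].electrodes == {"ch1", "ch2"}

    def test_disjoint_bursts_form_no_event(self):
        assert detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.5, 0.7, 3)]) == []

    def test_chain_merges_transitively(self):
        sbes = detect_sbes(
            [
                Burst("ch1", 0.0, 0.2, 3),
                Burst("ch2", 0.15, 0.35, 3),
                Burst("ch3", 0.3, 0.5, 3),
            ]
        )
        assert len(sbes) == 1
        assert sbes[0].window == (0.0, 0.5)
        assert sbes[0].electrodes == {"ch1", "ch2", "ch3"}

    def test_touching_endpoints_count_as_overlap(self):
        sbes = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.2, 0.4, 3)])
        assert len(sbes) == 1

    def test_matches_overlap_graph_components(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            bursts = []
            for _ in range(rng.integers(0, 30)):
                s = rng.uniform(0, 20)
                bursts.append(
                    Burst(f"ch{rng.integers(1, 6)}", s, s + rng.uniform(0.01, 1.0), 3)
                )
            got = sorted(
                (e.start, e.end, e.electrodes) for e in detect_sbes(bursts)
            )
            assert got == brute_force_sbes(bursts)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        bursts = [
            Burst(f"ch{i % 4}", s, s + 0.3, 3)
            for i, s in enumerate(rng.uniform(0, 10, size=20))
        ]
        a = detect_sbes(bursts)
        b = detect_sbes(list(reversed(bursts)))
        assert [(e.start, e.end, e.electrodes) for e in a] == [
            (e.start, e.end, e.electrodes) for e in b
        ]


class TestClassifySEs:
    def test_cross_module_sbe_is_se(self, two_module_map):
        sbes = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch3", 0.1, 0.3, 3)])
        ses = classify_ses(sbes, two_module_map)
        assert len(ses) == 1
        assert ses[0].modules == {"N1", "N2"}

    def test_single_module_sbe_is_not_se(self, two_module_map):
        sbes = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.1, 0.3, 3)])
        assert classify_ses(sbes, two_module_map) == []

    def test_single_spike_rule_promotes_and_adds_participant(self, two_module_map):
        session = make_session(
            {"ch1": [0.0, 0.1, 0.2], "ch2": [0.05, 0.15, 0.3], "ch3": [0.25], "ch4": [], "ch5": []},
            1.0,
        )
        sbes = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.05, 0.3, 3)])
        assert classify_ses(sbes, two_module_map) == []
        ses = classify_ses(sbes, two_module_map, session, single_spike_rule=True)
        assert len(ses) == 1
        assert ses[0].electrodes == {"ch1", "ch2", "ch3"}
        assert ses[0].modules == {"N1", "N2"}

    def test_control_electrodes_do_not_count_as_second_network(self, two_module_map):
        sbes = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch5", 0.1, 0.3, 3)])
        assert classify_ses(sbes, two_module_map) == []


class TestAssociationDegree:
    def _ses(self, windows):
        return [
            type(
                "E", (), {"start": a, "end": b, "electrodes": frozenset(), "kind": "SE"}
            )()
            for a, b in windows
        ]

    def test_partial_participation(self):
        spikes = [0.1, 0.2, 0.3, 0.4, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6]
        session = make_session({"ch1": spikes}, 2.0)
        assoc = association_degree(session, self._ses([(0.05, 0.45)]))
        assert assoc["ch1"] == pytest.approx(0.4)

    def test_no_ses_gives_zero(self):
        session = make_session({"ch1": [0.1, 0.2]}, 1.0)
        assert association_degree(session, [])["ch1"] == 0.0

    def test_full_containment_gives_one(self):
        session = make_session({"ch1": [0.1, 0.2]}, 1.0)
        assert association_degree(session, self._ses([(0.0, 0.5)]))["ch1"] == 1.0

    def test_matches_per_spike_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            spikes = np.unique(rng.uniform(0, 50, size=rng.integers(1, 150)))
            wins = []
            t = 0.0
            while t < 45 and len(wins) < 10:
                a = t + rng.uniform(0.1, 3)
                b = a + rng.uniform(0.1, 2)
                wins.append((a, b))
                t = b
            session = make_session({"ch1": spikes}, 50.0)
            got = association_degree(session, self._ses(wins))["ch1"]
            expected = sum(
                1 for s in spikes if any(a <= s <= b for a, b in wins)
            ) / len(spikes)
            assert got == pytest.approx(expected)

    def test_monotone_when_windows_enlarged(self):
        rng = np.random.default_rng(6)
        spikes = np.unique(rng.uniform(0, 50, size=100))
        session = make_session({"ch1": spikes}, 50.0)
        small = self._ses([(5, 6), (20, 22)])
        large = self._ses([(4, 8), (19, 25)])
        assert (
            association_degree(session, large)["ch1"]
            >= association_degree(session, small)["ch1"]
        )


class TestPropagation:
    def _session_three_modules(self):
        mmap = ModuleMap({"a1": "N1", "a2": "N1", "b1": "N2", "c1": "N3"})
        session = make_session(
            {"a1": [2.05, 2.10, 2.15], "a2": [2.06], "b1": [2.02, 2.07, 2.12], "c1": [2.00, 2.04, 2.09]},
            3.0,
        )
        return mmap, session

    def test_two_module_ordering(self, two_module_map):
        session = make_session(
            {"ch1": [1.00, 1.05, 1.1], "ch2": [], "ch3": [1.03, 1.08, 1.13], "ch4": [], "ch5": []},
            2.0,
        )
        sbes = detect_sbes([Burst("ch1", 1.0, 1.1, 3), Burst("ch3", 1.03, 1.13, 3)])
        (se,) = classify_ses(sbes, two_module_map)
        lab = propagation_direction(se, two_module_map, session)
        assert lab.sequence == ("N1", "N2")
        assert not lab.ambiguous

    def test_three_module_cascade_order(self):
        mmap, session = self._session_three_modules()
        bursts = [
            Burst("c1", 2.00, 2.09, 3),
            Burst("b1", 2.02, 2.12, 3),
            Burst("a1", 2.05, 2.15, 3),
        ]
        (se,) = classify_ses(detect_sbes(bursts), mmap)
        lab = propagation_direction(se, mmap, session)
        assert lab.sequence == ("N3", "N2", "N1")

    def test_tie_within_tolerance_is_ambiguous(self, two_module_map):
        session = make_session(
            {"ch1": [1.0, 1.05, 1.1], "ch2": [], "ch3": [1.0004, 1.05, 1.1], "ch4": [], "ch5": []},
            2.0,
        )
        sbes = detect_sbes([Burst("ch1", 1.0, 1.1, 3), Burst("ch3", 1.0004, 1.1, 3)])
        (se,) = classify_ses(sbes, two_module_map)
        lab = propagation_direction(se, two_module_map, session, tie_tolerance=0.001)
        assert lab.ambiguous

    def test_non_se_rejected(self):
        ev = detect_sbes([Burst("ch1", 0.0, 0.2, 3), Burst("ch2", 0.1, 0.3, 3)])[0]
        mmap = ModuleMap({"ch1": "N1", "ch2": "N1"})
        session = make_session({"ch1": [0.0, 0.1, 0.2], "ch2": [0.1, 0.2, 0.3]}, 1.0)
        with pytest.raises(ValidationError):
            propagation_direction(ev, mmap, session)

    def test_module_label_permutation_equivariance(self, two_module_map):
        session = make_session(
            {"ch1": [1.00, 1.05, 1.1], "ch2": [], "ch3": [1.03, 1.08, 1.13], "ch4": [], "ch5": []},
            2.0,
        )
        swapped = ModuleMap(
            {"ch1": "N2", "ch2": "N2", "ch3": "N1", "ch4": "N1", "ch5": "CTRL"}
        )
        sbes = detect_sbes([Burst("ch1", 1.0, 1.1, 3), Burst("ch3", 1.03, 1.13, 3)])
        (se1,) = classify_ses(sbes, two_module_map)
        (se2,) = classify_ses(sbes, swapped)
        lab1 = propagation_direction(se1, two_module_map, session)
        lab2 = propagation_direction(se2, swapped, session)
        relabel = {"N1": "N2", "N2": "N1"}
        assert tuple(relabel[m] for m in lab1.sequence) == lab2.sequence


class TestPropagationProportions:
    def test_direct_ratio(self):
        labels = [PropagationLabel(("A", "B"), ())] * 7 + [
            PropagationLabel(("B", "A"), ())
        ] * 3
        props = propagation_proportions(labels)
        assert props[("A", "B")] == pytest.approx(0.7)
        assert props[("B", "A")] == pytest.approx(0.3)

    def test_single_direction_is_unity(self):
        props = propagation_proportions([PropagationLabel(("A", "B"), ())] * 5)
        assert props == {("A", "B"): 1.0}

    def test_ambiguous_labels_excluded(self):
        labels = [
            PropagationLabel(("A", "B"), ()),
            PropagationLabel(("B", "A"), (), ambiguous=True),
        ]
        assert propagation_proportions(labels) == {("A", "B"): 1.0}

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            propagation_proportions([])
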