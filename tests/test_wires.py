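import itertools

import numpy as np
import pytest

from sercatools.contacts import HBondCriteria
from sercatools.core import Atom, Frame, SercatoolsError, Topology, Trajectory
from sercatools.selection import select
from sercatools.synth import WireScheduleSpec, make_wire_system
from sercatools.wires import (
    WireConfig,
    detect_events,
    hbond_graph,
    lifetime_stats,
    water_oxygen_indices,
    wire_present,
    WireEvent,
)


def wire_config(top, **kw):
    defaults = dict(
        source_sel=select(top, "resid 309 and name OE1 OE2"),
        sink_sel=select(top, "resid 101 and name ND2 OD1"),
    )
    defaults.update(kw)
    return WireConfig(**defaults)


def random_water_topology(n_waters):
    atoms = [
        Atom(1, "OE1", "O", "GLU", 309, "A", "protein"),
        Atom(2, "OE2", "O", "GLU", 309, "A", "protein"),
        Atom(3, "ND2", "N", "ASN", 101, "A", "protein"),
        Atom(4, "OD1", "O", "ASN", 101, "A", "protein"),
    ]
    for j in range(n_waters):
        atoms.append(Atom(5 + j, "O", "O", "HOH", 1001 + j, "W", "water"))
    return Topology(tuple(atoms))


def brute_force_wire(frame, top, config):
    """Enumerate all simple source->waters->sink paths up to the bound."""
    d_max = config.hbond_criteria.d_max
    waters = list(water_oxygen_indices(top))
    sources = list(config.source_sel.indices)
    sinks = list(config.sink_sel.indices)

    def near(i, j):
        return np.linalg.norm(frame.coords[i] - frame.coords[j]) <= d_max

    for s, t in itertools.product(sources, sinks):
        if near(s, t):
            return True
    for k in range(1, config.max_bridging_waters + 1):
        for combo in itertools.permutations(waters, k):
            for s, t in itertools.product(sources, sinks):
                chain = [s, *combo, t]
                if all(near(a, b) for a, b in zip(chain, chain[1:])):
                    return True
    return False


class TestHBondGraph:
    def test_chain_is_a_path_graph(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=((0, 0),), n_frames=1,
                             n_waters_bulk=0, seed=0))
        top = traj.topology
        g = hbond_graph(traj.frames[0], top, water_oxygen_indices(top),
                        [select(top, "name OE1"), select(top, "name ND2")])
        # source O, 3 chain waters, sink N: 5 nodes in a path = 4 edges
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 4
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1, 1, 2, 2, 2]

    def test_decoys_are_isolated(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=(), n_frames=1,
                             n_waters_bulk=6, seed=1))
        top = traj.topology
        g = hbond_graph(traj.frames[0], top, water_oxygen_indices(top),
                        [select(top, "resid 309 and name OE1 OE2")])
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        assert len(isolated) >= 6

    def test_edges_match_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        top = random_water_topology(12)
        crit = HBondCriteria()
        for _ in range(20):
            coords = rng.uniform(0, 1.2, size=(top.n_atoms, 3))
            fr = Frame(coords=coords)
            widx = water_oxygen_indices(top)
            g = hbond_graph(fr, top, widx,
                            [select(top, "resid 309 and name OE1 OE2"),
                             select(top, "resid 101 and name ND2 OD1")], crit)
            nodes = sorted(g.nodes)
            for a, b in itertools.combinations(nodes, 2):
                want = np.linalg.norm(coords[a] - coords[b]) <= crit.d_max
                assert g.has_edge(a, b) == want


class TestWirePresent:
    def test_on_window_has_three_water_path(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=((3, 5),), n_frames=8, seed=2))
        top = traj.topology
        cfg = wire_config(top)
        path = wire_present(traj.frames[4], top, cfg)
        assert path is not None and len(path) == 3

    def test_off_window_absent(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=((3, 5),), n_frames=8, seed=2))
        top = traj.topology
        cfg = wire_config(top)
        assert wire_present(traj.frames[0], top, cfg) is None

    def test_max_bridging_waters_bound(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=((0, 0),), n_frames=1,
                             n_chain_waters=5, seed=3))
        top = traj.topology
        assert wire_present(traj.frames[0], top,
                            wire_config(top, max_bridging_waters=4)) is None
        path = wire_present(traj.frames[0], top,
                            wire_config(top, max_bridging_waters=5))
        assert path is not None and len(path) == 5

    def test_bulk_boundary_plane_mode(self):
        traj, _ = make_wire_system(
            WireScheduleSpec(on_windows=((0, 0),), n_frames=1, seed=4))
        top = traj.topology
        # waters climb to z = 0.84 nm; a boundary below that is reachable,
        # one above is not
        reach = wire_config(top, sink_sel=None, bulk_z=0.8)
        no_reach = wire_config(top, sink_sel=None, bulk_z=2.0,
                               pore_radius=None)
        assert wire_present(traj.frames[0], top, reach) is not None
        assert wire_present(traj.frames[0], top, no_reach) is None

    def test_matches_simple_path_enumeration(self):
        rng = np.random.default_rng(11)
        top = random_water_topology(10)
        cfg = wire_config(top, pore_radius=None)
        disagreements = 0
        for _ in range(200):
            coords = rng.uniform(0, 1.0, size=(top.n_atoms, 3))
            fr = Frame(coords=coords)
            got = wire_present(fr, top, cfg) is not None
            want = brute_force_wire(fr, top, cfg)
            disagreements += got != want
        assert disagreements == 0


def schedule_traj(windows, n_frames=20, **kw):
    traj, truth = make_wire_system(
        WireScheduleSpec(on_windows=tuple(windows), n_frames=n_frames,
                         frame_interval=20.0, seed=5, **kw))
    return traj, truth


class TestDetectEvents:
    def test_single_window_single_event(self):
        traj, _ = schedule_traj([(4, 9)])
        events = detect_events(traj, wire_config(traj.topology))
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame, ev.lifetime) == (4, 9, 120.0)
        assert ev.example_path == [1001, 1002, 1003]

    def test_gap_merge_semantics(self):
        traj, _ = schedule_traj([(2, 4), (6, 8)])
        top = traj.topology
        merged = detect_events(traj, wire_config(top, gap_merge_frames=1))
        assert len(merged) == 1
        assert (merged[0].start_frame, merged[0].end_frame) == (2, 8)
        assert merged[0].lifetime == 140.0
        split = detect_events(traj, wire_config(top, gap_merge_frames=0))
        assert [e.lifetime for e in split] == [60.0, 60.0]

    def test_empty_schedule_no_events(self):
        traj, _ = schedule_traj([])
        assert detect_events(traj, wire_config(traj.topology)) == []

    def test_event_spans_sum_to_present_frames(self):
        traj, truth = schedule_traj([(1, 3), (7, 7), (12, 17)], n_frames=20)
        events = detect_events(traj, wire_config(traj.topology))
        total = sum(e.n_frames for e in events)
        want = sum(e - s + 1 for s, e in truth.windows)
        assert total == want

    def test_invariant_under_water_relabeling(self):
        traj, _ = schedule_traj([(2, 6)])
        top = traj.topology
        base = detect_events(traj, wire_config(top))
        # swap the two chain waters' coordinates in every frame: the wire
        # call must not depend on which water sits where
        frames = []
        for fr in traj.frames:
            c = fr.coords.copy()
            c[[4, 5]] = c[[5, 4]]
            frames.append(Frame(coords=c, time=fr.time))
        traj2 = Trajectory(top, frames, frame_interval=traj.frame_interval)
        swapped = detect_events(traj2, wire_config(top))
        assert [(e.start_frame, e.end_frame) for e in base] == \
               [(e.start_frame, e.end_frame) for e in swapped]

    def test_monotone_in_distance_cutoff_and_water_bound(self):
        rng = np.random.default_rng(13)
        top = random_water_topology(8)
        frames = [Frame(coords=rng.uniform(0, 0.9, (top.n_atoms, 3)),
                        time=0.02 * i) for i in range(50)]
        traj = Trajectory(top, frames, frame_interval=20.0)
        loose = HBondCriteria(d_max=0.45)
        for k, fr in enumerate(frames):
            tight_hit = wire_present(fr, top, wire_config(top, pore_radius=None)) is not None
            loose_hit = wire_present(
                fr, top, wire_config(top, hbond_criteria=loose,
                                     pore_radius=None)) is not None
            more_hit = wire_present(
                fr, top, wire_config(top, max_bridging_waters=6,
                                     pore_radius=None)) is not None
            if tight_hit:
                assert loose_hit and more_hit


class TestLifetimeStats:
    def test_summary_of_two_events(self):
        events = [WireEvent(0, 4, 100.0, [1]), WireEvent(10, 16, 140.0, [2])]
        st = lifetime_stats(events)
        assert (st.count, st.mean_lifetime) == (2, 120.0)
        assert (st.min_lifetime, st.max_lifetime) == (100.0, 140.0)

    def test_no_events_is_empty_not_error(self):
        st = lifetime_stats([])
        assert st.count == 0
        assert st.mean_lifetime is None

    def test_planted_lifetimes_recovered_in_range(self):
        rng = np.random.default_rng(17)
        windows, pos = [], 0
        for _ in range(5):
            pos += int(rng.integers(3, 8))
            n = int(rng.integers(5, 8))  # 5-7 frames -> 100-140 ps
            windows.append((pos, pos + n - 1))
            pos += n
        traj, truth = schedule_traj(windows, n_frames=pos + 5)
        events = detect_events(traj, wire_config(traj.topology))
        st = lifetime_stats(events)
        assert st.count == 5
        assert 100.0 <= st.min_lifetime <= st.max_lifetime <= 150.0
        assert st.mean_lifetime == pytest.approx(np.mean(truth.lifetimes_ps))
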