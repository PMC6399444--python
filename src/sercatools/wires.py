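"""Hydrogen-bonded water-wire detection between two protein sites.

A water wire is any configuration of hydrogen-bonded waters in a pore
connecting a source site (e.g. the carboxyl oxygens of a buried, protonated
glutamate) with a sink site (e.g. a carboxamide group at the cytosolic
mouth) or with bulk solvent past a boundary plane.  The wire call is a
binary per-frame observable — wire or no wire — irrespective of how many
hydrogen-bonded configurations exist or which water molecules participate.
Maximal runs of wire frames form events whose lifetimes are reported in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import (
    AtomSelection,
    SelectionError,
    SercatoolsError,
    Frame,
    Topology,
    Trajectory,
)
from .contacts import HBondCriteria, minimum_image_deltas

__all__ = [
    "WireConfig",
    "WireEvent",
    "WireStats",
    "water_oxygen_indices",
    "hbond_graph",
    "wire_present",
    "detect_events",
    "lifetime_stats",
]


@dataclass(frozen=True)
class WireConfig:
    """Parameters of one wire search.

    ``sink_sel`` names the acceptor-site atoms; alternatively ``bulk_z``
    declares a boundary plane (nm) past which any connected water counts
    as having reached bulk solvent.  ``pore_radius`` restricts candidate
    waters to a cylinder around the source→sink axis, emulating a narrow
    pathway between helices without requiring a geometric pore definition.
    """

    source_sel: AtomSelection
    sink_sel: AtomSelection | None = None
    bulk_z: float | None = None
    max_bridging_waters: int = 4
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    gap_merge_frames: int = 0
    pore_radius: float | None = 0.8  # nm; None disables the pre-filter

    def __post_init__(self):
        if self.max_bridging_waters < 1:
            raise SercatoolsError("max_bridging_waters must be >= 1")
        if self.gap_merge_frames < 0:
            raise SercatoolsError("gap_merge_frames must be >= 0")
        if (self.sink_sel is None) == (self.bulk_z is None):
            raise SercatoolsError("exactly one of sink_sel or bulk_z is required")
        if len(self.source_sel) == 0:
            raise SelectionError("source selection is empty")
        if self.sink_sel is not None and len(self.sink_sel) == 0:
            raise SelectionError("sink selection is empty")


@dataclass
class WireEvent:
    """A maximal run of frames during which a wire is present."""

    start_frame: int
    end_frame: int          # inclusive
    lifetime: float         # ps = (end - start + 1) * frame_interval
    example_path: list[int]  # water residue ids of one representative frame

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class WireStats:
    count: int
    mean_lifetime: float | None  # ps
    min_lifetime: float | None
    max_lifetime: float | None


def water_oxygen_indices(topology: Topology) -> np.ndarray:
    """Indices of water oxygen atoms (category water, element O)."""
    return np.flatnonzero(
        (topology.categories == "water") & (topology.elements == "O")
    )


def _hbond_distance_edges(coords: np.ndarray, box, d_max: float) -> np.ndarray:
    """Boolean adjacency under the distance criterion (self-pairs excluded)."""
    d = coords[:, None, :] - coords[None, :, :]
    d = minimum_image_deltas(d, box)
    dist = np.sqrt((d ** 2).sum(axis=-1))
    adj = (dist <= d_max)
    np.fill_diagonal(adj, False)
    return adj


def hbond_graph(
    frame: Frame,
    topology: Topology,
    water_idx: np.ndarray,
    endpoint_sels: list[AtomSelection],
    criteria: HBondCriteria = HBondCriteria(),
) -> nx.Graph:
    """Undirected H-bond graph over water oxygens plus endpoint atoms.

    Nodes are atom indices; an edge joins two nodes whose heavy atoms are
    within the H-bond distance.  Topologies without hydrogens are the norm
    for this graph (a distance-only criterion); the per-node ``kind``
    attribute distinguishes ``water`` from ``endpoint``.
    """
    nodes = list(map(int, water_idx))
    kinds = {i: "water" for i in nodes}
    for sel in endpoint_sels:
        for i in sel:
            if i not in kinds:
                nodes.append(int(i))
            kinds[int(i)] = "endpoint"
    nodes = sorted(set(nodes))
    sub = frame.coords[nodes]
    adj = _hbond_distance_edges(sub, frame.box, criteria.d_max)
    g = nx.Graph()
    for i in nodes:
        g.add_node(i, kind=kinds[i])
    n = len(nodes)
    for a in range(n):
        for b in range(a + 1, n):
            if adj[a, b]:
                # endpoint-endpoint edges are kept: a direct source-sink
                # H-bond short-circuits the wire with zero bridging waters
                g.add_edge(nodes[a], nodes[b])
    return g


def _candidate_waters(
    frame: Frame,
    topology: Topology,
    config: WireConfig,
) -> np.ndarray:
    widx = water_oxygen_indices(topology)
    if config.pore_radius is None or len(widx) == 0:
        return widx
    src = frame.coords[config.source_sel.indices].mean(axis=0)
    if config.sink_sel is not None:
        snk = frame.coords[config.sink_sel.indices].mean(axis=0)
        axis = snk - src
    else:
        axis = np.array([0.0, 0.0, 1.0])
        if config.bulk_z is not None and config.bulk_z < src[2]:
            axis = -axis
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return widx
    u = axis / norm
    rel = frame.coords[widx] - src
    radial = rel - np.outer(rel @ u, u)
    keep = np.linalg.norm(radial, axis=1) <= config.pore_radius
    return widx[keep]


def wire_present(
    frame: Frame,
    topology: Topology,
    config: WireConfig,
) -> list[int] | None:
    """BFS search for a water-bridged path from source to sink.

    Returns the water atom indices of the first shortest path found under
    deterministic (ascending atom index) node ordering, or ``None`` when no
    path through at most ``max_bridging_waters`` waters exists.  A direct
    source–sink hydrogen bond counts as a (zero-water) connection.
    """
    widx = _candidate_waters(frame, topology, config)
    if config.sink_sel is not None:
        endpoint_sels = [config.source_sel, config.sink_sel]
        sink_nodes = set(map(int, config.sink_sel.indices))
    else:
        endpoint_sels = [config.source_sel]
        sink_nodes = set()
    g = hbond_graph(frame, topology, widx, endpoint_sels, config.hbond_criteria)
    if config.bulk_z is not None:
        # waters past the boundary plane are themselves sinks
        for i in widx:
            if frame.coords[i, 2] >= config.bulk_z:
                sink_nodes.add(int(i))
    sources = [int(i) for i in config.source_sel.indices if g.has_node(i)]
    # BFS over (node, waters_used); waters_used counts bridging waters on path
    from collections import deque

    best: list[int] | None = None
    seen: dict[int, int] = {}
    queue = deque()
    for s in sorted(sources):
        queue.append((s, 0, []))
        seen[s] = 0
    while queue:
        node, used, path = queue.popleft()
        for nb in sorted(g.neighbors(node)):
            kind = g.nodes[nb]["kind"]
            is_water = kind == "water"
            nused = used + (1 if is_water else 0)
            if is_water and nb in sink_nodes:
                # a bulk-boundary water terminates the path; it still counts
                # as one bridging water
                if nused <= config.max_bridging_waters:
                    return path + [nb]
                continue
            if nb in sink_nodes:
                return path
            if not is_water:
                continue  # other endpoint atoms are not intermediates
            if nused > config.max_bridging_waters:
                continue
            if nb in seen and seen[nb] <= nused:
                continue
            seen[nb] = nused
            queue.append((nb, nused, path + [nb]))
    return best


def detect_events(traj: Trajectory, config: WireConfig) -> list[WireEvent]:
    """Binarize the wire observable per frame and segment it into events.

    Maximal runs of wire frames form events; runs separated by at most
    ``gap_merge_frames`` wire-less frames are merged.  Lifetimes use the
    trajectory's declared frame interval (ps) and count frames inclusively.
    """
    if traj.frame_interval is None:
        raise SercatoolsError("detect_events needs a declared frame_interval")
    present: list[list[int] | None] = [
        wire_present(fr, traj.topology, config) for fr in traj.frames
    ]
    resids = traj.topology.resids
    runs: list[tuple[int, int]] = []
    start = None
    for k, p in enumerate(present):
        if p is not None and start is None:
            start = k
        elif p is None and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, traj.n_frames - 1))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= config.gap_merge_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        path = next(p for p in present[s:e + 1] if p is not None)
        events.append(
            WireEvent(
                start_frame=s,
                end_frame=e,
                lifetime=(e - s + 1) * traj.frame_interval,
                example_path=[int(resids[i]) for i in path],
            )
        )
    return events


def lifetime_stats(events: list[WireEvent]) -> WireStats:
    """Count / mean / min / max lifetime (ps) over detected events."""
    if not events:
        return WireStats(0, None, None, None)
    lt = np.array([e.lifetime for e in events], dtype=float)
    return WireStats(len(events), float(lt.mean()), float(lt.min()), float(lt.max()))
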