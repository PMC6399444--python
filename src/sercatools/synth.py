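"""Synthetic structures and trajectories with planted, known statistics.

Every generator is a pure function of its spec: the same seed gives
bit-identical output, and the planted quantities (state occupancies,
eigen-spectra and bases, wire on-windows) are returned as ground-truth
sidecar records so downstream tests recover parameters instead of
re-deriving them from the fixture.

The fixtures emulate the statistical structure of long all-atom
simulations of a lipid-bound membrane pump — bimodal inter-atomic distance
processes (e.g. peaks near 0.5 and 0.8 nm), contact events with planted
occupancies, a positional covariance with a few dominant non-Gaussian
modes, and intermittent three-water hydrogen-bonded chains with ~100–150 ps
lifetimes — without any force-field dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Atom, Frame, SercatoolsError, ShapeError, Topology, Trajectory

__all__ = [
    "DistanceProcessSpec",
    "DistanceProcessResult",
    "PlantedPCASpec",
    "PlantedPCATruth",
    "WireScheduleSpec",
    "WireTruth",
    "make_distance_process",
    "make_planted_pca_trajectory",
    "make_wire_system",
    "make_structure_fixture",
    "make_state_hopping_trajectory",
    "StateHopTruth",
    "make_demo_pair",
]


# --------------------------------------------------------------------------- #
# two-state (or k-state) distance processes
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DistanceProcessSpec:
    """Hidden-Markov distance process: Gaussian emission per state (nm).

    ``transition_rate`` is the per-frame probability that the chain
    resamples its state from ``stationary_weights`` (otherwise it stays),
    which makes the stationary law exactly the declared weights.  The
    default rate of 0.5 models frames saved at intervals comparable to the
    contact correlation time, so successive frames are nearly independent.
    """

    state_means: tuple[float, ...]
    state_sigmas: tuple[float, ...]
    stationary_weights: tuple[float, ...]
    transition_rate: float = 0.5
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self):
        k = len(self.state_means)
        if not (len(self.state_sigmas) == len(self.stationary_weights) == k):
            raise ShapeError("state_means/sigmas/weights lengths differ")
        if abs(sum(self.stationary_weights) - 1.0) > 1e-12:
            raise SercatoolsError("stationary_weights must sum to 1")
        if any(s < 0 for s in self.state_sigmas):
            raise SercatoolsError("state_sigmas must be >= 0")
        if not 0.0 <= self.transition_rate <= 1.0:
            raise SercatoolsError("transition_rate must be in [0, 1]")


@dataclass
class DistanceProcessResult:
    values: np.ndarray   # per-frame distance, nm
    states: np.ndarray   # per-frame hidden state index (ground truth)
    spec: DistanceProcessSpec


def make_distance_process(spec: DistanceProcessSpec) -> DistanceProcessResult:
    rng = np.random.default_rng(spec.seed)
    k = len(spec.state_means)
    w = np.asarray(spec.stationary_weights)
    states = np.empty(spec.n_frames, dtype=np.int64)
    s = int(rng.choice(k, p=w))
    for t in range(spec.n_frames):
        if t > 0 and rng.random() < spec.transition_rate:
            s = int(rng.choice(k, p=w))
        states[t] = s
    means = np.asarray(spec.state_means)[states]
    sigmas = np.asarray(spec.state_sigmas)[states]
    values = means + sigmas * rng.standard_normal(spec.n_frames)
    # distances are physical: clip the (rare) negative Gaussian excursions
    np.clip(values, 0.0, None, out=values)
    return DistanceProcessResult(values=values, states=states, spec=spec)


# --------------------------------------------------------------------------- #
# planted-covariance trajectories
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PlantedPCASpec:
    """Trajectory with a planted orthonormal mode basis and spectrum.

    Flagged ``nongaussian_components`` get a symmetric two-well amplitude
    distribution: equal-weight wells at ±offset with per-well sigma such
    that offset = 3·sigma and offset² + sigma² equals the planted
    eigenvalue, so the total planted variance is preserved while a
    one-Gaussian fit to the projection histogram fails (r² < 0.9).
    """

    n_atoms: int
    eigenvalues: tuple[float, ...]   # nm², strictly positive, descending
    nongaussian_components: frozenset[int] = frozenset()
    n_frames: int = 20_000
    seed: int = 0
    frame_interval: float = 20.0     # ps

    def __post_init__(self):
        ev = self.eigenvalues
        if any(e <= 0 for e in ev):
            raise SercatoolsError("eigenvalues must be strictly positive")
        if any(a < b for a, b in zip(ev, ev[1:])):
            raise SercatoolsError("eigenvalues must be descending")
        if len(ev) > 3 * self.n_atoms:
            raise ShapeError(
                f"{len(ev)} eigenvalues requested for {self.n_atoms} atoms "
                f"(max {3 * self.n_atoms})"
            )


@dataclass
class PlantedPCATruth:
    basis: np.ndarray        # (3*n_atoms, k) orthonormal planted modes
    eigenvalues: np.ndarray  # (k,) planted variances, nm²
    amplitudes: np.ndarray   # (n_frames, k) planted per-frame amplitudes
    mean_coords: np.ndarray  # (n_atoms, 3)


def _pseudo_ca_topology(n_atoms: int, resname: str = "ALA",
                        first_resid: int = 1, chain: str = "A") -> Topology:
    atoms = tuple(
        Atom(atom_id=i + 1, name="CA", element="C", resname=resname,
             resid=first_resid + i, chain=chain, category="protein")
        for i in range(n_atoms)
    )
    return Topology(atoms)


def _two_well_samples(rng, n, eigenvalue):
    sigma = np.sqrt(eigenvalue / 10.0)
    offset = 3.0 * sigma
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * offset + sigma * rng.standard_normal(n)


def make_planted_pca_trajectory(
    spec: PlantedPCASpec,
) -> tuple[Trajectory, PlantedPCATruth]:
    rng = np.random.default_rng(spec.seed)
    dim = 3 * spec.n_atoms
    k = len(spec.eigenvalues)
    mean = rng.uniform(0.0, 2.0, size=(spec.n_atoms, 3))
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    basis = q[:, :k]
    amps = np.empty((spec.n_frames, k))
    for j, lam in enumerate(spec.eigenvalues):
        if j in spec.nongaussian_components:
            amps[:, j] = _two_well_samples(rng, spec.n_frames, lam)
        else:
            amps[:, j] = np.sqrt(lam) * rng.standard_normal(spec.n_frames)
    flat = mean.reshape(-1) + amps @ basis.T
    dt_ns = spec.frame_interval * 1e-3
    frames = [
        Frame(coords=flat[t].reshape(spec.n_atoms, 3), time=t * dt_ns)
        for t in range(spec.n_frames)
    ]
    traj = Trajectory(_pseudo_ca_topology(spec.n_atoms), frames,
                      frame_interval=spec.frame_interval)
    truth = PlantedPCATruth(
        basis=basis,
        eigenvalues=np.asarray(spec.eigenvalues, dtype=float),
        amplitudes=amps,
        mean_coords=mean,
    )
    return traj, truth


# --------------------------------------------------------------------------- #
# scheduled water-wire systems
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class WireScheduleSpec:
    """Trajectory in which a 3-water H-bonded chain exists on a schedule.

    During each on-window the chain waters sit on the source→sink axis at
    0.28 nm successive O–O spacings (safely inside the 0.35 nm H-bond
    cutoff); outside the windows they are parked mutually >0.6 nm apart and
    >0.6 nm from both sites.  Decoy bulk waters never come within H-bond
    range of the chain, the sites, or each other.
    """

    on_windows: tuple[tuple[int, int], ...]  # inclusive frame ranges
    n_frames: int = 100
    n_waters_bulk: int = 10
    frame_interval: float = 20.0  # ps
    seed: int = 0
    n_chain_waters: int = 3

    def __post_init__(self):
        prev_end = -1
        for s, e in self.on_windows:
            if s > e:
                raise SercatoolsError(f"bad window ({s}, {e})")
            if s <= prev_end:
                raise SercatoolsError("on_windows must be non-overlapping and sorted")
            if e >= self.n_frames:
                raise SercatoolsError("window extends past trajectory length")
            prev_end = e


@dataclass
class WireTruth:
    windows: list[tuple[int, int]]
    lifetimes_ps: list[float]
    source_resid: int
    sink_resid: int
    chain_water_resids: list[int]


_WIRE_SPACING = 0.28  # nm, chain O–O distance


def _wire_topology(spec: WireScheduleSpec) -> Topology:
    atoms = []
    aid = 0

    def add(name, elem, resname, resid, chain, cat):
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, elem, resname, resid, chain, cat))

    add("OE1", "O", "GLU", 309, "A", "protein")
    add("OE2", "O", "GLU", 309, "A", "protein")
    add("ND2", "N", "ASN", 101, "A", "protein")
    add("OD1", "O", "ASN", 101, "A", "protein")
    for j in range(spec.n_chain_waters):
        add("O", "O", "HOH", 1001 + j, "W", "water")
    for j in range(spec.n_waters_bulk):
        add("O", "O", "HOH", 2001 + j, "W", "water")
    return Topology(tuple(atoms))


def _decoy_positions(n: int, z_top: float, rng) -> np.ndarray:
    """Bulk-water positions on rings far outside the pore cylinder."""
    out = np.empty((n, 3))
    per_ring = 12
    for j in range(n):
        ring, slot = divmod(j, per_ring)
        radius = 2.0 + 0.9 * ring
        theta = 2.0 * np.pi * slot / per_ring
        z = (0.1 + 0.9 * (slot / per_ring)) * z_top + 0.3 * ring
        jitter = rng.uniform(-0.05, 0.05, size=3)
        out[j] = [radius * np.cos(theta) + jitter[0],
                  radius * np.sin(theta) + jitter[1],
                  z + jitter[2]]
    return out


def make_wire_system(spec: WireScheduleSpec) -> tuple[Trajectory, WireTruth]:
    rng = np.random.default_rng(spec.seed)
    top = _wire_topology(spec)
    nw = spec.n_chain_waters
    z_sink = _WIRE_SPACING * (nw + 1)
    static = {
        0: (0.0, 0.0, 0.0),          # GLU OE1 (source)
        1: (0.22, 0.0, 0.0),         # GLU OE2
        2: (0.0, 0.0, z_sink),       # ASN ND2 (sink)
        3: (0.22, 0.0, z_sink),      # ASN OD1
    }
    chain_on = np.array(
        [[0.0, 0.0, _WIRE_SPACING * (j + 1)] for j in range(nw)]
    )
    # parked (off-window) chain-water positions: mutually >0.6 nm apart and
    # far from sites, decoys and the pore cylinder
    chain_off = np.array([[6.0 + 1.0 * j, 6.0, 0.5] for j in range(nw)])
    decoys = _decoy_positions(spec.n_waters_bulk, z_sink, rng)
    on_mask = np.zeros(spec.n_frames, dtype=bool)
    for s, e in spec.on_windows:
        on_mask[s:e + 1] = True
    frames = []
    dt_ns = spec.frame_interval * 1e-3
    for t in range(spec.n_frames):
        coords = np.empty((top.n_atoms, 3))
        for i, pos in static.items():
            coords[i] = pos
        coords[4:4 + nw] = chain_on if on_mask[t] else chain_off
        coords[4 + nw:] = decoys
        frames.append(Frame(coords=coords, time=t * dt_ns))
    traj = Trajectory(top, frames, frame_interval=spec.frame_interval)
    truth = WireTruth(
        windows=[tuple(w) for w in spec.on_windows],
        lifetimes_ps=[(e - s + 1) * spec.frame_interval
                      for s, e in spec.on_windows],
        source_resid=309,
        sink_resid=101,
        chain_water_resids=[1001 + j for j in range(nw)],
    )
    return traj, truth


# --------------------------------------------------------------------------- #
# structure fixtures and discrete-state (clustering) fixtures
# --------------------------------------------------------------------------- #

def make_structure_fixture(
    n_protein_residues: int = 10,
    n_lipids: int = 1,
    n_waters: int = 20,
    seed: int = 0,
) -> tuple[Topology, Frame]:
    """Small mixed-category structure: GLY residues + POPC headgroups + waters."""
    rng = np.random.default_rng(seed)
    atoms, xyz = [], []
    aid = 0

    def add(name, elem, resname, resid, chain, cat, pos):
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, elem, resname, resid, chain, cat))
        xyz.append(pos)

    for r in range(n_protein_residues):
        base = rng.uniform(0, 3, 3)
        for name, elem, off in (("N", "N", (0, 0, 0)), ("CA", "C", (0.15, 0, 0)),
                                ("C", "C", (0.25, 0.1, 0)), ("O", "O", (0.3, 0.2, 0))):
            add(name, elem, "GLY", r + 1, "A", "protein", base + np.asarray(off))
    for l in range(n_lipids):
        base = rng.uniform(0, 3, 3) + np.array([4.0, 0, 0])
        add("P", "P", "POPC", 1001 + l, "L", "lipid", base)
        add("N", "N", "POPC", 1001 + l, "L", "lipid", base + np.array([0.4, 0, 0]))
    for w in range(n_waters):
        add("O", "O", "HOH", 2001 + w, "W", "water",
            rng.uniform(0, 3, 3) + np.array([0, 4.0, 0]))
    # snap to the PDB printed precision (0.001 Å) so write->read is exact
    coords = np.round(np.asarray(xyz), 4)
    return Topology(tuple(atoms)), Frame(coords=coords)


@dataclass
class StateHopTruth:
    labels: np.ndarray       # per-frame planted state index
    populations: np.ndarray  # planted stationary populations
    offsets: np.ndarray      # (k, 3) rigid per-state displacements, nm


def make_state_hopping_trajectory(
    populations: tuple[float, ...],
    separation: float,
    n_atoms: int = 5,
    n_frames: int = 2000,
    noise: float = 0.0,
    seed: int = 0,
    frame_interval: float = 20.0,
) -> tuple[Trajectory, StateHopTruth]:
    """Frames hop i.i.d. between k rigidly displaced copies of one structure.

    State j displaces the whole structure by ``separation`` nm along its own
    orthogonal-ish axis, so every inter-state RMSD is at least ``separation``;
    optional isotropic ``noise`` (nm, sd per coordinate) is added on top.
    Emulates the discrete spatial orientations a mobile lipid headgroup
    adopts in a binding site, including a small minority state.
    """
    if abs(sum(populations) - 1.0) > 1e-12:
        raise SercatoolsError("populations must sum to 1")
    k = len(populations)
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1.0, size=(n_atoms, 3))
    dirs = np.zeros((k, 3))
    for j in range(1, k):
        axis = np.zeros(3)
        axis[(j - 1) % 3] = 1.0
        dirs[j] = axis * (1 + (j - 1) // 3)  # 1,1,1,2,2,2,... multiples
    offsets = dirs * separation
    labels = rng.choice(k, size=n_frames, p=np.asarray(populations))
    dt_ns = frame_interval * 1e-3
    frames = []
    for t in range(n_frames):
        coords = base + offsets[labels[t]]
        if noise > 0:
            coords = coords + noise * rng.standard_normal((n_atoms, 3))
        frames.append(Frame(coords=coords, time=t * dt_ns))
    traj = Trajectory(_pseudo_ca_topology(n_atoms, resname="SER",
                                          first_resid=501), frames,
                      frame_interval=frame_interval)
    return traj, StateHopTruth(
        labels=labels,
        populations=np.asarray(populations, dtype=float),
        offsets=offsets,
    )


# --------------------------------------------------------------------------- #
# paired demo systems for the pipeline
# --------------------------------------------------------------------------- #

def make_demo_pair(outdir, seed: int = 0, n_frames: int = 4000) -> dict:
    """Write a lipid-bound/lipid-free pair of synthetic systems + ground truth.

    Each system combines, in one topology, four independent planted blocks:

    * a probe pair (Gln-like NE2 vs. a POPC phosphorus) whose separation
      follows a planted distance process — bimodal (0.5/0.8 nm, weight 0.6
      on the contact state) for "bound", unimodal (0.3 nm) for "free";
    * a wire subsystem (Glu309-like source, Asn101-like sink, scheduled
      3-water chain) — 2 events for "bound", 3 for "free", lifetimes in
      the 100–150 ps range;
    * a planted-covariance block of 10 pseudo-Cα atoms (spectrum
      (4,2,1,0.5,0.25,...)·10⁻³ nm², components 1–2 two-well);
    * a 4-state hopping block for clustering (populations 0.45/0.30/0.18/0.07).

    Returns a manifest dict (also written as JSON) with file paths and the
    planted ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import io as sio

    rng = np.random.default_rng(seed)
    manifest: dict = {"systems": {}, "seed": seed, "n_frames": n_frames}
    dt = 20.0  # ps

    if n_frames < 200:
        raise SercatoolsError("demo pair needs at least 200 frames")
    # window starts scale with trajectory length; lengths 5-7 frames at
    # 20 ps/frame give the 100-150 ps lifetime range
    wire_windows = {
        "bound": ((n_frames // 8, n_frames // 8 + 5),
                  (n_frames // 2, n_frames // 2 + 6)),
        "free": ((n_frames // 10, n_frames // 10 + 4),
                 (2 * n_frames // 5, 2 * n_frames // 5 + 6),
                 (3 * n_frames // 4, 3 * n_frames // 4 + 5)),
    }
    dist_spec = {
        "bound": DistanceProcessSpec(
            state_means=(0.5, 0.8), state_sigmas=(0.03, 0.03),
            stationary_weights=(0.6, 0.4), transition_rate=0.5,
            n_frames=n_frames, seed=int(rng.integers(2**31 - 1))),
        "free": DistanceProcessSpec(
            state_means=(0.3, 0.8), state_sigmas=(0.03, 0.03),
            stationary_weights=(0.9, 0.1), transition_rate=0.5,
            n_frames=n_frames, seed=int(rng.integers(2**31 - 1))),
    }
    for label in ("bound", "free"):
        dist = make_distance_process(dist_spec[label])
        pca_spec = PlantedPCASpec(
            n_atoms=10,
            eigenvalues=tuple(4e-3 * 0.5 ** i for i in range(8)),
            nongaussian_components=frozenset({0, 1}),
            n_frames=n_frames,
            seed=int(rng.integers(2**31 - 1)),
        )
        pca_traj, pca_truth = make_planted_pca_trajectory(pca_spec)
        wire_spec = WireScheduleSpec(
            on_windows=wire_windows[label], n_frames=n_frames,
            n_waters_bulk=10, frame_interval=dt,
            seed=int(rng.integers(2**31 - 1)))
        wire_traj, wire_truth = make_wire_system(wire_spec)
        hop_traj, hop_truth = make_state_hopping_trajectory(
            populations=(0.45, 0.30, 0.18, 0.07), separation=0.3,
            n_atoms=4, n_frames=n_frames, noise=0.01,
            seed=int(rng.integers(2**31 - 1)))

        top, frames = _combine_blocks(dist, wire_traj, pca_traj, hop_traj, dt)
        traj = Trajectory(top, frames, frame_interval=dt)
        pdb = outdir / f"{label}.pdb"
        xyz = outdir / f"{label}.xyz"
        sio.write_structure(pdb, top, frames[0])
        sio.write_xyz_trajectory(xyz, traj)
        manifest["systems"][label] = {
            "structure": str(pdb),
            "trajectory": str(xyz),
            "frame_interval_ps": dt,
            "truth": {
                "contact_occupancy": float(np.mean(dist.states == 0)),
                # interval bracketing the contact state at +-5 emission sd
                "contact_recovery_interval": [
                    round(dist_spec[label].state_means[0] - 0.15, 6),
                    round(dist_spec[label].state_means[0] + 0.15, 6),
                ],
                "contact_state_means": list(dist_spec[label].state_means),
                "contact_weights": list(dist_spec[label].stationary_weights),
                "pca_eigenvalues": list(pca_truth.eigenvalues),
                "pca_nongaussian": sorted(pca_spec.nongaussian_components),
                "wire_windows": [list(w) for w in wire_truth.windows],
                "wire_lifetimes_ps": wire_truth.lifetimes_ps,
                "cluster_populations": hop_truth.populations.tolist(),
            },
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _combine_blocks(dist, wire_traj, pca_traj, hop_traj, dt):
    """Assemble the four planted blocks into one topology + frame list."""
    n_frames = len(dist.values)
    atoms: list[Atom] = []
    aid = 0

    def add(name, elem, resname, resid, chain, cat):
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, elem, resname, resid, chain, cat))

    # block 1: probe pair
    add("NE2", "N", "GLN", 108, "A", "protein")
    add("P", "P", "POPC", 1201, "L", "lipid")
    # block 2: wire subsystem (shifted +10 nm in x)
    wire_shift = np.array([10.0, 0.0, 0.0])
    for a in wire_traj.topology.atoms:
        add(a.name, a.element, a.resname, a.resid, a.chain, a.category)
    # block 3: planted-covariance block (shifted +20 nm), resids 401+
    pca_shift = np.array([20.0, 0.0, 0.0])
    for j, a in enumerate(pca_traj.topology.atoms):
        add("CA", "C", "ALA", 401 + j, "B", "protein")
    # block 4: state-hopping block (shifted +30 nm), resids 501+
    hop_shift = np.array([30.0, 0.0, 0.0])
    for a in hop_traj.topology.atoms:
        add(a.name, a.element, a.resname, a.resid, a.chain, a.category)
    top = Topology(tuple(atoms))
    nw = wire_traj.topology.n_atoms
    npca = pca_traj.topology.n_atoms
    nhop = hop_traj.topology.n_atoms
    frames = []
    for t in range(n_frames):
        coords = np.empty((top.n_atoms, 3))
        coords[0] = (0.0, 0.0, 0.0)
        coords[1] = (dist.values[t], 0.0, 0.0)
        coords[2:2 + nw] = wire_traj.frames[t].coords + wire_shift
        coords[2 + nw:2 + nw + npca] = pca_traj.frames[t].coords + pca_shift
        coords[2 + nw + npca:] = hop_traj.frames[t].coords + hop_shift
        frames.append(Frame(coords=coords, time=t * dt * 1e-3))
    return top, frames
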