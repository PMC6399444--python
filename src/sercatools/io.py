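"""Readers and writers for structures, trajectories and segment maps.

Formats
-------
* **PDB** (read/write): ATOM/HETATM/TER/END records, parsed and emitted
  through :mod:`MDAnalysis`, which preserves the four-character residue
  names (POPC, TIP3, ...) that simulation force fields use.  PDB
  coordinates are ångström; they are converted to nanometres on read and
  back on write.
* **XYZ-dialect trajectory** (read/write): plain text, per frame an atom
  count line, a comment line carrying the time (``frame <i> time_ps <t>``),
  then one ``name x y z`` line per atom with coordinates in nm.
* **DCD trajectory** (read/write): the CHARMM/NAMD binary dialect as
  written by mdtraj — little-endian, 32-bit floats, coordinates in
  ångström on disk (converted to nm in memory).
* **Segment map**: a YAML mapping from a segment label to a list of
  inclusive residue-id ranges, e.g. ``M2: [[89, 120]]``.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ANGSTROM_TO_NM,
    Atom,
    EmptyInputError,
    FormatError,
    Frame,
    ShapeError,
    Topology,
    Trajectory,
    categorize_residue,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_dcd_trajectory",
    "write_dcd_trajectory",
    "read_trajectory",
    "write_trajectory",
    "load_segment_map",
    "default_segment_map",
]


# --------------------------------------------------------------------------- #
# PDB structures
# --------------------------------------------------------------------------- #

def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields of ATOM/HETATM records; return their count.

    General-purpose PDB readers are forgiving about malformed records, so a
    light pre-scan gives format errors that actually name the offending line.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unparseable ATOM/HETATM record"
                )
            n += 1
    return n


def read_structure(path) -> tuple[Topology, Frame]:
    """Read a PDB file into a (Topology, Frame) pair, coordinates in nm.

    Categories are assigned from residue names (standard amino acids →
    protein, HOH/TIP3/... → water, K/CL/NA/... → ion, anything else →
    lipid).  Only the first model of a multi-model file is read.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _prescan_pdb(path) == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), topology_format="PDB", format="PDB")
        ag = u.atoms
        names = ag.names
        resnames = ag.resnames
        resids = ag.resids
        try:
            chains = ag.chainIDs
        except AttributeError:
            chains = np.array(["A"] * len(ag))
        try:
            elements = [e if e else _guess_element(n)
                        for e, n in zip(ag.elements, names)]
        except AttributeError:
            elements = [_guess_element(n) for n in names]
        coords = ag.positions.astype(float) * ANGSTROM_TO_NM
    atoms = tuple(
        Atom(
            atom_id=i + 1,
            name=str(names[i]),
            element=str(elements[i]),
            resname=str(resnames[i]),
            resid=int(resids[i]),
            chain=str(chains[i]) or "A",
            category=categorize_residue(str(resnames[i])),
        )
        for i in range(len(ag))
    )
    return Topology(atoms), Frame(coords=coords, time=0.0)


def _guess_element(name: str) -> str:
    for c in name:
        if c.isalpha():
            return c.upper()
    return "X"


def write_structure(path, topology: Topology, frame: Frame) -> None:
    """Write a (Topology, Frame) pair as a PDB file (coordinates in Å)."""
    import MDAnalysis as mda

    if frame.n_atoms != topology.n_atoms:
        raise ShapeError("frame atom count does not match topology")
    n = topology.n_atoms
    # group consecutive atoms with the same (chain, resid, resname)
    res_index = np.empty(n, dtype=int)
    res_keys: list[tuple] = []
    prev = None
    for i, a in enumerate(topology.atoms):
        key = (a.chain, a.resid, a.resname)
        if key != prev:
            res_keys.append(key)
            prev = key
        res_index[i] = len(res_keys) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=len(res_keys),
                               atom_resindex=res_index, trajectory=True)
        u.add_TopologyAttr("names", list(topology.names))
        u.add_TopologyAttr("elements", list(topology.elements))
        u.add_TopologyAttr("chainIDs", list(topology.chains))
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.atoms.positions = np.asarray(frame.coords, dtype=np.float32) / ANGSTROM_TO_NM
        u.atoms.write(str(path))


# --------------------------------------------------------------------------- #
# XYZ-dialect text trajectories
# --------------------------------------------------------------------------- #

def write_xyz_trajectory(path, traj: Trajectory) -> None:
    names = traj.topology.names
    with open(path, "w") as fh:
        for i, fr in enumerate(traj.frames):
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"frame {i} time_ps {fr.time * 1000.0:.6f}\n")
            for name, (x, y, z) in zip(names, fr.coords):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(path, topology: Topology,
                        frame_interval: float | None = None) -> Trajectory:
    """Read an XYZ-dialect text trajectory (nm) against a topology.

    The per-frame atom count must match the topology; a mismatch or a
    truncated frame raises :class:`ShapeError` naming the frame index.
    """
    frames: list[Frame] = []
    n_top = topology.n_atoms
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected atom count")
        if n != n_top:
            raise ShapeError(
                f"{path}: frame {frame_idx}: {n} atoms, topology has {n_top}"
            )
        if i + 1 >= len(lines):
            raise ShapeError(f"{path}: frame {frame_idx}: missing comment line")
        time_ps = _parse_time_ps(lines[i + 1], frame_idx, frame_interval)
        block = lines[i + 2: i + 2 + n]
        if len(block) < n or any(len(l.split()) < 4 for l in block):
            raise ShapeError(f"{path}: truncated frame {frame_idx}")
        coords = np.array(
            [[float(v) for v in l.split()[1:4]] for l in block], dtype=float
        )
        frames.append(Frame(coords=coords, time=time_ps * 1e-3))
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    return Trajectory(topology, frames, frame_interval=frame_interval)


def _parse_time_ps(comment: str, frame_idx: int,
                   frame_interval: float | None) -> float:
    toks = comment.split()
    if "time_ps" in toks:
        try:
            return float(toks[toks.index("time_ps") + 1])
        except (IndexError, ValueError):
            raise FormatError(f"bad time in comment of frame {frame_idx}")
    if frame_interval is not None:
        return frame_idx * frame_interval
    return float(frame_idx)


# --------------------------------------------------------------------------- #
# DCD binary trajectories (via mdtraj)
# --------------------------------------------------------------------------- #

def write_dcd_trajectory(path, traj: Trajectory) -> None:
    from mdtraj.formats import DCDTrajectoryFile

    xyz = traj.coords / ANGSTROM_TO_NM  # nm -> Å on disk
    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(np.asarray(xyz, dtype=np.float32))


def read_dcd_trajectory(path, topology: Topology,
                        frame_interval: float | None = None) -> Trajectory:
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as fh:
        xyz, cell_lengths, _angles = fh.read()
    if xyz.shape[0] == 0:
        raise EmptyInputError(f"{path}: no frames")
    if xyz.shape[1] != topology.n_atoms:
        raise ShapeError(
            f"{path}: frames have {xyz.shape[1]} atoms, topology has "
            f"{topology.n_atoms}"
        )
    dt_ns = (frame_interval or 0.0) * 1e-3
    frames = [
        Frame(coords=np.asarray(fr, dtype=float) * ANGSTROM_TO_NM,
              time=i * dt_ns if frame_interval else float(i))
        for i, fr in enumerate(xyz)
    ]
    return Trajectory(topology, frames, frame_interval=frame_interval)


def read_trajectory(path, topology: Topology,
                    frame_interval: float | None = None) -> Trajectory:
    """Dispatch on extension: ``.dcd`` → binary DCD, anything else → XYZ text."""
    if str(path).lower().endswith(".dcd"):
        return read_dcd_trajectory(path, topology, frame_interval)
    return read_xyz_trajectory(path, topology, frame_interval)


def write_trajectory(path, traj: Trajectory) -> None:
    if str(path).lower().endswith(".dcd"):
        write_dcd_trajectory(path, traj)
    else:
        write_xyz_trajectory(path, traj)


# --------------------------------------------------------------------------- #
# Segment maps
# --------------------------------------------------------------------------- #

def load_segment_map(path) -> dict[str, list[tuple[int, int]]]:
    """Load a YAML segment map (label → list of [start, end] residue ranges)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: segment map must be a mapping")
    out: dict[str, list[tuple[int, int]]] = {}
    for label, ranges in raw.items():
        parsed: list[tuple[int, int]] = []
        for r in ranges:
            if not (isinstance(r, (list, tuple)) and len(r) == 2):
                raise FormatError(
                    f"{path}: segment {label!r}: ranges must be [start, end] pairs"
                )
            lo, hi = int(r[0]), int(r[1])
            if lo > hi:
                raise FormatError(f"{path}: segment {label!r}: empty range {r}")
            parsed.append((lo, hi))
        out[str(label)] = parsed
    return out


def default_segment_map() -> dict[str, list[tuple[int, int]]]:
    """The shipped SERCA1a segment map (TM helices M1–M10, N/P/A domains).

    Helix and domain boundaries are literature-conventional approximations
    keyed to SERCA1a crystal-structure numbering; real analyses should
    supply their own map when a different convention is wanted.
    """
    ref = importlib.resources.files("sercatools").joinpath("data/serca_segments.yaml")
    with importlib.resources.as_file(ref) as p:
        return load_segment_map(p)
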