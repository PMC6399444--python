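import numpy as np
import pytest

from sercatools.core import Atom, Frame, Topology, Trajectory
from sercatools.synth import make_structure_fixture


@pytest.fixture
def mixed_structure():
    """10 GLY residues + 1 POPC headgroup + 20 waters, deterministic."""
    return make_structure_fixture(n_protein_residues=10, n_lipids=1,
                                  n_waters=20, seed=7)


@pytest.fixture
def glu_topology():
    """Minimal topology holding a Glu309-like side chain plus waters."""
    atoms = (
        Atom(1, "OE1", "O", "GLU", 309, "A", "protein"),
        Atom(2, "OE2", "O", "GLU", 309, "A", "protein"),
        Atom(3, "CA", "C", "GLU", 309, "A", "protein"),
        Atom(4, "O", "O", "HOH", 1001, "W", "water"),
        Atom(5, "O", "O", "HOH", 1002, "W", "water"),
    )
    return Topology(atoms, segments={"M4": [(295, 330)]})


def random_topology(rng, n_atoms=200):
    """Random topology exercising all clause types, for property tests."""
    names = ["CA", "CB", "OE1", "N", "P", "O"]
    resnames = ["GLY", "GLU", "POPC", "HOH", "K"]
    atoms = []
    resid = 0
    for i in range(n_atoms):
        if i == 0 or rng.random() < 0.4:
            resid += 1
            resname = resnames[rng.integers(len(resnames))]
        atoms.append(
            Atom(
                atom_id=i + 1,
                name=names[rng.integers(len(names))],
                element="C",
                resname=resname,
                resid=resid,
                chain="A",
                category={"GLY": "protein", "GLU": "protein",
                          "POPC": "lipid", "HOH": "water", "K": "ion"}[resname],
            )
        )
    segments = {"S1": [(1, max(1, resid // 2))]}
    return Topology(tuple(atoms), segments=segments)


def make_trajectory(coords_per_frame, topology=None, frame_interval=20.0):
    """Trajectory from an (F, N, 3) array with uniform frame times."""
    coords_per_frame = np.asarray(coords_per_frame, dtype=float)
    if topology is None:
        n = coords_per_frame.shape[1]
        atoms = tuple(
            Atom(i + 1, "CA", "C", "ALA", i + 1, "A", "protein")
            for i in range(n)
        )
        topology = Topology(atoms)
    dt_ns = frame_interval * 1e-3
    frames = [Frame(coords=c, time=i * dt_ns)
              for i, c in enumerate(coords_per_frame)]
    return Trajectory(topology, frames, frame_interval=frame_interval)
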