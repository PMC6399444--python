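"""Core data model: topologies, frames, trajectories and atom selections.

All coordinates are stored in nanometres and all times in nanoseconds;
frame intervals are declared in picoseconds because trajectory-saving
intervals and hydrogen-bond lifetimes in this domain are conventionally
quoted in ps.  PDB files (ångström) are converted at the I/O boundary.

Residue numbering is 1-based and follows the numbering of the source
structure, so that SERCA1a residue labels such as Glu309 or Thr316 can be
used verbatim in selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "SercatoolsError",
    "FormatError",
    "EmptyInputError",
    "ShapeError",
    "SelectionError",
    "CardinalityError",
    "DegenerateFitError",
    "InsufficientDataError",
    "CATEGORIES",
    "categorize_residue",
    "ANGSTROM_TO_NM",
]

ANGSTROM_TO_NM = 0.1

CATEGORIES = ("protein", "lipid", "water", "ion")

#: Three-letter codes of the twenty standard amino acids plus common
#: protonation-state variants used by simulation force fields.
_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "GLUP", "ASPP", "CYX",
}

_WATER_RESNAMES = {"HOH", "TIP3", "TIP4", "WAT", "SOL", "SPC", "TP3"}

_ION_RESNAMES = {
    "K", "CL", "NA", "MG", "ZN", "POT", "SOD", "CLA", "CAL", "CA2", "KCL",
}


def categorize_residue(resname: str) -> str:
    """Assign one of the four atom categories from a residue name.

    Standard amino acids map to ``protein``, water models to ``water``,
    monatomic ions to ``ion``; everything else (phospholipids such as POPC
    or DOPC, ligands, detergents) falls into the ``lipid`` bucket, which
    doubles as the generic small-molecule category.
    """
    rn = resname.strip().upper()
    if rn in _PROTEIN_RESNAMES:
        return "protein"
    if rn in _WATER_RESNAMES:
        return "water"
    if rn in _ION_RESNAMES:
        return "ion"
    return "lipid"


class SercatoolsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SercatoolsError):
    """A file record could not be parsed; the message names the line."""


class EmptyInputError(SercatoolsError):
    """An input contained no usable data (zero atoms, empty series...)."""


class ShapeError(SercatoolsError):
    """Array or frame dimensions are inconsistent."""


class SelectionError(SercatoolsError):
    """A selection expression is invalid or empty where non-empty required."""


class CardinalityError(SercatoolsError):
    """A selection has the wrong number of atoms for the requested mode."""


class DegenerateFitError(SercatoolsError):
    """A least-squares superposition is underdetermined (collinear/< 3 atoms)."""


class InsufficientDataError(SercatoolsError):
    """Too few frames or samples for the requested statistic."""


class Atom(NamedTuple):
    atom_id: int            # 1-based, strictly increasing
    name: str               # e.g. "OE1"
    element: str            # e.g. "O"
    resname: str            # e.g. "GLU"
    resid: int              # 1-based residue number
    chain: str              # chain / segment identifier
    category: str           # one of CATEGORIES


@dataclass(frozen=True)
class Topology:
    """Ordered atom metadata plus named structural segments.

    ``segments`` maps labels such as ``"M2"`` or ``"N-domain"`` to lists of
    inclusive 1-based residue-id ranges, e.g. ``{"M2": [(89, 120)]}``.
    """

    atoms: tuple[Atom, ...]
    segments: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise EmptyInputError("topology must contain at least one atom")
        ids = np.array([a.atom_id for a in self.atoms])
        if not np.all(np.diff(ids) > 0):
            raise SercatoolsError("atom_ids must be strictly increasing and unique")
        for a in self.atoms:
            if a.category not in CATEGORIES:
                raise SercatoolsError(
                    f"atom {a.atom_id}: unknown category {a.category!r}"
                )
        resids = set(self.resids.tolist())
        for label, ranges in self.segments.items():
            if len(ranges) == 0:
                raise SercatoolsError(f"segment {label!r} has no residue ranges")
            if not any(r in resids for lo, hi in ranges for r in range(lo, hi + 1)):
                raise SercatoolsError(
                    f"segment {label!r} refers to no existing residue"
                )

    # --- cached column views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _col(self, key: str, dtype) -> np.ndarray:
        cache = self.__dict__.setdefault("_cols", {})
        if key not in cache:
            cache[key] = np.array([getattr(a, key) for a in self.atoms], dtype=dtype)
        return cache[key]

    @property
    def names(self) -> np.ndarray:
        return self._col("name", object)

    @property
    def elements(self) -> np.ndarray:
        return self._col("element", object)

    @property
    def resnames(self) -> np.ndarray:
        return self._col("resname", object)

    @property
    def resids(self) -> np.ndarray:
        return self._col("resid", np.int64)

    @property
    def chains(self) -> np.ndarray:
        return self._col("chain", object)

    @property
    def categories(self) -> np.ndarray:
        return self._col("category", object)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def segment_resid_mask(self, label: str) -> np.ndarray:
        """Boolean per-atom mask of a named segment."""
        if label not in self.segments:
            raise SelectionError(f"unknown segment label {label!r}")
        mask = np.zeros(self.n_atoms, dtype=bool)
        for lo, hi in self.segments[label]:
            mask |= (self.resids >= lo) & (self.resids <= hi)
        return mask

    def with_segments(self, segments: Mapping[str, Sequence[tuple[int, int]]]) -> "Topology":
        return Topology(self.atoms, dict(segments))


@dataclass
class Frame:
    """A single coordinate set: (n_atoms, 3) array in nm, time in ns.

    ``box`` optionally holds the three orthorhombic edge lengths in nm and
    enables minimum-image distances downstream.
    """

    coords: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("coords contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ShapeError("box must be three positive edge lengths (nm)")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology.

    ``frame_interval`` (ps) is pure metadata: the saving interval of the
    source simulation is unknowable from coordinates alone, so it is never
    guessed, only declared.  When declared, frame times must be uniformly
    spaced to 1e-9 relative tolerance.
    """

    topology: Topology
    frames: list[Frame]
    frame_interval: float | None = None  # picoseconds

    def __post_init__(self):
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ShapeError(
                    f"frame {i}: {fr.n_atoms} atoms, topology has {n}"
                )
        t = self.times
        if len(t) > 1:
            dt = np.diff(t)
            if not np.all(dt > 0):
                raise ShapeError("frame times must be strictly increasing")
            if self.frame_interval is not None:
                expected = self.frame_interval * 1e-3  # ps -> ns
                if not np.allclose(dt, expected, rtol=1e-9, atol=1e-12):
                    raise ShapeError(
                        "frame times not uniform at the declared frame_interval"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array (nm)."""
        if "_coords" not in self.__dict__:
            self.__dict__["_coords"] = np.stack([fr.coords for fr in self.frames])
        return self.__dict__["_coords"]


@dataclass(frozen=True)
class AtomSelection:
    """A sorted, unique set of 0-based atom positions into a Topology."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise SelectionError("indices must be one-dimensional")
        if len(idx) and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            idx = np.unique(idx)
            if idx[0] < 0:
                raise SelectionError("negative atom index in selection")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices.tolist())

    @staticmethod
    def from_mask(mask: np.ndarray, expression: str = "") -> "AtomSelection":
        return AtomSelection(np.flatnonzero(np.asarray(mask, bool)), expression)

    def mask(self, n_atoms: int) -> np.ndarray:
        m = np.zeros(n_atoms, dtype=bool)
        m[self.indices] = True
        return m
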