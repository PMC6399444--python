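"""Per-frame distance observables, occupancies, H-bond stability, histograms.

This is the machinery behind protein–lipid contact analysis: distance
probability distributions between named residue/headgroup atoms, fractions
of frames satisfying a distance criterion (``R <= 0.5 nm``-style thresholds
as well as crystal-structure boundary intervals), hydrogen-bond occupancy
expressed as a percentage of trajectory time, and the correlation between
a contact observable and a structural-mobility observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    AtomSelection,
    CardinalityError,
    EmptyInputError,
    Frame,
    InsufficientDataError,
    SelectionError,
    SercatoolsError,
    ShapeError,
    Topology,
    Trajectory,
)

__all__ = [
    "DistanceSeries",
    "OccupancyResult",
    "Histogram",
    "CorrelationResult",
    "HBondCriteria",
    "distance_series",
    "occupancy",
    "hbond_occupancy",
    "histogram",
    "contact_rmsd_correlation",
    "minimum_image_deltas",
    "NAMED_ATOM_MAP",
    "crystal_pair_distance",
]

DISTANCE_MODES = ("min-heavy-atom", "named-atom", "center-of-geometry")

#: Conventional atom names behind the named residue/headgroup pairs: the
#: lipid choline is represented by its nitrogen, the lipid phosphate by its
#: phosphorus, Gln/Asn by their side-chain amide atoms, Thr by its hydroxyl
#: oxygen, and interdomain distances use Cα.  All entries are overridable
#: conventions, not facts about any particular dataset.
NAMED_ATOM_MAP: dict[str, list[str]] = {
    "choline": ["N"],
    "phosphate": ["P"],
    "GLN": ["NE2", "OE1"],
    "ASN": ["ND2", "OD1"],
    "THR": ["OG1"],
    "GLU": ["OE1", "OE2"],
    "LYS": ["NZ"],
    "interdomain": ["CA"],
}


@dataclass
class DistanceSeries:
    """Per-frame scalar distance R (nm) for one labelled atom pair/group."""

    values: np.ndarray
    pair_label: str = ""
    mode: str = "min-heavy-atom"
    reference_value: float | None = None  # crystal-structure distance, nm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ShapeError("distance series must be one-dimensional")
        if len(self.values) and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ShapeError("distances must be finite and non-negative")

    def __len__(self):
        return len(self.values)


@dataclass
class OccupancyResult:
    """Fraction of frames satisfying a geometric criterion."""

    fraction: float
    n_frames_satisfying: int
    n_frames_total: int
    criterion: str

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass
class Histogram:
    """Density-normalized histogram: sum(density * width) == 1."""

    bin_edges: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ShapeError("bin edges must be strictly increasing")
        total = float(np.sum(self.densities * widths))
        if abs(total - 1.0) > 1e-9:
            raise ShapeError(f"histogram not normalized (integral {total})")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CorrelationResult:
    r: float
    n: int


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Defaults (donor–acceptor heavy-atom distance ≤ 0.35 nm, donor–H–acceptor
    angle ≥ 150°) are the conventional values used across MD analysis tools;
    when the topology carries no hydrogens the angle term cannot be evaluated
    and a distance-only fallback is applied (recorded in the result).
    """

    d_max: float = 0.35        # nm, donor–acceptor heavy-atom distance
    angle_min: float = 150.0   # degrees, donor–H–acceptor
    dh_max: float = 0.125      # nm, covalent donor–H bond detection distance


# --------------------------------------------------------------------------- #
# distances
# --------------------------------------------------------------------------- #

def minimum_image_deltas(deltas: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors."""
    if box is None:
        return deltas
    return deltas - box * np.round(deltas / box)


def _pair_min_distance(a: np.ndarray, b: np.ndarray, box) -> float:
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_deltas(d, box)
    return float(np.sqrt((d ** 2).sum(axis=-1)).min())


def distance_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    mode: str = "min-heavy-atom",
    pair_label: str = "",
    reference_value: float | None = None,
) -> DistanceSeries:
    """Per-frame distance between two selections.

    ``min-heavy-atom``: minimum pairwise distance over non-hydrogen atoms of
    the two selections.  ``named-atom``: both selections must be singletons.
    ``center-of-geometry``: distance between the unweighted centroids.
    The minimum-image convention is applied whenever a frame declares a box.
    """
    if mode not in DISTANCE_MODES:
        raise SercatoolsError(f"unknown distance mode {mode!r}")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("distance_series requires two non-empty selections")
    ia, ib = sel_a.indices, sel_b.indices
    if mode == "named-atom" and (len(ia) != 1 or len(ib) != 1):
        raise CardinalityError(
            "named-atom mode requires singleton selections "
            f"(got {len(ia)} and {len(ib)} atoms)"
        )
    if mode == "min-heavy-atom":
        heavy = traj.topology.heavy_mask
        ia = ia[heavy[ia]]
        ib = ib[heavy[ib]]
        if len(ia) == 0 or len(ib) == 0:
            raise SelectionError("selection contains no heavy atoms")
    values = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        if mode == "center-of-geometry":
            d = fr.coords[ia].mean(axis=0) - fr.coords[ib].mean(axis=0)
            d = minimum_image_deltas(d, fr.box)
            values[k] = float(np.linalg.norm(d))
        else:
            values[k] = _pair_min_distance(fr.coords[ia], fr.coords[ib], fr.box)
    return DistanceSeries(values, pair_label=pair_label, mode=mode,
                          reference_value=reference_value)


# --------------------------------------------------------------------------- #
# occupancies
# --------------------------------------------------------------------------- #

def occupancy(series: DistanceSeries, interval: tuple[float, float]) -> OccupancyResult:
    """Fraction of frames with lo ≤ R ≤ hi (closed on both ends).

    The closed-interval convention makes a pure upper threshold
    ``R ≤ 0.5 nm`` expressible as ``(0, 0.5)`` with the boundary included.
    """
    lo, hi = interval
    if not lo < hi:
        raise SercatoolsError(f"interval must satisfy lo < hi, got {interval}")
    if len(series) == 0:
        raise EmptyInputError("occupancy of an empty series is undefined")
    sat = int(np.count_nonzero((series.values >= lo) & (series.values <= hi)))
    n = len(series)
    label = series.pair_label or "R"
    return OccupancyResult(
        fraction=sat / n,
        n_frames_satisfying=sat,
        n_frames_total=n,
        criterion=f"{lo} <= {label} <= {hi} nm",
    )


# --------------------------------------------------------------------------- #
# hydrogen bonds
# --------------------------------------------------------------------------- #

def _donor_hydrogens(topology: Topology, frame: Frame, donor_idx: np.ndarray,
                     dh_max: float) -> dict[int, np.ndarray]:
    """Map each donor heavy atom to the indices of its covalent hydrogens."""
    h_idx = np.flatnonzero(topology.elements == "H")
    out: dict[int, np.ndarray] = {}
    if len(h_idx) == 0:
        return out
    for d in donor_idx:
        delta = minimum_image_deltas(frame.coords[h_idx] - frame.coords[d], frame.box)
        dist = np.linalg.norm(delta, axis=1)
        out[int(d)] = h_idx[dist <= dh_max]
    return out


def hbond_satisfied_frame(
    topology: Topology,
    frame: Frame,
    donor_idx: np.ndarray,
    acceptor_idx: np.ndarray,
    criteria: HBondCriteria,
    use_angle: bool,
) -> bool:
    """True if any donor–acceptor pair forms an H-bond in this frame."""
    hmap = _donor_hydrogens(topology, frame, donor_idx, criteria.dh_max) if use_angle else {}
    for d in donor_idx:
        delta = minimum_image_deltas(
            frame.coords[acceptor_idx] - frame.coords[d], frame.box
        )
        dist = np.linalg.norm(delta, axis=1)
        close = acceptor_idx[(dist <= criteria.d_max) & (dist > 1e-9)]
        if len(close) == 0:
            continue
        if not use_angle:
            return True
        hs = hmap.get(int(d), np.empty(0, dtype=int))
        for a in close:
            for h in hs:
                v1 = minimum_image_deltas(frame.coords[d] - frame.coords[h], frame.box)
                v2 = minimum_image_deltas(frame.coords[a] - frame.coords[h], frame.box)
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 < 1e-12 or n2 < 1e-12:
                    continue
                cos_dha = float(np.dot(v1, v2) / (n1 * n2))
                # angle at H >= angle_min  <=>  cos(angle) <= cos(angle_min)
                if cos_dha <= np.cos(np.deg2rad(criteria.angle_min)):
                    return True
    return False


def hbond_occupancy(
    traj: Trajectory,
    donor_sel: AtomSelection,
    acceptor_sel: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> OccupancyResult:
    """Percentage of frames in which an H-bond links the two selections.

    A frame satisfies the criterion when any donor–acceptor pair is within
    ``d_max`` and (when hydrogens are present in the topology) some donor
    hydrogen makes a donor–H–acceptor angle ≥ ``angle_min``.  Without
    hydrogens the check degrades to distance-only and the result's
    criterion string records the fallback.
    """
    if len(donor_sel) == 0 or len(acceptor_sel) == 0:
        raise SelectionError("hbond_occupancy requires non-empty selections")
    has_h = bool(np.any(traj.topology.elements == "H"))
    use_angle = has_h
    sat = 0
    for fr in traj.frames:
        if hbond_satisfied_frame(traj.topology, fr, donor_sel.indices,
                                 acceptor_sel.indices, criteria, use_angle):
            sat += 1
    crit = f"d(D..A) <= {criteria.d_max} nm"
    if use_angle:
        crit += f" and angle(D-H..A) >= {criteria.angle_min} deg"
    else:
        crit += " [distance-only fallback: no hydrogens in topology]"
    n = traj.n_frames
    return OccupancyResult(sat / n, sat, n, crit)


# --------------------------------------------------------------------------- #
# histograms and correlation
# --------------------------------------------------------------------------- #

def histogram(series: DistanceSeries, bin_width: float = 0.025) -> Histogram:
    """Density histogram with edges snapped to multiples of ``bin_width``."""
    if bin_width <= 0:
        raise SercatoolsError("bin_width must be positive")
    if len(series) == 0:
        raise EmptyInputError("cannot histogram an empty series")
    v = series.values
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo + 1e-12:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    dens, edges = np.histogram(v, bins=edges, density=True)
    return Histogram(edges, dens)


def contact_rmsd_correlation(contact_series: np.ndarray,
                             rmsd_series: np.ndarray) -> CorrelationResult:
    """Pearson correlation between a contact observable and an RMSD series."""
    x = np.asarray(contact_series, dtype=float)
    y = np.asarray(rmsd_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("series must be one-dimensional and equal length")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise SercatoolsError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=len(x))


# --------------------------------------------------------------------------- #
# crystal worked values
# --------------------------------------------------------------------------- #

def crystal_pair_distance(
    topology: Topology,
    frame: Frame,
    resid_a: int,
    resid_b: int,
    atoms_a: list[str] | None = None,
    atoms_b: list[str] | None = None,
) -> float:
    """Minimum distance (nm) between mapped side-chain atoms of two residues.

    When atom-name lists are not given, the shipped :data:`NAMED_ATOM_MAP`
    entry for each residue's name is used (e.g. Gln → NE2/OE1, Thr → OG1).
    This is the convention behind crystal-structure reference distances such
    as the Gln108–Thr316 interhelical pair.
    """
    from .selection import select

    def _resolve(resid, names):
        mask = topology.resids == resid
        if names is None:
            rn = topology.resnames[mask]
            if len(rn) == 0:
                raise SelectionError(f"residue {resid} not in topology")
            names = NAMED_ATOM_MAP.get(str(rn[0]).upper())
            if names is None:
                raise SelectionError(
                    f"no shipped atom map for residue type {rn[0]!r}"
                )
        idx = np.flatnonzero(mask & np.isin(topology.names, names))
        if len(idx) == 0:
            raise SelectionError(
                f"residue {resid}: none of atoms {names} present"
            )
        return idx

    ia = _resolve(resid_a, atoms_a)
    ib = _resolve(resid_b, atoms_b)
    return _pair_min_distance(frame.coords[ia], frame.coords[ib], frame.box)
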