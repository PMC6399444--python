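"""Optimal superposition, RMSD profiling and conformational clustering.

Superposition uses the closed-form least-squares optimal rotation (the
Kabsch/quaternion family, computed via :func:`scipy.spatial.transform.
Rotation.align_vectors`), which is deterministic and exact up to floating
point.  Per-segment RMSD profiles, RMSD time series and leader/medoid
clustering are built on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    AtomSelection,
    DegenerateFitError,
    Frame,
    SelectionError,
    ShapeError,
    Topology,
    Trajectory,
)

__all__ = [
    "SuperpositionResult",
    "SegmentRMSDProfile",
    "ClusterResult",
    "Cluster",
    "superpose",
    "apply_superposition",
    "rmsd",
    "segment_rmsd_profile",
    "rmsd_timeseries",
    "cluster_conformations",
    "BACKBONE_NAMES",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    """Rigid transform x -> R @ x + t minimizing RMSD over the fit atoms."""

    rotation: np.ndarray    # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), nm
    rmsd: float             # nm, over the fit selection after the transform


@dataclass
class SegmentRMSDProfile:
    labels: list[str]
    mean_rmsd: np.ndarray  # nm, per segment
    sd_rmsd: np.ndarray    # nm, per segment
    per_frame: np.ndarray  # (n_frames, n_segments) nm

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            lab: (float(m), float(s))
            for lab, m, s in zip(self.labels, self.mean_rmsd, self.sd_rmsd)
        }


@dataclass
class Cluster:
    members: np.ndarray       # frame indices
    population: float         # fraction of all frames
    representative: int       # medoid frame index


@dataclass
class ClusterResult:
    clusters: list[Cluster]

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.clusters])


def _check_fit_coords(x: np.ndarray, what: str) -> None:
    if x.shape[0] < 3:
        raise DegenerateFitError(f"{what}: need at least 3 atoms for a fit")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateFitError(f"{what}: fit atoms are collinear")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_sel: AtomSelection | np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mobile onto reference.

    ``fit_sel`` restricts both coordinate sets to the same atom subset for
    fitting; the reported RMSD is over that subset after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError(
            f"coordinate shapes differ or are not (n, 3): "
            f"{mobile.shape} vs {reference.shape}"
        )
    idx = None
    if fit_sel is not None:
        idx = fit_sel.indices if isinstance(fit_sel, AtomSelection) else np.asarray(fit_sel)
        mob_fit, ref_fit = mobile[idx], reference[idx]
    else:
        mob_fit, ref_fit = mobile, reference
    _check_fit_coords(ref_fit, "reference")
    _check_fit_coords(mob_fit, "mobile")
    mob_c = mob_fit - mob_fit.mean(axis=0)
    ref_c = ref_fit - ref_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref_fit.mean(axis=0) - R @ mob_fit.mean(axis=0)
    moved = mob_fit @ R.T + t
    val = float(np.sqrt(np.mean(np.sum((moved - ref_fit) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=val)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ result.rotation.T + result.translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no refit) root-mean-square deviation between coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeError("coordinate shapes differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _segment_measure_indices(
    topology: Topology, label: str, measure: str
) -> np.ndarray:
    mask = topology.segment_resid_mask(label)
    if measure == "backbone":
        mask &= np.isin(topology.names, BACKBONE_NAMES) & (
            topology.categories == "protein"
        )
    elif measure == "heavy":
        mask &= topology.heavy_mask
    elif measure != "all":
        raise SelectionError(f"unknown measure mode {measure!r}")
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(f"segment {label!r}: no atoms under measure {measure!r}")
    return idx


def segment_rmsd_profile(
    traj: Trajectory,
    reference: Frame,
    segments: list[str],
    fit_sel: AtomSelection,
    measure: str = "backbone",
) -> SegmentRMSDProfile:
    """Mean ± sd RMSD per named segment, after per-frame superposition.

    Each frame is first superposed on the reference over ``fit_sel`` (for
    helix profiles, typically the backbone of all TM helices); the RMSD of
    each segment is then measured over that segment's ``measure`` atoms
    (backbone by default) without refitting, so the profile reports how
    each segment moves within the common frame of the fit.
    """
    seg_idx = {
        lab: _segment_measure_indices(traj.topology, lab, measure)
        for lab in segments
    }
    per_frame = np.empty((traj.n_frames, len(segments)))
    for k, fr in enumerate(traj.frames):
        sup = superpose(fr.coords, reference.coords, fit_sel)
        moved = apply_superposition(fr.coords, sup)
        for j, lab in enumerate(segments):
            idx = seg_idx[lab]
            per_frame[k, j] = rmsd(moved[idx], reference.coords[idx])
    return SegmentRMSDProfile(
        labels=list(segments),
        mean_rmsd=per_frame.mean(axis=0),
        sd_rmsd=per_frame.std(axis=0),
        per_frame=per_frame,
    )


def rmsd_timeseries(
    traj: Trajectory,
    reference: Frame,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after per-frame superposition.

    ``measure_sel`` defaults to the fit selection (fit and measure on the
    same atoms, e.g. the cytosolic-headpiece backbone).
    """
    if measure_sel is None:
        measure_sel = fit_sel
    out = np.empty(traj.n_frames)
    midx = measure_sel.indices
    for k, fr in enumerate(traj.frames):
        sup = superpose(fr.coords, reference.coords, fit_sel)
        moved = apply_superposition(fr.coords, sup)
        out[k] = rmsd(moved[midx], reference.coords[midx])
    return out


def cluster_conformations(
    traj: Trajectory,
    sel: AtomSelection,
    cutoff: float = 0.1,
) -> ClusterResult:
    """Leader clustering on pairwise RMSD, with medoid representatives.

    Frames are assumed pre-aligned on a fit selection of the caller's
    choosing; distances here are plain RMSD over ``sel`` with no refit.
    Frames are scanned in order: a frame joins the first cluster whose
    leader (founding frame) is within ``cutoff``, otherwise founds a new
    cluster.  Representatives are then re-assigned as in-cluster medoids
    (the member minimizing summed RMSD to all other members), and clusters
    are sorted by descending population.
    """
    if cutoff <= 0:
        raise ShapeError("cutoff must be positive")
    if len(sel) == 0:
        raise SelectionError("clustering requires a non-empty selection")
    X = traj.coords[:, sel.indices, :]
    n = X.shape[0]
    leaders: list[int] = []
    assign = np.empty(n, dtype=int)
    for i in range(n):
        placed = False
        for c, lead in enumerate(leaders):
            if rmsd(X[i], X[lead]) <= cutoff:
                assign[i] = c
                placed = True
                break
        if not placed:
            leaders.append(i)
            assign[i] = len(leaders) - 1
    clusters: list[Cluster] = []
    for c in range(len(leaders)):
        members = np.flatnonzero(assign == c)
        sub = X[members]
        m = len(members)
        if m == 1:
            medoid = members[0]
        else:
            diffs = sub[:, None, :, :] - sub[None, :, :, :]
            dmat = np.sqrt((diffs ** 2).sum(axis=-1).mean(axis=-1))
            medoid = members[int(np.argmin(dmat.sum(axis=1)))]
        clusters.append(Cluster(members=members, population=m / n,
                                representative=int(medoid)))
    clusters.sort(key=lambda c: (-c.population, c.representative))
    return ClusterResult(clusters=clusters)
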