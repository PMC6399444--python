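"""Cartesian principal component analysis of positional fluctuations.

After rigid-body alignment on a reference (conventionally the ten-helix
transmembrane domain), the 3N-dimensional covariance matrix of the selected
atoms' coordinates is eigendecomposed.  Projections of the trajectory onto
the eigenvectors are the principal components; each component's projection
histogram is fitted to a single Gaussian by least squares, and its
coefficient of determination r² classifies the component:

* r² < 0.9          — essential (markedly non-Gaussian collective motion)
* 0.9 ≤ r² < 0.98   — partial (retains significant non-Gaussian features)
* r² ≥ 0.98         — non-essential (Gaussian fluctuation)

Collinearity between the component sets of two trajectories is measured by
the matrix of absolute inner products of unit eigenvectors: entries near 1
mean the two components span the same direction of the structural space,
entries near 0 mean orthogonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .core import (
    AtomSelection,
    Frame,
    InsufficientDataError,
    SercatoolsError,
    ShapeError,
    Trajectory,
)
from .metrics import apply_superposition, superpose

__all__ = [
    "PCModel",
    "GaussianFit",
    "fit_pca",
    "variance_accounting",
    "components_needed",
    "project",
    "classify_gaussianity",
    "inner_products",
    "CLASS_ESSENTIAL",
    "CLASS_PARTIAL",
    "CLASS_NON_ESSENTIAL",
    "classify_r_squared",
]

CLASS_ESSENTIAL = "essential"
CLASS_PARTIAL = "partial"
CLASS_NON_ESSENTIAL = "non-essential"

R2_ESSENTIAL_MAX = 0.9
R2_PARTIAL_MAX = 0.98


@dataclass
class PCModel:
    """Eigendecomposition of the positional covariance of selected atoms."""

    mean_coords: np.ndarray        # (n_sel, 3) nm
    eigenvectors: np.ndarray       # (3*n_sel, k), orthonormal columns
    eigenvalues: np.ndarray        # (k,), nm², descending, >= 0
    atom_selection: AtomSelection
    fit_reference: np.ndarray | None = None  # full-topology coords used to align
    fit_indices: np.ndarray | None = None
    degenerate: np.ndarray | None = None     # bool flags: eigenvalue gap < 1e-6 rel.

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def check(self, atol: float = 1e-8) -> None:
        V = self.eigenvectors
        g = V.T @ V
        if np.max(np.abs(g - np.eye(g.shape[0]))) > atol:
            raise ShapeError("eigenvector matrix not orthonormal")
        if np.any(np.diff(self.eigenvalues) > atol):
            raise ShapeError("eigenvalues not descending")


@dataclass
class GaussianFit:
    """One-Gaussian least-squares fit to a projection histogram."""

    amplitude: float
    mu: float
    sigma: float
    r_squared: float
    classification: str | None
    message: str = ""


def classify_r_squared(r2: float) -> str:
    if r2 < R2_ESSENTIAL_MAX:
        return CLASS_ESSENTIAL
    if r2 < R2_PARTIAL_MAX:
        return CLASS_PARTIAL
    return CLASS_NON_ESSENTIAL


def _aligned_coords(
    traj: Trajectory,
    sel_idx: np.ndarray,
    fit_reference: Frame | None,
    fit_sel: AtomSelection | None,
) -> np.ndarray:
    """(n_frames, n_sel, 3) coordinates, optionally aligned per frame."""
    if fit_reference is None:
        return traj.coords[:, sel_idx, :]
    fidx = fit_sel if fit_sel is not None else None
    out = np.empty((traj.n_frames, len(sel_idx), 3))
    for k, fr in enumerate(traj.frames):
        sup = superpose(fr.coords, fit_reference.coords, fidx)
        out[k] = apply_superposition(fr.coords, sup)[sel_idx]
    return out


def fit_pca(
    traj: Trajectory,
    sel: AtomSelection,
    fit_reference: Frame | None = None,
    fit_sel: AtomSelection | None = None,
) -> PCModel:
    """PCA of the selected atoms' coordinates about their trajectory mean.

    When ``fit_reference`` is given every frame is first superposed on it
    over ``fit_sel`` (the standard way to remove rigid-body motion before
    essential-dynamics analysis); pass ``None`` for frames that are already
    aligned.  Components are ordered by descending eigenvalue; each
    eigenvector's sign is fixed so its largest-magnitude entry is positive.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    if len(sel) == 0:
        raise SercatoolsError("PCA selection is empty")
    X = _aligned_coords(traj, sel.indices, fit_reference, fit_sel)
    F = X.shape[0]
    flat = X.reshape(F, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (F - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    degenerate = np.zeros(len(evals), dtype=bool)
    if total > 0:
        gaps = np.abs(np.diff(evals)) / total
        small = gaps < 1e-6
        degenerate[:-1] |= small
        degenerate[1:] |= small
    return PCModel(
        mean_coords=mean.reshape(-1, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        atom_selection=sel,
        fit_reference=None if fit_reference is None else fit_reference.coords.copy(),
        fit_indices=None if fit_sel is None else np.asarray(fit_sel.indices),
        degenerate=degenerate,
    )


def variance_accounting(model: PCModel) -> np.ndarray:
    """Cumulative fraction of total variance carried by the first k components."""
    total = model.eigenvalues.sum()
    if total == 0:
        raise SercatoolsError("model has zero total variance")
    return np.cumsum(model.eigenvalues) / total


def components_needed(model: PCModel, fraction: float) -> int:
    """Smallest k whose cumulative variance reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise SercatoolsError(f"fraction must be in (0, 1], got {fraction}")
    curve = variance_accounting(model)
    k = int(np.searchsorted(curve, fraction - 1e-12)) + 1
    return min(k, len(curve))


def project(traj: Trajectory, model: PCModel, k: int) -> np.ndarray:
    """Per-frame projection of the trajectory onto component ``k`` (0-based)."""
    if not 0 <= k < model.n_components:
        raise IndexError(f"component {k} out of range (model has {model.n_components})")
    fit_ref = None
    fit_sel = None
    if model.fit_reference is not None:
        fit_ref = Frame(coords=model.fit_reference)
        fit_sel = None if model.fit_indices is None else AtomSelection(model.fit_indices)
    X = _aligned_coords(traj, model.atom_selection.indices, fit_ref, fit_sel)
    dev = X.reshape(X.shape[0], -1) - model.mean_coords.reshape(-1)
    return dev @ model.eigenvectors[:, k]


def classify_gaussianity(values: np.ndarray, n_bins: int = 50) -> GaussianFit:
    """Fit one Gaussian to the projection histogram and classify by r².

    The histogram spans mean ± 4 sd with ``n_bins`` bins; the Gaussian
    (amplitude, mu, sigma) is fitted by least squares to the bin densities
    and r² = 1 − SS_res/SS_tot is computed over those densities.  If the
    fit fails to converge the classification is withheld and the failure
    reported in ``message``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 100:
        raise InsufficientDataError("classification needs at least 100 samples")
    m, s = v.mean(), v.std()
    if s == 0:
        raise SercatoolsError("projection has zero variance")
    edges = np.linspace(m - 4 * s, m + 4 * s, n_bins + 1)
    dens, edges = np.histogram(v, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))

    p0 = (float(dens.max()), float(m), float(s))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(gauss, centers, dens, p0=p0, maxfev=10000)
    except RuntimeError as err:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, None,
                           message=f"fit did not converge: {err}")
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    resid = dens - gauss(centers, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return GaussianFit(float(a), float(mu), sigma, r2, classify_r_squared(r2))


def inner_products(model_a: PCModel, model_b: PCModel, k: int) -> np.ndarray:
    """k×k matrix of absolute inner products between unit eigenvectors.

    Entry (i, j) = \\|v_i^A · v_j^B\\|; values near 1 mean the components span
    the same direction (collinear), near 0 orthogonal subspaces.
    """
    if model_a.eigenvectors.shape[0] != model_b.eigenvectors.shape[0]:
        raise ShapeError("models built on different coordinate dimensions")
    if k > model_a.n_components or k > model_b.n_components:
        raise ShapeError(f"models provide fewer than {k} components")
    A = model_a.eigenvectors[:, :k]
    B = model_b.eigenvectors[:, :k]
    return np.abs(A.T @ B)
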