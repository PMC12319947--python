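"""Structural connectome container, normalized Laplacian, and its eigenmode basis.

The structural graph is an undirected, weighted graph whose vertices are
atlas brain regions and whose edge weights quantify white-matter connection
strength (e.g. fiber density).  Its symmetric normalized Laplacian

    L = I - D^{-1/2} A D^{-1/2}

has an orthonormal eigenvector basis ("connectome harmonics") ordered by
eigenvalue; low-eigenvalue modes vary smoothly over the graph, high ones are
spatially localized.  All downstream graph-Fourier machinery lives on top of
this basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "StructuralConnectome",
    "GraphSpectrum",
    "load_connectome",
    "save_connectome",
    "normalized_laplacian",
    "eigendecompose",
    "save_spectrum",
    "DegenerateCutoffWarning",
]

#: tolerance for enforcing/accepting symmetry of input weight matrices
SYMMETRY_TOL = 1e-8

#: eigenvalues of the symmetric normalized Laplacian live in [0, 2]
EIGENVALUE_RANGE_TOL = 1e-8


class DegenerateCutoffWarning(UserWarning):
    """Raised when a spectral cutoff would split a (near-)degenerate eigenspace."""


@dataclass
class StructuralConnectome:
    """Weighted undirected graph over atlas regions.

    Parameters
    ----------
    region_ids
        Ordered region labels; the region order is the single source of
        truth for every matrix/vector the pipeline produces.
    weights
        ``(N, N)`` symmetric nonnegative weight matrix, zero diagonal.
    subject_id
        Free-form identifier.
    """

    region_ids: list[str]
    weights: np.ndarray
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Weighted node degrees (row sums of the adjacency matrix)."""
        return self.weights.sum(axis=1)

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError("a connectome needs at least 2 regions")
        if len(self.region_ids) != n:
            raise ValueError(
                f"{len(self.region_ids)} region labels for {n}x{n} matrix"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weight matrix contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("negative connection weights are not allowed")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be exactly zero")
        asym = np.max(np.abs(w - w.T)) if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"weight matrix asymmetric (max |A - A^T| = {asym:g})")
        deg = w.sum(axis=1)
        if np.any(deg <= 0):
            bad = [self.region_ids[i] for i in np.flatnonzero(deg <= 0)]
            raise ValueError(f"isolated regions (zero degree): {bad}")


@dataclass
class GraphSpectrum:
    """Eigendecomposition of a symmetric normalized Laplacian.

    ``eigenvectors[:, k]`` is the harmonic paired with ``eigenvalues[k]``;
    eigenvalues are ascending, the basis is orthonormal, and each column's
    sign is fixed deterministically (largest-magnitude entry positive).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sign_convention: str = "max-abs-entry-positive"

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def validate(self, atol: float = EIGENVALUE_RANGE_TOL) -> None:
        lam, u = self.eigenvalues, self.eigenvectors
        if np.any(np.diff(lam) < 0):
            raise ValueError("eigenvalues must be sorted ascending")
        if lam.min() < -atol or lam.max() > 2 + atol:
            raise ValueError("normalized-Laplacian eigenvalues must lie in [0, 2]")
        gram = u.T @ u
        if not np.allclose(gram, np.eye(len(lam)), atol=1e-8):
            raise ValueError("eigenvector matrix is not orthonormal")


def _sniff_delimiter(path: str) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # whitespace


def load_connectome(
    path: str,
    region_table: str | None = None,
    subject_id: str | None = None,
) -> StructuralConnectome:
    """Read a square delimited weight matrix (comma/tab/whitespace) from disk.

    Tiny asymmetries (max |A - A^T| <= 1e-8), as emitted by some tractography
    pipelines, are repaired by averaging ``A`` with its transpose; larger
    asymmetry is an error.  An optional ``region_table`` file supplies one
    region label per line; otherwise labels are ``R000, R001, ...``.
    """
    delim = _sniff_delimiter(path)
    w = np.loadtxt(path, delimiter=delim, ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome file {path!r} is not square: {w.shape}")
    asym = np.max(np.abs(w - w.T))
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"connectome asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if region_table is not None:
        with open(region_table) as fh:
            labels = [line.strip() for line in fh if line.strip()]
    else:
        labels = [f"R{i:03d}" for i in range(w.shape[0])]
    return StructuralConnectome(
        region_ids=labels,
        weights=w,
        subject_id=subject_id or "unknown",
    )


def save_connectome(conn: StructuralConnectome, path: str) -> None:
    """Write the weight matrix as comma-delimited text (full precision)."""
    np.savetxt(path, conn.weights, delimiter=",", fmt="%.17g")


def normalized_laplacian(connectome: StructuralConnectome) -> np.ndarray:
    """Symmetric normalized Laplacian ``L = I - D^{-1/2} A D^{-1/2}``."""
    a = connectome.weights
    d_inv_sqrt = 1.0 / np.sqrt(connectome.degrees)
    lap = -d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    np.fill_diagonal(lap, 1.0)
    return (lap + lap.T) / 2.0


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| entry is positive (ties: lowest index)."""
    idx = np.argmax(np.abs(u), axis=0)  # argmax returns the first maximum
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs[None, :]


def eigendecompose(laplacian: np.ndarray) -> GraphSpectrum:
    """Full eigendecomposition of a symmetric matrix into a GraphSpectrum.

    Eigenpairs come out ascending by eigenvalue (LAPACK ``eigh``), and each
    eigenvector's sign is made deterministic so repeated runs and different
    platforms produce identical bases.  Bases inside a degenerate eigenspace
    are still only unique up to rotation; downstream index-set projections
    are unaffected as long as a cutoff never splits such a subspace.
    """
    laplacian = np.asarray(laplacian, dtype=float)
    if not np.allclose(laplacian, laplacian.T, atol=1e-10):
        raise ValueError("eigendecompose requires a symmetric matrix")
    eigenvalues, eigenvectors = scipy.linalg.eigh(laplacian)
    order = np.argsort(eigenvalues, kind="stable")
    return GraphSpectrum(
        eigenvalues=eigenvalues[order],
        eigenvectors=_fix_signs(eigenvectors[:, order]),
    )


def warn_if_degenerate_cutoff(
    spectrum: GraphSpectrum, cutoff: int, tol: float = 1e-10
) -> None:
    """Warn when the coupled/decoupled boundary falls inside a degenerate pair."""
    lam = spectrum.eigenvalues
    if 1 <= cutoff < len(lam) and abs(lam[cutoff] - lam[cutoff - 1]) < tol:
        warnings.warn(
            f"cutoff C={cutoff} splits a degenerate eigenvalue pair "
            f"(|lambda_C - lambda_C+1| < {tol:g}); filtered components "
            "depend on the solver's basis choice there",
            DegenerateCutoffWarning,
            stacklevel=2,
        )


def save_spectrum(spectrum: GraphSpectrum, eigenvalue_path: str,
                  eigenvector_path: str, sidecar_path: str | None = None) -> None:
    """Export eigenvalues + eigenvector matrix as delimited text.

    The optional sidecar records the sign convention and tolerances so a
    dump can be audited without re-running the decomposition.
    """
    np.savetxt(eigenvalue_path, spectrum.eigenvalues, delimiter=",", fmt="%.17g")
    np.savetxt(eigenvector_path, spectrum.eigenvectors, delimiter=",", fmt="%.17g")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write(f"sign_convention: {spectrum.sign_convention}\n")
            fh.write(f"eigenvalue_range_tol: {EIGENVALUE_RANGE_TOL}\n")
            fh.write(f"symmetry_tol: {SYMMETRY_TOL}\n")
            fh.write(f"n_modes: {spectrum.n_modes}\n")
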