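"""Conformational substates via covariance PCA and partitional clustering.

Essential-dynamics convention: frames are rigid-body aligned (by default onto
the first frame over the analysis selection), the 3N Cartesian coordinates of
the N selected atoms form the sample vectors, and the covariance matrix

    c_ij = < (x_i - <x_i>) (x_j - <x_j>) >        (average over frames)

is diagonalized.  The leading eigenvectors span the large-amplitude collective
motions; projections of the frames onto a few of them are clustered (KMeans)
into conformational substates, each represented by the member frame closest to
its cluster centroid.

The covariance average uses 1/n by default (``ddof=0``); pass ``ddof=1`` for
the sample-covariance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .traj_metrics import TrajectoryEnsemble, _resolve, apply_transform, superpose

__all__ = [
    "CovarianceMatrix",
    "SubstateModel",
    "coordinate_matrix",
    "covariance",
    "pca",
    "scree_table",
    "project",
    "cluster_substates",
    "centroid_frames",
    "choose_dims",
    "silhouette_scan",
    "find_substates",
]

#: Default master seed for the stochastic clustering restarts.
DEFAULT_SEED = 2023


def coordinate_matrix(traj: TrajectoryEnsemble, selection=None,
                      align: bool = True, reference_frame: int = 0) -> np.ndarray:
    """Flattened (n_frames, 3N) coordinates of the selected atoms.

    With ``align=True`` every frame is first superposed onto the reference
    frame over the selection, removing rigid-body variance.
    """
    idx = _resolve(selection, traj.n_atoms)
    if align:
        ref = traj.coords[reference_frame]
        frames = [
            apply_transform(traj.coords[i], superpose(traj.coords[i], ref, idx))[idx]
            for i in range(traj.n_frames)
        ]
        X = np.stack(frames)
    else:
        X = traj.coords[:, idx, :]
    return X.reshape(traj.n_frames, -1)


@dataclass(frozen=True)
class CovarianceMatrix:
    """3N x 3N coordinate covariance (Angstrom^2) plus the mean vector."""

    matrix: np.ndarray
    mean: np.ndarray
    n_frames: int
    ddof: int = 0

    @property
    def trace(self) -> float:
        """Total coordinate variance (Angstrom^2)."""
        return float(np.trace(self.matrix))


def covariance(traj: TrajectoryEnsemble, selection=None, align: bool = True,
               ddof: int = 0, reference_frame: int = 0) -> CovarianceMatrix:
    """Coordinate covariance matrix over frames for the selected atoms."""
    if traj.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    X = coordinate_matrix(traj, selection, align=align, reference_frame=reference_frame)
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / (traj.n_frames - ddof)
    return CovarianceMatrix(matrix=C, mean=mean, n_frames=traj.n_frames, ddof=ddof)


@dataclass(frozen=True)
class SubstateModel:
    """Eigen-decomposition of a coordinate covariance, plus clustering results.

    ``eigenvalues`` are descending (Angstrom^2); ``eigenvectors`` holds the
    matching orthonormal eigenvectors in its *columns*.  The clustering fields
    are filled by :func:`find_substates` (or manually).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean: np.ndarray
    projections: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    cluster_centers: np.ndarray | None = None
    centroid_frames: np.ndarray | None = None
    kept_dims: int | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def pca(cov: CovarianceMatrix) -> SubstateModel:
    """Eigen-decomposition of the covariance; eigenvalues descending.

    The eigenvector sign is fixed deterministically (largest-magnitude
    component made positive) so degenerate spectra still yield reproducible
    output.  The eigenvalue sum equals the covariance trace.
    """
    C = np.asarray(cov.matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance matrix must be square")
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return SubstateModel(eigenvalues=vals, eigenvectors=vecs, mean=cov.mean)


def scree_table(model: SubstateModel, max_rows: int | None = None) -> str:
    """Scree listing: rank, eigenvalue, variance fraction, cumulative fraction."""
    frac = model.explained_variance_ratio
    cum = np.cumsum(frac)
    rows = ["rank\teigenvalue_A2\tfraction\tcumulative"]
    n = len(frac) if max_rows is None else min(max_rows, len(frac))
    for i in range(n):
        rows.append(f"{i + 1}\t{model.eigenvalues[i]:.6g}\t{frac[i]:.6f}\t{cum[i]:.6f}")
    return "\n".join(rows) + "\n"


def project(data, model: SubstateModel, dims=None, selection=None,
            align: bool = True) -> np.ndarray:
    """Project frames onto principal components.

    ``data`` is either a :class:`TrajectoryEnsemble` (converted with the same
    selection/alignment used for the covariance) or an already-built
    (n_frames, 3N) coordinate matrix.  ``dims`` lists 0-based component
    indices (default: all).  Projecting onto all components and reconstructing
    recovers the centered coordinates; the variance along component m equals
    its eigenvalue (for ddof matching the covariance).
    """
    if isinstance(data, TrajectoryEnsemble):
        X = coordinate_matrix(data, selection, align=align)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[-1] != model.mean.shape[0]:
        raise ValueError("coordinate dimension does not match the model")
    if dims is None:
        dims = np.arange(model.eigenvectors.shape[1])
    dims = np.asarray(dims, dtype=int)
    if dims.size and (dims.min() < 0 or dims.max() >= model.eigenvectors.shape[1]):
        raise ValueError("requested component outside the kept range")
    return (X - model.mean) @ model.eigenvectors[:, dims]


def cluster_substates(projections: np.ndarray, k: int,
                      seed: int = DEFAULT_SEED,
                      n_restarts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """KMeans (Lloyd) clustering of frame projections into k substates.

    Runs ``n_restarts`` seeded restarts and keeps the lowest within-cluster
    sum of squares; deterministic given ``seed``.  Returns (labels, centers).
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > P.shape[0]:
        raise ValueError(f"k={k} exceeds the number of frames ({P.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(P)
    return km.labels_.astype(int), km.cluster_centers_


def centroid_frames(projections: np.ndarray, labels: np.ndarray,
                    centers: np.ndarray) -> np.ndarray:
    """Representative frame per cluster: member nearest its centroid.

    Ties resolve to the lowest frame index.  Returns an array of length k.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    labels = np.asarray(labels, dtype=int)
    centers = np.asarray(centers, dtype=float)
    out = np.empty(len(centers), dtype=int)
    for c in range(len(centers)):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} has no members")
        d = np.linalg.norm(P[members] - centers[c], axis=1)
        out[c] = members[int(np.argmin(d))]  # argmin returns the first minimum
    return out


def choose_dims(eigenvalues, method: str = "threshold", param: float = 0.9) -> int:
    """Number of components to keep, from the scree.

    ``method="threshold"``: smallest m whose cumulative variance fraction
    reaches ``param`` (restricted to nonzero eigenvalues, so ``param=1.0``
    keeps exactly the nonzero spectrum).  ``method="elbow"``: index of maximum
    curvature (discrete second difference) of the eigenvalue curve.  Both are
    deterministic.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    if vals.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    tol = 1e-12 * max(vals.max(), 1.0)
    n_nonzero = max(1, int(np.sum(vals > tol)))
    if method == "threshold":
        total = vals.sum()
        if total <= 0:
            return 1
        cum = np.cumsum(vals) / total
        m = int(np.argmax(cum >= param - 1e-12)) + 1
        return min(m, n_nonzero)
    if method == "elbow":
        if len(vals) < 3:
            return n_nonzero if len(vals) < 2 else 1
        d2 = vals[:-2] - 2.0 * vals[1:-1] + vals[2:]
        return int(np.argmax(d2)) + 1
    raise ValueError(f"unknown method {method!r}")


def silhouette_scan(projections: np.ndarray, k_values=range(2, 11),
                    seed: int = DEFAULT_SEED) -> dict[int, float]:
    """Silhouette score per candidate k — guidance only, not an automatic choice."""
    P = np.asarray(projections, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    out = {}
    for k in k_values:
        if k < 2 or k >= P.shape[0]:
            continue
        labels, _ = cluster_substates(P, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        out[int(k)] = float(silhouette_score(P, labels))
    return out


def find_substates(traj: TrajectoryEnsemble, selection=None, k: int = 4,
                   seed: int = DEFAULT_SEED, dims: int | None = None,
                   align: bool = True, ddof: int = 0,
                   project_first: int | None = None) -> SubstateModel:
    """End-to-end pipeline: covariance -> PCA -> projection -> KMeans -> centroids.

    ``dims`` fixes the number of kept components (default: scree threshold at
    90% cumulative variance).  ``project_first`` clusters on only the first
    that-many components (e.g. 2 for strict 2D-projection clustering) instead
    of all kept dims.
    """
    cov = covariance(traj, selection, align=align, ddof=ddof)
    model = pca(cov)
    kept = dims if dims is not None else choose_dims(model.eigenvalues)
    kept = max(kept, 1)
    X = coordinate_matrix(traj, selection, align=align)
    proj = project(X, model, dims=np.arange(kept))
    cluster_input = proj[:, :project_first] if project_first else proj
    labels, centers = cluster_substates(cluster_input, k, seed=seed)
    reps = centroid_frames(cluster_input, labels, centers)
    return replace(model, projections=proj, cluster_labels=labels,
                   cluster_centers=centers, centroid_frames=reps, kept_dims=kept)
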