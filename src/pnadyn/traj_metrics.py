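"""Per-frame analyses on selected atoms of a coordinate trajectory.

Superposed RMSD against a reference frame, RMSF against windowed average
coordinates, hydrogen-bond occupancy under a distance + linearity criterion,
and signed backbone dihedral distributions.  Analyses are typically restricted
to the backbone atoms of the central base pairs of a duplex, since terminal
pairs fray.

All metrics are invariant under a global rigid transformation applied to every
frame (superposition removes rigid-body motion; distances, angles and
dihedrals are rigid invariants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import AtomRecord, StructureModel

__all__ = [
    "TrajectoryEnsemble",
    "AtomSelection",
    "HBondCriterion",
    "SuperpositionResult",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "hbond_occupancy",
    "dihedral",
    "dihedral_series",
    "torsion_histogram",
]


@dataclass
class TrajectoryEnsemble:
    """Frames x atoms x 3 coordinates (Angstrom) plus per-atom metadata."""

    coords: np.ndarray
    atoms: list[AtomRecord]
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[1] != len(self.atoms):
            raise ValueError("coords atom dimension does not match atom metadata")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinate in trajectory")
        self.coords = c

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_models(cls, models: Sequence[StructureModel]) -> "TrajectoryEnsemble":
        """Stack a multi-model structure (e.g. NMR ensemble) into a trajectory."""
        if not models:
            raise ValueError("no models")
        coords = np.stack([m.coords for m in models])
        return cls(coords=coords, atoms=list(models[0].atoms))

    def to_models(self) -> list[StructureModel]:
        out = []
        for i in range(self.n_frames):
            atoms = [
                AtomRecord(
                    atom_name=a.atom_name, residue_name=a.residue_name,
                    residue_index=a.residue_index, element=a.element,
                    coordinates=tuple(self.coords[i, j]),
                    chain_id=a.chain_id, insertion_code=a.insertion_code,
                )
                for j, a in enumerate(self.atoms)
            ]
            out.append(StructureModel(atoms=atoms, model_id=i + 1))
        return out

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class AtomSelection:
    """A resolved, deterministic list of atom indices with a readable label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def select(cls, atoms: Sequence[AtomRecord],
               atom_names: Sequence[str] | None = None,
               residue_indices: Sequence[int] | None = None,
               residue_names: Sequence[str] | None = None,
               predicate: Callable[[AtomRecord], bool] | None = None,
               label: str = "") -> "AtomSelection":
        """Select atoms by name / 1-based residue index / residue name / predicate."""
        names = set(atom_names) if atom_names is not None else None
        resids = set(int(r) for r in residue_indices) if residue_indices is not None else None
        resnames = set(residue_names) if residue_names is not None else None
        idx = []
        for i, a in enumerate(atoms):
            if names is not None and a.atom_name not in names:
                continue
            if resids is not None and a.residue_index not in resids:
                continue
            if resnames is not None and a.residue_name not in resnames:
                continue
            if predicate is not None and not predicate(a):
                continue
            idx.append(i)
        return cls(indices=tuple(idx), label=label)


def _resolve(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    if isinstance(selection, AtomSelection):
        idx = np.asarray(selection.indices, dtype=int)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise ValueError("selection index out of range")
    return idx


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    A frame counts for a (donor D, hydrogen H, acceptor A) triple iff the D-A
    distance is <= ``distance_cutoff`` (Angstrom) and the D-H-A angle is
    within ``linearity_deviation`` degrees of linearity, i.e.
    angle(D-H-A) >= 180 - deviation.  Note the angle is measured *at the
    hydrogen* (D-H-A), not the H-D-A angle some tools use.
    """

    distance_cutoff: float = 3.5
    linearity_deviation: float = 30.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not (0.0 < self.linearity_deviation < 90.0):
            raise ValueError("linearity_deviation must lie in (0, 90)")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float              # Angstrom, over the fit selection, post-fit


def _check_not_collinear(pts: np.ndarray, what: str) -> None:
    if len(pts) < 3:
        raise ValueError(f"{what}: need at least 3 atoms for superposition")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError(f"{what}: selected atoms are collinear or degenerate")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection=None) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch) of mobile onto reference.

    The rotation/translation minimize the RMSD over the selected atoms; the
    returned RMSD is the post-fit value over that selection.  A proper
    rotation (det = +1) is always returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    idx = _resolve(selection, mobile.shape[0])
    m, r = mobile[idx], reference[idx]
    _check_not_collinear(m, "mobile")
    _check_not_collinear(r, "reference")
    mu_m, mu_r = m.mean(axis=0), r.mean(axis=0)
    rot, _ = Rotation.align_vectors(r - mu_r, m - mu_m)
    R = rot.as_matrix()
    t = mu_r - R @ mu_m
    # recompute the residual directly; the rssd returned by align_vectors
    # carries O(1e-8) cancellation noise near a perfect fit
    d = (m - mu_m) @ R.T - (r - mu_r)
    rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid transform to a full (n_atoms, 3) frame."""
    return coords @ result.rotation.T + result.translation


def rmsd_series(traj: TrajectoryEnsemble, reference_frame_index: int = 0,
                selection=None, fit: bool = True) -> np.ndarray:
    """Per-frame RMSD (Angstrom) over the selection against a reference frame.

    Each frame is superposed onto the reference over the selection first
    (``fit=False`` gives the raw, unfitted RMSD).  The series is zero at the
    reference frame.
    """
    if not (0 <= reference_frame_index < traj.n_frames):
        raise ValueError("reference frame index out of range")
    idx = _resolve(selection, traj.n_atoms)
    ref = traj.coords[reference_frame_index]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        if fit:
            out[i] = superpose(traj.coords[i], ref, idx).rmsd
        else:
            d = traj.coords[i][idx] - ref[idx]
            out[i] = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return out


def _window_frames(traj: TrajectoryEnsemble, window) -> np.ndarray:
    if window is None:
        frames = np.arange(traj.n_frames)
    elif isinstance(window, slice):
        frames = np.arange(traj.n_frames)[window]
    else:
        start, stop = window
        frames = np.arange(traj.n_frames)[start:stop]
    if frames.size == 0:
        raise ValueError("empty frame window")
    return frames


def rmsf(traj: TrajectoryEnsemble, selection=None, window=None,
         align: bool = True) -> np.ndarray:
    """Per-atom RMS fluctuation (Angstrom) about windowed mean coordinates.

    Frames in the window are superposed onto their running-average structure
    (first onto the window's first frame, then once more onto the resulting
    mean — one iteration); the RMSF of each selected atom is the RMS deviation
    from the final mean coordinates.  ``align=False`` skips superposition for
    trajectories already free of rigid-body motion.
    """
    idx = _resolve(selection, traj.n_atoms)
    frames = _window_frames(traj, window)
    sub = traj.coords[frames][:, idx, :]
    if align:
        ref = sub[0]
        aligned = np.stack([
            apply_transform(f, superpose(f, ref)) for f in sub
        ])
        mean1 = aligned.mean(axis=0)
        aligned = np.stack([
            apply_transform(f, superpose(f, mean1)) for f in sub
        ])
        sub = aligned
    mean = sub.mean(axis=0)
    dev = sub - mean
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def hbond_occupancy(traj: TrajectoryEnsemble,
                    donors: Sequence[tuple[int, int]],
                    acceptors: Sequence[int],
                    criterion: HBondCriterion = HBondCriterion()) -> np.ndarray:
    """Fraction of frames each (donor, acceptor) pair is hydrogen bonded.

    ``donors`` are (donor-heavy-atom, bonded-hydrogen) index pairs;
    ``acceptors`` are acceptor atom indices.  Returns an array of shape
    (n_donors, n_acceptors) with values in [0, 1]; occupancy is monotone
    non-decreasing in both the distance cutoff and the allowed angular
    deviation.
    """
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        raise ValueError("donor and acceptor lists must be non-empty")
    d_idx = np.asarray([d for d, _ in donors], dtype=int)
    h_idx = np.asarray([h for _, h in donors], dtype=int)
    a_idx = np.asarray(acceptors, dtype=int)
    for arr in (d_idx, h_idx, a_idx):
        _resolve(arr, traj.n_atoms)

    D = traj.coords[:, d_idx]  # (F, nd, 3)
    H = traj.coords[:, h_idx]
    A = traj.coords[:, a_idx]  # (F, na, 3)

    diff_da = D[:, :, None, :] - A[:, None, :, :]
    dist = np.linalg.norm(diff_da, axis=-1)  # (F, nd, na)

    hd = D - H                                # (F, nd, 3)
    ha = A[:, None, :, :] - H[:, :, None, :]  # (F, nd, na, 3)
    cos = np.einsum("fdx,fdax->fda", hd, ha)
    norm = np.linalg.norm(hd, axis=-1)[:, :, None] * np.linalg.norm(ha, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norm > 0, cos / norm, 1.0)
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))

    bonded = (dist <= criterion.distance_cutoff) & (
        angle >= 180.0 - criterion.linearity_deviation
    )
    return bonded.mean(axis=0)


def dihedral(p: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees) of point quadruples of shape (..., 4, 3).

    IUPAC convention: cis = 0, positive clockwise viewed from the first atom
    along the central bond; range (-180, 180].
    """
    p = np.asarray(p, dtype=float)
    b1 = p[..., 1, :] - p[..., 0, :]
    b2 = p[..., 2, :] - p[..., 1, :]
    b3 = p[..., 3, :] - p[..., 2, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(b2n, n1)  # cross order sets the IUPAC sign
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral_series(traj: TrajectoryEnsemble,
                    four_atoms: Sequence[int]) -> np.ndarray:
    """Per-frame signed dihedral (degrees, in (-180, 180]) of four atoms."""
    four = [int(i) for i in four_atoms]
    if len(four) != 4 or len(set(four)) != 4:
        raise ValueError("four distinct atom indices are required")
    _resolve(four, traj.n_atoms)
    return dihedral(traj.coords[:, four, :])


def torsion_histogram(series, bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Probability per torsion bin over (-180, 180].

    ``bin_width`` (degrees) must divide 360.  Returns (probabilities, edges);
    probabilities sum to 1.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty torsion series")
    nbins = 360.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    edges = -180.0 + bin_width * np.arange(int(round(nbins)) + 1)
    counts, _ = np.histogram(series, bins=edges)
    return counts / series.size, edges
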