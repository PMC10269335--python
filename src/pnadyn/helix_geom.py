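"""Helical bend of a duplex from base-pair-plane normals.

Standard helicoidal-parameter programs are built around the sugar-phosphate
backbone and do not directly measure bending of peptide-nucleic-acid duplexes,
so the bend is estimated geometrically: for each of two designated base pairs
(typically the second and the second-to-last pair, away from fraying termini)
a plane is fitted through the N1 and N3 ring nitrogens of both bases, and the
bend is the angle between the two plane normals, folded to [0, 90] degrees
because a plane normal's sign is arbitrary.

The reading of "the normal vectors for the geometric centers of N1 and N3" as
a best-fit plane normal is one of two defensible interpretations; the
alternative — the unit vector joining the per-base N1/N3 midpoints — is
available as ``mode="midpoint"`` for sensitivity analysis.  Plane-normal is
the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AtomRecord, StructureModel
from .traj_metrics import TrajectoryEnsemble

__all__ = [
    "BasePairSpec",
    "BendSeries",
    "pair_plane_normal",
    "helical_bend",
    "bend_series",
]


@dataclass(frozen=True)
class BasePairSpec:
    """A base pair named by its two residue indices plus per-base anchor atoms."""

    strand1_res: int
    strand2_res: int
    anchor_atoms: tuple[str, str] = ("N1", "N3")

    def __post_init__(self) -> None:
        if self.strand1_res == self.strand2_res:
            raise ValueError("base-pair residues must be distinct")
        if len(self.anchor_atoms) < 2:
            raise ValueError("at least two anchor atom names are required")


def _atoms_of(structure) -> tuple[Sequence[AtomRecord], np.ndarray]:
    if isinstance(structure, StructureModel):
        return structure.atoms, structure.coords
    atoms, coords = structure
    return atoms, np.asarray(coords, dtype=float)


def anchor_indices(atoms: Sequence[AtomRecord], pair: BasePairSpec) -> list[int]:
    """Indices of the anchor atoms (all anchors of residue 1, then residue 2)."""
    out = []
    for res in (pair.strand1_res, pair.strand2_res):
        for name in pair.anchor_atoms:
            hits = [i for i, a in enumerate(atoms)
                    if a.residue_index == res and a.atom_name == name]
            if not hits:
                raise ValueError(f"anchor atom {name!r} not found in residue {res}")
            out.append(hits[0])
    return out


def _plane_normal(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("anchor atoms are collinear; no unique plane")
    normal = vt[2]
    i = int(np.argmax(np.abs(normal)))
    if normal[i] < 0:  # deterministic sign
        normal = -normal
    return normal / np.linalg.norm(normal), centroid


def _midpoint_axis(pts: np.ndarray, n_anchors: int) -> tuple[np.ndarray, np.ndarray]:
    m1 = pts[:n_anchors].mean(axis=0)
    m2 = pts[n_anchors:].mean(axis=0)
    vec = m2 - m1
    norm = np.linalg.norm(vec)
    if norm <= 1e-10:
        raise ValueError("base midpoints coincide; no unique axis")
    return vec / norm, (m1 + m2) / 2.0


def pair_plane_normal(structure, pair: BasePairSpec,
                      mode: str = "plane") -> tuple[np.ndarray, np.ndarray]:
    """Unit normal (or midpoint axis) and centroid of one base pair.

    ``mode="plane"``: normal of the least-squares plane through the anchor
    atoms (the smallest-variance principal direction of the points).
    ``mode="midpoint"``: unit vector between the per-base anchor midpoints.
    Rigid motion of the structure rotates the returned vector accordingly
    (up to sign).
    """
    atoms, coords = _atoms_of(structure)
    idx = anchor_indices(atoms, pair)
    pts = coords[idx]
    if mode == "plane":
        return _plane_normal(pts)
    if mode == "midpoint":
        return _midpoint_axis(pts, len(pair.anchor_atoms))
    raise ValueError(f"unknown mode {mode!r}")


def helical_bend(structure, pair_a: BasePairSpec, pair_b: BasePairSpec,
                 mode: str = "plane") -> float:
    """Angle (degrees, folded to [0, 90]) between two base-pair plane normals.

    Folding is required because plane normals carry no sign; the result is
    invariant under global rigid motion and under swapping the two pairs.
    """
    na, _ = pair_plane_normal(structure, pair_a, mode=mode)
    nb, _ = pair_plane_normal(structure, pair_b, mode=mode)
    c = abs(float(np.dot(na, nb)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


@dataclass(frozen=True)
class BendSeries:
    """Per-frame helical bend plus its summary statistics."""

    angles: np.ndarray  # degrees, one per frame
    mean: float
    sd: float  # sample standard deviation (ddof=1); 0 for a single frame


def bend_series(traj: TrajectoryEnsemble, pair_a: BasePairSpec,
                pair_b: BasePairSpec, mode: str = "plane") -> BendSeries:
    """Helical bend per frame of a trajectory, with mean and sample SD."""
    angles = np.array([
        helical_bend((traj.atoms, traj.coords[i]), pair_a, pair_b, mode=mode)
        for i in range(traj.n_frames)
    ])
    sd = float(np.std(angles, ddof=1)) if len(angles) > 1 else 0.0
    return BendSeries(angles=angles, mean=float(angles.mean()), sd=sd)
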