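"""Synthetic data with known ground truth for every analysis in the toolkit.

Three generators:

* :func:`synth_scan` — torsional-scan pairs (target, baseline) built from a
  planted dihedral series on top of a smooth baseline, with optional Gaussian
  noise, for fit-recovery tests.
* :func:`build_duplex` — an idealized two-strand duplex of rigid pseudo-bases
  on a helical axis with controllable rise, twist and programmed bend, and
  satisfiable Watson-Crick-like hydrogen-bond geometry (donor-acceptor 2.9
  Angstrom, linear).
* :func:`build_trajectory` — frame ensembles around that duplex with thermal
  noise and scripted perturbation events (hydrogen-bond breaking, basin
  shifts) whose schedule is returned as ground truth.

Pseudo-bases are rigid 6-atom templates (ring nitrogens N1/N3, a backbone
anchor C1, and one donor triplet ND/HD plus acceptor OA) — enough geometry for
superposition, hydrogen-bond, torsion, PCA and bend analyses without modelling
real nucleobase chemistry.  The programmed bend is defined as the angle
between the base-pair planes of the second and second-to-last pairs, the pairs
the bend estimator reads.  Every generator is deterministic under a fixed
seed; the default thermal noise is isotropic Gaussian of 0.1 Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dihedral_fit import DihedralSeries, EnergyProfile, ScanSpec
from .helix_geom import BasePairSpec
from .io_formats import AtomRecord, StructureModel
from .traj_metrics import TrajectoryEnsemble

__all__ = [
    "DuplexRecipe",
    "SynthScan",
    "BreakHBond",
    "ShiftBasin",
    "synth_scan",
    "build_duplex",
    "build_trajectory",
    "wc_pair",
    "wc_hbond_triplets",
    "backbone_selection_indices",
    "synthetic_nmr_ensemble",
]

# Rigid strand-1 base template in the local base-pair frame (z = 0 plane).
# The strand-2 base is the same template rotated 180 degrees about z, which
# places its acceptor OA 2.9 Angstrom from — and collinear with — the partner
# ND-HD donor, so each pair carries two satisfiable near-linear H-bonds.
_BASE_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("N1", "N", (-2.4, 0.4, 0.0)),
    ("N3", "N", (-1.0, 2.0, 0.0)),
    ("C1", "C", (-4.5, 0.0, 0.0)),
    ("ND", "N", (-1.45, 0.5, 0.0)),
    ("HD", "H", (-0.45, 0.5, 0.0)),
    ("OA", "O", (-1.45, -0.5, 0.0)),
)
ATOMS_PER_BASE = len(_BASE_TEMPLATE)


@dataclass(frozen=True)
class DuplexRecipe:
    """Construction parameters for an idealized pseudo-duplex.

    ``programmed_bend`` (degrees) is applied as a smooth axis curvature and
    equals the angle between the base-pair planes of the second and
    second-to-last pairs.  ``noise_sd`` is isotropic Gaussian positional noise
    (Angstrom) applied per structure/frame.
    """

    n_base_pairs: int = 8
    rise: float = 3.2
    twist: float = 20.0
    programmed_bend: float = 0.0
    noise_sd: float = 0.1
    seed: int = 2023

    def __post_init__(self) -> None:
        if self.n_base_pairs < 4:
            raise ValueError("need at least 4 base pairs")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP = _rot_z(180.0)  # strand-2 base placement within the pair


def _pair_tilt(recipe: DuplexRecipe, i: int) -> float:
    # Linear tilt profile normalized so pairs 1 and n-2 (0-based; the second
    # and second-to-last) differ by exactly programmed_bend.
    return recipe.programmed_bend * (i - 1) / (recipe.n_base_pairs - 3)


def _ideal_coords(recipe: DuplexRecipe) -> tuple[list[AtomRecord], np.ndarray]:
    n = recipe.n_base_pairs
    template = np.array([xyz for _, _, xyz in _BASE_TEMPLATE])
    strand1: list[tuple[AtomRecord, np.ndarray]] = []
    strand2: list[tuple[AtomRecord, np.ndarray]] = []
    pos = np.zeros(3)
    for i in range(n):
        tilt = _pair_tilt(recipe, i)
        R = _rot_y(tilt) @ _rot_z(recipe.twist * i)
        if i > 0:
            pos = pos + recipe.rise * (_rot_y(tilt) @ np.array([0.0, 0.0, 1.0]))
        for (name, element, _), local in zip(_BASE_TEMPLATE, template):
            strand1.append((
                AtomRecord(atom_name=name, residue_name="PNB",
                           residue_index=i + 1, element=element,
                           coordinates=(0.0, 0.0, 0.0), chain_id="A"),
                pos + R @ local,
            ))
        for (name, element, _), local in zip(_BASE_TEMPLATE, template):
            strand2.append((
                AtomRecord(atom_name=name, residue_name="PNB",
                           residue_index=2 * n - i, element=element,
                           coordinates=(0.0, 0.0, 0.0), chain_id="B"),
                pos + R @ (_FLIP @ local),
            ))
    # strand 1 ascending, then strand 2 ascending residue index
    strand2.sort(key=lambda pair: pair[0].residue_index)
    records = [a for a, _ in strand1] + [a for a, _ in strand2]
    coords = np.array([c for _, c in strand1] + [c for _, c in strand2])
    return records, coords


def _with_coords(records: Sequence[AtomRecord], coords: np.ndarray,
                 model_id: int = 1) -> StructureModel:
    atoms = [
        AtomRecord(atom_name=a.atom_name, residue_name=a.residue_name,
                   residue_index=a.residue_index, element=a.element,
                   coordinates=tuple(coords[i]), chain_id=a.chain_id,
                   insertion_code=a.insertion_code)
        for i, a in enumerate(records)
    ]
    return StructureModel(atoms=atoms, model_id=model_id)


def build_duplex(recipe: DuplexRecipe, rng: np.random.Generator | None = None,
                 model_id: int = 1) -> StructureModel:
    """Build one idealized duplex structure from a recipe.

    Residues 1..n are strand 1, n+1..2n strand 2; pair i (0-based) joins
    residues (i+1, 2n-i), so for an 8-pair duplex the second and
    second-to-last pairs are residues 2/15 and 7/10.  Atom count is
    ``n_base_pairs * 2 * 6``.
    """
    rng = rng if rng is not None else np.random.default_rng(recipe.seed)
    records, coords = _ideal_coords(recipe)
    if recipe.noise_sd > 0:
        coords = coords + rng.normal(0.0, recipe.noise_sd, coords.shape)
    return _with_coords(records, coords, model_id=model_id)


def wc_pair(recipe: DuplexRecipe, pair_index: int,
            anchor_atoms: tuple[str, str] = ("N1", "N3")) -> BasePairSpec:
    """BasePairSpec for pair ``pair_index`` (0-based along strand 1)."""
    n = recipe.n_base_pairs
    if not (0 <= pair_index < n):
        raise ValueError("pair index out of range")
    return BasePairSpec(strand1_res=pair_index + 1, strand2_res=2 * n - pair_index,
                        anchor_atoms=anchor_atoms)


def _atom_index(atoms: Sequence[AtomRecord], residue_index: int, name: str) -> int:
    for i, a in enumerate(atoms):
        if a.residue_index == residue_index and a.atom_name == name:
            return i
    raise ValueError(f"atom {name!r} of residue {residue_index} not found")


def wc_hbond_triplets(atoms: Sequence[AtomRecord],
                      pair: BasePairSpec) -> list[tuple[tuple[int, int], int]]:
    """The two bonded ((donor, hydrogen), acceptor) index triples of a pair."""
    r1, r2 = pair.strand1_res, pair.strand2_res
    return [
        ((_atom_index(atoms, r1, "ND"), _atom_index(atoms, r1, "HD")),
         _atom_index(atoms, r2, "OA")),
        ((_atom_index(atoms, r2, "ND"), _atom_index(atoms, r2, "HD")),
         _atom_index(atoms, r1, "OA")),
    ]


def backbone_selection_indices(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Indices of the pseudo-backbone anchor atoms (C1 of every residue)."""
    return np.array([i for i, a in enumerate(atoms) if a.atom_name == "C1"], dtype=int)


# ---------------------------------------------------------------------------
# trajectory events


@dataclass(frozen=True)
class BreakHBond:
    """Move a pair's acceptor atoms away from their donors for a frame range.

    Frames ``start <= f < stop`` have both OA atoms of the pair displaced by
    ``displacement`` Angstrom along the donor-to-acceptor direction, pushing
    the donor-acceptor distance beyond the 3.5 Angstrom criterion.
    """

    pair_index: int
    start: int
    stop: int
    displacement: float = 2.0


@dataclass(frozen=True)
class ShiftBasin:
    """Displace every strand-2 atom by ``vector`` for a frame range.

    The shift is an internal deformation (it survives rigid-body alignment),
    creating a separable basin in principal-component space.  Basin ground
    truth labels each such event 1, 2, ... in order; unshifted frames are 0.
    """

    start: int
    stop: int
    vector: tuple[float, float, float]


def build_trajectory(recipe: DuplexRecipe, n_frames: int,
                     events: Sequence[BreakHBond | ShiftBasin] = ()
                     ) -> tuple[TrajectoryEnsemble, dict]:
    """Frame ensemble: ideal duplex + scripted events + thermal noise.

    Returns the trajectory and a ground-truth dict with ``basin_labels``
    (int per frame), ``broken`` (pair_index -> bool per frame) and
    ``programmed_bend``.
    """
    records, ideal = _ideal_coords(recipe)
    n = recipe.n_base_pairs
    rng = np.random.default_rng(recipe.seed)
    for ev in events:
        if not (0 <= ev.start <= ev.stop <= n_frames):
            raise ValueError(f"event frame range [{ev.start}, {ev.stop}) out of bounds")
        if isinstance(ev, BreakHBond) and not (0 <= ev.pair_index < n):
            raise ValueError("event pair index out of range")

    strand2_mask = np.array([a.residue_index > n for a in records])
    basin_labels = np.zeros(n_frames, dtype=int)
    broken: dict[int, np.ndarray] = {}
    shift_ordinal = 0
    frame_offsets = np.zeros((n_frames, len(records), 3))

    for ev in events:
        if isinstance(ev, ShiftBasin):
            shift_ordinal += 1
            frame_offsets[ev.start:ev.stop, strand2_mask, :] += np.asarray(ev.vector)
            basin_labels[ev.start:ev.stop] = shift_ordinal
        else:
            pair = wc_pair(recipe, ev.pair_index)
            flags = broken.setdefault(ev.pair_index, np.zeros(n_frames, dtype=bool))
            flags[ev.start:ev.stop] = True
            for (d_idx, _), a_idx in wc_hbond_triplets(records, pair):
                direction = ideal[a_idx] - ideal[d_idx]
                direction = direction / np.linalg.norm(direction)
                frame_offsets[ev.start:ev.stop, a_idx, :] += ev.displacement * direction

    coords = ideal[None, :, :] + frame_offsets
    if recipe.noise_sd > 0:
        coords = coords + rng.normal(0.0, recipe.noise_sd, coords.shape)
    traj = TrajectoryEnsemble(coords=coords, atoms=list(records))
    truth = {
        "basin_labels": basin_labels,
        "broken": broken,
        "programmed_bend": recipe.programmed_bend,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# torsional scans


@dataclass(frozen=True)
class SynthScan:
    """A synthetic target/baseline scan pair with its planted series."""

    target: EnergyProfile
    baseline: EnergyProfile
    truth: DihedralSeries


def _default_baseline(angles: np.ndarray) -> np.ndarray:
    # smooth, non-trivial MM-like baseline; deliberately not in the default
    # fitting basis (offsets 40 and -25 degrees)
    a = np.radians(angles)
    return (1.1 * (1.0 + np.cos(a - np.radians(40.0)))
            + 0.45 * (1.0 + np.cos(2.0 * a + np.radians(25.0))))


def synth_scan(series: DihedralSeries,
               baseline_shape: Callable[[np.ndarray], np.ndarray] | None = None,
               noise_sd: float = 0.0, seed: int = 0,
               grid: ScanSpec | None = None) -> SynthScan:
    """Target/baseline scan profiles with a planted torsion series.

    ``target = baseline + series (+ Gaussian noise of sd noise_sd)``, both
    min-shifted on construction.  The planted series is returned as ground
    truth for recovery tests; an empty series makes target identical to
    baseline (up to noise).  Bitwise reproducible for a fixed seed.
    """
    grid = grid if grid is not None else ScanSpec()
    angles = grid.grid()
    shape = baseline_shape if baseline_shape is not None else _default_baseline
    base_raw = np.asarray(shape(angles), dtype=float)
    target_raw = base_raw + series.energy(angles)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        target_raw = target_raw + rng.normal(0.0, noise_sd, angles.shape)
    return SynthScan(
        target=EnergyProfile(angles, target_raw),
        baseline=EnergyProfile(angles, base_raw),
        truth=series,
    )


# ---------------------------------------------------------------------------
# synthetic multi-model ensemble


def synthetic_nmr_ensemble(n_models: int = 11, mean_bend: float = 23.2,
                           bend_sd: float = 0.94, seed: int = 2023,
                           recipe: DuplexRecipe | None = None
                           ) -> tuple[list[StructureModel], np.ndarray]:
    """Synthetic stand-in for a multi-model solution-NMR duplex ensemble.

    This is *not* real deposition data: it builds ``n_models`` idealized
    8-base-pair pseudo-duplexes whose per-model programmed bends are drawn
    from N(mean_bend, bend_sd), emulating an ensemble whose reported helical
    bend is ``mean_bend +/- bend_sd`` degrees.  Returns the models (model_id
    1..n) and the programmed per-model bends as ground truth.
    """
    base = recipe if recipe is not None else DuplexRecipe(noise_sd=0.02, seed=seed)
    rng = np.random.default_rng(seed)
    bends = rng.normal(mean_bend, bend_sd, n_models)
    models = []
    for m, bend in enumerate(bends, start=1):
        r = DuplexRecipe(n_base_pairs=base.n_base_pairs, rise=base.rise,
                         twist=base.twist, programmed_bend=float(bend),
                         noise_sd=base.noise_sd, seed=base.seed + m)
        models.append(build_duplex(r, rng=rng, model_id=m))
    return models, bends


def ground_truth_json(truth: dict) -> str:
    """Serialize a ground-truth dict (from :func:`build_trajectory`) to JSON."""
    def convert(value):
        if isinstance(value, np.ndarray):
            return value.tolist()
        if isinstance(value, dict):
            return {str(k): convert(v) for k, v in value.items()}
        return value

    return json.dumps({k: convert(v) for k, v in truth.items()}, indent=1)
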