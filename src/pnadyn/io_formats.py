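"""Readers and writers for the external formats the toolkit touches.

Multi-model PDB (v3 fixed columns), delimited torsional-scan tables, charge
tables and CHARMM parameter-stream DIHEDRALS stanzas.  All other modules
consume only the in-memory domain types defined here and in their own modules;
nothing downstream re-parses text.

Conventions: residue indexing follows the file (1-based); PDB coordinates are
read and written at the standard 8.3 precision with occupancy/B-factor ignored
on read and written as 1.00/0.00; scan-table angles are wrapped to [0, 360)
degrees on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np

from .charges import ChargeSet
from .dihedral_fit import DihedralSeries, DihedralTerm, EnergyProfile

__all__ = [
    "AtomRecord",
    "StructureModel",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "load_scan_columns",
    "read_scan_table",
    "write_scan_table",
    "read_charge_table",
    "write_charge_table",
    "read_parameter_stream",
    "write_parameter_stream",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, residue, element and coordinates (Angstrom)."""

    atom_name: str
    residue_name: str
    residue_index: int
    element: str
    coordinates: tuple[float, float, float]
    chain_id: str = ""
    insertion_code: str = ""

    def __post_init__(self) -> None:
        xyz = tuple(float(v) for v in self.coordinates)
        if len(xyz) != 3 or not all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.atom_name!r}: coordinates must be a finite 3-vector")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.atom_name!r}: residue_index must be >= 1")
        object.__setattr__(self, "coordinates", xyz)


@dataclass
class StructureModel:
    """An ordered list of atoms for one model of a (possibly multi-model) file."""

    atoms: list[AtomRecord]
    model_id: int = 1

    @cached_property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_multimodel_pdb(path) -> list[StructureModel]:
    """Parse a PDB file into one :class:`StructureModel` per MODEL block.

    Files without MODEL records yield exactly one model.  Atom names are
    whitespace-stripped; insertion codes and chain identifiers are preserved.
    All models must have the same atom count and ordering (same atom name,
    residue name and residue index at every position) or a ``ValueError``
    naming the offending model is raised; an unparseable coordinate field
    raises with the line number.
    """
    path = Path(path)
    models: list[StructureModel] = []
    atoms: list[AtomRecord] = []
    model_id: int | None = None
    saw_model_record = False

    def close(mid: int) -> None:
        nonlocal atoms
        if atoms:
            models.append(StructureModel(atoms=atoms, model_id=mid))
        atoms = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if saw_model_record:
                    close(model_id)
                saw_model_record = True
                try:
                    model_id = int(line[6:].split()[0])
                except (IndexError, ValueError):
                    model_id = len(models) + 1
            elif rec == "ENDMDL":
                close(model_id if model_id is not None else len(models) + 1)
                model_id = None
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ValueError(
                        f"{path.name}: unparseable coordinate field on line {lineno}"
                    ) from exc
                try:
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise ValueError(
                        f"{path.name}: unparseable residue number on line {lineno}"
                    ) from exc
                name = line[12:16].strip()
                element = line[76:78].strip() if len(line) >= 78 else ""
                atoms.append(AtomRecord(
                    atom_name=name,
                    residue_name=line[17:20].strip(),
                    residue_index=resseq,
                    element=element or _guess_element(name),
                    coordinates=(x, y, z),
                    chain_id=line[21].strip() if len(line) > 21 else "",
                    insertion_code=line[26].strip() if len(line) > 26 else "",
                ))
    if atoms:  # trailing atoms (no ENDMDL, or file without MODEL records)
        close(model_id if model_id is not None else len(models) + 1)
    if not models:
        raise ValueError(f"{path.name}: no ATOM/HETATM records found")

    first = models[0]
    for model in models[1:]:
        if len(model) != len(first):
            raise ValueError(
                f"{path.name}: model {model.model_id} has {len(model)} atoms "
                f"but model {first.model_id} has {len(first)}"
            )
        for i, (a, b) in enumerate(zip(first.atoms, model.atoms)):
            if (a.atom_name, a.residue_name, a.residue_index) != (
                    b.atom_name, b.residue_name, b.residue_index):
                raise ValueError(
                    f"{path.name}: model {model.model_id} atom ordering differs "
                    f"from model {first.model_id} at atom {i + 1}"
                )
    return models


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names shorter than 4 characters start in column 14.
    return name if len(name) >= 4 else f" {name:<3s}"


def write_multimodel_pdb(models: Sequence[StructureModel], path) -> None:
    """Write models as a multi-model PDB (8.3 coordinates, occ 1.00, B 0.00)."""
    if not models:
        raise ValueError("no models to write")
    with open(path, "w") as fh:
        for model in models:
            fh.write(f"MODEL     {model.model_id:4d}\n")
            for serial, a in enumerate(model.atoms, start=1):
                x, y, z = a.coordinates
                fh.write(
                    f"ATOM  {serial:>5d} {_format_atom_name(a.atom_name)} "
                    f"{a.residue_name:>3s} {(a.chain_id or 'A'):1s}"
                    f"{a.residue_index:>4d}{(a.insertion_code or ' '):1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# delimited scan tables


_COMMENT_PREFIXES = ("#", "!", ";")


def load_scan_columns(path) -> tuple[np.ndarray, np.ndarray]:
    """Read the raw (angle, energy) columns of a scan table, unwrapped.

    Use this form (with both 0 and 360 endpoints intact) to feed
    :func:`pnadyn.dihedral_fit.check_scan_periodicity`; use
    :func:`read_scan_table` for the wrapped, validated profile.
    """
    path = Path(path)
    angles: list[float] = []
    energies: list[float] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith(_COMMENT_PREFIXES):
                continue
            parts = re.split(r"[,\t ]+", s)
            if len(parts) < 2:
                raise ValueError(f"{path.name}: line {lineno}: expected at least 2 columns")
            try:
                a, e = float(parts[0]), float(parts[1])
            except ValueError:
                if first_data_line:  # tolerate a single header line
                    first_data_line = False
                    continue
                raise ValueError(
                    f"{path.name}: line {lineno}: non-numeric cell"
                ) from None
            first_data_line = False
            angles.append(a)
            energies.append(e)
    return np.asarray(angles, dtype=float), np.asarray(energies, dtype=float)


def read_scan_table(path) -> EnergyProfile:
    """Read a two-column scan table into an :class:`EnergyProfile`.

    Angles are wrapped to [0, 360) and sorted ascending.  A 360-degree row
    that wraps onto an existing 0-degree row with the same energy is the
    periodic endpoint and is dropped; any other duplicate angle is a hard
    error (a nonperiodic raw scan should go through
    :func:`pnadyn.dihedral_fit.check_scan_periodicity` on
    :func:`load_scan_columns` output instead).
    """
    path = Path(path)
    angles, energies = load_scan_columns(path)
    if angles.size == 0:
        raise ValueError(f"{path.name}: no data rows")
    wrapped = np.round(angles, 9) % 360.0
    order = np.argsort(wrapped, kind="stable")
    wrapped, energies = wrapped[order], energies[order]
    keep_a: list[float] = []
    keep_e: list[float] = []
    for a, e in zip(wrapped, energies):
        if keep_a and abs(a - keep_a[-1]) < 1e-9:
            if abs(e - keep_e[-1]) <= 1e-9:
                continue  # periodic endpoint (e.g. 360 wrapped onto 0)
            raise ValueError(
                f"{path.name}: duplicate angle {a:g} with differing energies "
                f"({keep_e[-1]:g} vs {e:g})"
            )
        keep_a.append(float(a))
        keep_e.append(float(e))
    return EnergyProfile(np.asarray(keep_a), np.asarray(keep_e))


def write_scan_table(profile: EnergyProfile, path) -> None:
    """Write a profile as TSV (full float precision; round-trip exact)."""
    with open(path, "w") as fh:
        fh.write("# angle_deg\tenergy_kcal_mol\n")
        for a, e in zip(profile.angles, profile.energies):
            fh.write(f"{float(a)!r}\t{float(e)!r}\n")


# ---------------------------------------------------------------------------
# charge tables


def read_charge_table(path, group_id: str = "") -> ChargeSet:
    """Read a TSV/CSV table of (atom_name, charge in e) into a ChargeSet."""
    path = Path(path)
    entries: dict[str, float] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith(_COMMENT_PREFIXES):
                continue
            parts = re.split(r"[,\t ]+", s)
            if len(parts) < 2:
                raise ValueError(f"{path.name}: line {lineno}: expected atom_name and charge")
            name = parts[0]
            try:
                q = float(parts[1])
            except ValueError:
                if first_data_line:
                    first_data_line = False
                    continue
                raise ValueError(f"{path.name}: line {lineno}: non-numeric charge") from None
            first_data_line = False
            if name in entries:
                raise ValueError(f"{path.name}: line {lineno}: duplicate atom {name!r}")
            entries[name] = q
    return ChargeSet(entries=entries, group_id=group_id or path.stem)


def write_charge_table(charge_set: ChargeSet, path, decimals: int | None = None) -> None:
    """Write a ChargeSet as TSV.

    ``decimals=None`` (default) writes shortest-repr full precision so a
    write/read round trip is the identity; pass ``decimals=2`` for
    CHARMM-convention output.
    """
    with open(path, "w") as fh:
        fh.write("# atom_name\tcharge_e\n")
        for name, q in charge_set.entries.items():
            text = f"{float(q)!r}" if decimals is None else f"{q:.{decimals}f}"
            fh.write(f"{name}\t{text}\n")


# ---------------------------------------------------------------------------
# CHARMM parameter stream (DIHEDRALS stanza)


def write_parameter_stream(series: DihedralSeries, atom_types: Sequence[str],
                           path, title: str = "torsion parameters") -> None:
    """Write a DIHEDRALS stanza in CHARMM parameter-stream dialect.

    One line per term: four atom types, k_chi (kcal/mol, 4 decimals),
    multiplicity (integer), offset (degrees, 2 decimals).  The file is
    re-readable bit-exactly by :func:`read_parameter_stream` for parameters
    at that precision.
    """
    if len(series) == 0:
        raise ValueError("cannot write an empty dihedral series")
    types = tuple(str(t) for t in atom_types)
    if len(types) != 4 or any(not t.strip() for t in types):
        raise ValueError("atom_types must be four non-blank type names")
    for term in series:
        if term.multiplicity <= 0:
            raise ValueError("multiplicity must be positive")
        if not (-180.0 <= term.offset < 360.0):
            raise ValueError("offset outside [-180, 360)")
    with open(path, "w") as fh:
        fh.write(f"* {title}\n*\n\n")
        fh.write("DIHEDRALS\n")
        for term in series:
            fh.write(
                f"{types[0]:<6s} {types[1]:<6s} {types[2]:<6s} {types[3]:<6s} "
                f"{term.force_constant:10.4f} {term.multiplicity:2d} {term.offset:8.2f}\n"
            )
        fh.write("END\n\nRETURN\n")


def read_parameter_stream(path) -> tuple[DihedralSeries, tuple[str, ...]]:
    """Read a DIHEDRALS stanza written by :func:`write_parameter_stream`."""
    path = Path(path)
    terms: list[DihedralTerm] = []
    types: tuple[str, ...] | None = None
    in_stanza = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("*") or s.startswith(_COMMENT_PREFIXES):
                continue
            upper = s.upper()
            if upper == "DIHEDRALS":
                in_stanza = True
                continue
            if upper in ("END", "RETURN"):
                in_stanza = False
                continue
            if not in_stanza:
                continue
            parts = s.split()
            if len(parts) != 7:
                raise ValueError(f"{path.name}: line {lineno}: malformed DIHEDRALS line")
            line_types = tuple(parts[:4])
            if types is None:
                types = line_types
            elif line_types != types:
                raise ValueError(
                    f"{path.name}: line {lineno}: mixed atom-type quadruples in one stanza"
                )
            terms.append(DihedralTerm(
                force_constant=float(parts[4]),
                multiplicity=int(parts[5]),
                offset=float(parts[6]),
            ))
    if types is None or not terms:
        raise ValueError(f"{path.name}: no DIHEDRALS stanza found")
    return DihedralSeries(tuple(terms)), types
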