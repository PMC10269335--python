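"""CHARMM-style periodic torsion model and potential-energy-surface fitting.

The torsional energy of a single dihedral is modelled as a truncated Fourier
series

    E(phi) = sum_terms  k_chi * (1 + cos(n * phi - delta))

with force constants ``k_chi`` (kcal/mol), integer multiplicities ``n`` and
phase offsets ``delta`` (degrees).  Target data is a relative torsional energy
profile (for instance a quantum-mechanical scan), the baseline is the
molecular-mechanics profile with the fitted dihedral's own contribution absent
or frozen, and the fit minimizes an offset-invariant pairwise error between
``baseline + series`` and the target.

Relative energy profiles are only defined up to an additive constant, so the
fitting objective must not depend on where either profile puts its zero.  The
pairwise error used here is the RMS, over all unordered point pairs (i, j), of
``(model_i - model_j) - (target_i - target_j)``, which is invariant to adding
a constant to either profile.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DihedralTerm",
    "DihedralSeries",
    "EnergyProfile",
    "ScanSpec",
    "PeriodicityReport",
    "FitReport",
    "dihedral_energy",
    "profile_from_series",
    "check_scan_periodicity",
    "pairwise_error",
    "fit_series",
    "fit_report_table",
    "parse_fit_report",
]

#: Default multiplicities considered by the fit (standard CHARMM practice).
DEFAULT_MULTIPLICITIES = (1, 2, 3, 6)
#: Default phase offsets; k_chi >= 0 with delta in {0, 180} absorbs the sign.
DEFAULT_OFFSETS = (0.0, 180.0)


@dataclass(frozen=True)
class DihedralTerm:
    """One periodic torsion term ``k_chi * (1 + cos(n*phi - delta))``.

    Parameters
    ----------
    force_constant : float
        Amplitude ``k_chi`` in kcal/mol; must be finite and >= 0.
    multiplicity : int
        Periodicity ``n``; a positive integer (1..6 by default policy).
    offset : float
        Phase ``delta`` in degrees, in [-180, 360).
    """

    force_constant: float
    multiplicity: int
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.force_constant) or self.force_constant < 0:
            raise ValueError(f"force_constant must be finite and >= 0, got {self.force_constant}")
        if int(self.multiplicity) != self.multiplicity or self.multiplicity < 1:
            raise ValueError(f"multiplicity must be a positive integer, got {self.multiplicity}")
        if not (-180.0 <= self.offset < 360.0):
            raise ValueError(f"offset must lie in [-180, 360), got {self.offset}")

    def energy(self, phi_deg):
        """Energy (kcal/mol) of this term at dihedral angle(s) ``phi_deg``."""
        phi = np.asarray(phi_deg, dtype=float)
        return self.force_constant * (
            1.0 + np.cos(np.radians(self.multiplicity * phi - self.offset))
        )


@dataclass(frozen=True)
class DihedralSeries:
    """A sum of :class:`DihedralTerm`; no two terms may share (n, delta)."""

    terms: tuple[DihedralTerm, ...] = ()

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        object.__setattr__(self, "terms", terms)
        keys = [(t.multiplicity, t.offset) for t in terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (multiplicity, offset) pair in series")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[DihedralTerm]:
        return iter(self.terms)

    def energy(self, phi_deg):
        """Total series energy at ``phi_deg`` (degrees); 0 for an empty series."""
        phi = np.asarray(phi_deg, dtype=float)
        out = np.zeros_like(phi)
        for term in self.terms:
            out = out + term.energy(phi)
        return out if out.shape else float(out)


def dihedral_energy(phi_deg, series: DihedralSeries):
    """Evaluate ``E(phi) = sum k_chi (1 + cos(n phi - delta))`` in kcal/mol.

    Total function: periodic with period ``360 / gcd(multiplicities)`` and
    everywhere >= 0 for non-negative force constants.
    """
    return series.energy(phi_deg)


@dataclass(frozen=True)
class EnergyProfile:
    """Ordered relative torsional-scan samples.

    ``angles`` are degrees, strictly increasing in [0, 360); ``energies`` are
    kcal/mol and are shifted on construction so the minimum is exactly 0
    (relative energetics).  At least 3 points are required.
    """

    angles: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        ene = np.asarray(self.energies, dtype=float)
        if ang.ndim != 1 or ene.shape != ang.shape:
            raise ValueError("angles and energies must be 1-D arrays of equal length")
        if len(ang) < 3:
            raise ValueError("an energy profile needs at least 3 points")
        if not (np.all(np.isfinite(ang)) and np.all(np.isfinite(ene))):
            raise ValueError("non-finite value in profile")
        if np.any(ang < 0) or np.any(ang >= 360.0):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "energies", ene - ene.min())

    def __len__(self) -> int:
        return len(self.angles)

    def same_grid(self, other: "EnergyProfile", tol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.angles, other.angles, atol=tol)
        )


@dataclass(frozen=True)
class ScanSpec:
    """Dihedral scan grid: every ``step`` degrees from ``start`` to ``stop``.

    ``restraint_k`` records the harmonic restraint (kcal/mol/radian^2) applied
    to the scanned torsion during the restrained minimizations that produced
    the profile; it is provenance metadata only — no MM energies are evaluated
    here.  ``direction`` records forward vs backward scanning (the backward
    re-scan is the remedy when a forward scan ends in a different, lower
    conformer and the profile comes out nonperiodic).
    """

    start: float = 0.0
    stop: float = 360.0
    step: float = 15.0
    direction: str = "forward"
    restraint_k: float = 1.0e4

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        span = self.stop - self.start
        if span <= 0:
            raise ValueError("stop must exceed start")
        n = span / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide (stop - start)")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.restraint_k <= 0:
            raise ValueError("restraint_k must be positive")

    def grid(self) -> np.ndarray:
        """Unique scan angles wrapped to [0, 360), ascending (endpoint deduplicated)."""
        n = int(round((self.stop - self.start) / self.step))
        raw = self.start + self.step * np.arange(n + 1)
        return np.unique(np.round(raw, 9) % 360.0)

    def raw_angles(self) -> np.ndarray:
        """The scan angles in scan order, unwrapped (includes both endpoints)."""
        n = int(round((self.stop - self.start) / self.step))
        ang = self.start + self.step * np.arange(n + 1)
        return ang[::-1] if self.direction == "backward" else ang


def profile_from_series(series: DihedralSeries, grid) -> EnergyProfile:
    """Evaluate a series on a scan grid and return the min-shifted profile.

    ``grid`` may be a :class:`ScanSpec` or an array of angles in degrees
    (wrapped to [0, 360) and deduplicated).
    """
    if isinstance(grid, ScanSpec):
        angles = grid.grid()
    else:
        angles = np.unique(np.round(np.asarray(grid, dtype=float), 9) % 360.0)
    if angles.size == 0:
        raise ValueError("empty scan grid")
    return EnergyProfile(angles, series.energy(angles))


@dataclass(frozen=True)
class PeriodicityReport:
    """Outcome of the 0-vs-360 degree endpoint check on a raw scan."""

    gap: float
    periodic: bool
    rescan_backward_recommended: bool


def check_scan_periodicity(angles, energies, tol: float = 0.1) -> PeriodicityReport:
    """Check whether a raw (unwrapped) scan closes on itself.

    A forward scan that relaxes into a different, lower-energy conformer by
    360 degrees yields ``E(360) != E(0)``; the remedy is to re-scan backward
    from 360 to 0 starting from the ending geometry.  ``angles``/``energies``
    are the raw scan columns *before* wrapping (both the 0 and 360 endpoints
    must be present); the gap is ``|E(0) - E(360)|`` and the scan is flagged
    nonperiodic when the gap exceeds ``tol`` (kcal/mol).
    """
    ang = np.asarray(angles, dtype=float)
    ene = np.asarray(energies, dtype=float)
    at0 = np.isclose(ang, 0.0, atol=1e-6)
    at360 = np.isclose(ang, 360.0, atol=1e-6)
    if not (at0.any() and at360.any()):
        raise ValueError("scan must cover both the 0 and 360 degree endpoints")
    gap = float(abs(ene[at0][0] - ene[at360][0]))
    periodic = gap <= tol
    return PeriodicityReport(gap=gap, periodic=periodic,
                             rescan_backward_recommended=not periodic)


def _pairwise_rms_from_residual(d: np.ndarray) -> float:
    # RMS over unordered pairs of (d_i - d_j); uses the identity
    # sum_{i<j} (d_i - d_j)^2 = n*sum(d^2) - (sum d)^2, applied to the
    # mean-centered residual (pair differences are unchanged by the shift,
    # and centering avoids catastrophic cancellation when d carries a large
    # constant offset).
    n = len(d)
    d = d - d.mean()
    num = n * float(np.dot(d, d)) - float(np.sum(d)) ** 2
    pairs = n * (n - 1) / 2.0
    return math.sqrt(max(num, 0.0) / pairs)


def pairwise_error(model: EnergyProfile, target: EnergyProfile,
                   method: str = "pairwise") -> float:
    """Discrepancy (kcal/mol) between two profiles on an identical grid.

    ``method="pairwise"`` (default): RMS over all unordered point pairs of
    ``(model_i - model_j) - (target_i - target_j)``; symmetric in its
    arguments and invariant to adding a constant to either profile.
    ``method="min_aligned"``: plain RMSD after both profiles are shifted to a
    zero minimum (provided for comparison; sensitive to where the minima sit).
    """
    if not model.same_grid(target):
        raise ValueError("profiles are on different angle grids")
    d = model.energies - target.energies
    if method == "pairwise":
        return _pairwise_rms_from_residual(d)
    if method == "min_aligned":
        return float(np.sqrt(np.mean(d * d)))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class FitReport:
    """Bookkeeping for one fit: errors before/after, iterations, convergence."""

    initial_error: float
    final_error: float
    iterations: int
    converged: bool
    tol: float
    method: str
    #: full (multiplicity, offset, k_chi) table over the allowed basis,
    #: including zero amplitudes.
    coefficients: tuple[tuple[int, float, float], ...] = field(default_factory=tuple)


def _basis(angles: np.ndarray, allowed_n: Sequence[int],
           allowed_delta: Sequence[float]) -> tuple[list[tuple[int, float]], np.ndarray]:
    keys = sorted({(int(n), float(d)) for n in allowed_n for d in allowed_delta})
    cols = [np.cos(np.radians(n * angles - d)) for n, d in keys]
    return keys, np.column_stack(cols)


def fit_series(target: EnergyProfile, baseline: EnergyProfile,
               allowed_n: Iterable[int] = DEFAULT_MULTIPLICITIES,
               allowed_delta: Iterable[float] = DEFAULT_OFFSETS,
               tol: float = 0.2, method: str = "lstsq",
               max_iter: int = 10_000) -> tuple[DihedralSeries, FitReport]:
    """Fit torsion terms so that ``baseline + series`` matches ``target``.

    The fit minimizes :func:`pairwise_error` over non-negative force constants
    on the basis ``cos(n*phi - delta)`` for the allowed multiplicities and
    offsets.  Because the pairwise error is offset-invariant, this reduces to
    non-negative least squares on mean-centered columns.

    ``method="lstsq"`` (default) solves the non-negative least-squares problem
    directly, then polishes with coordinate descent; ``method="scalar"``
    starts from zero amplitudes and refines one force constant at a time (the
    iterative amplitude-tuning mode).  Convergence means the final pairwise
    error is <= ``tol`` (kcal/mol; 0.2 by default).  Non-convergence is
    reported in the :class:`FitReport`, never raised.
    """
    if not target.same_grid(baseline):
        raise ValueError("target and baseline are on different angle grids")
    allowed_n = tuple(allowed_n)
    if not allowed_n:
        raise ValueError("allowed_n must not be empty")
    allowed_delta = tuple(allowed_delta)
    if method not in ("lstsq", "scalar"):
        raise ValueError(f"unknown fit method {method!r}")

    keys, B = _basis(target.angles, allowed_n, allowed_delta)
    npts, m = B.shape
    if npts <= m:
        raise ValueError(
            f"scan grid has {npts} points for {m} basis functions; "
            "the fit would be underdetermined"
        )

    r = target.energies - baseline.energies
    Bc = B - B.mean(axis=0)
    rc = r - r.mean()

    initial = _pairwise_rms_from_residual(r)

    if method == "lstsq":
        k, _ = nnls(Bc, rc)
        iterations = 1
    else:
        k = np.zeros(m)
        iterations = 0

    # Coordinate-descent refinement of each k_chi with the others held fixed
    # (closed-form 1-D non-negative least squares per coordinate).
    col_sq = np.einsum("ij,ij->j", Bc, Bc)
    resid = rc - Bc @ k
    for _ in range(max_iter):
        biggest = 0.0
        for j in range(m):
            if col_sq[j] == 0.0:
                continue
            kj_new = max(0.0, k[j] + float(Bc[:, j] @ resid) / col_sq[j])
            change = kj_new - k[j]
            if change != 0.0:
                resid = resid - change * Bc[:, j]
                k[j] = kj_new
                biggest = max(biggest, abs(change))
        iterations += 1
        if biggest < 1e-12:
            break

    final = _pairwise_rms_from_residual(r - B @ k)
    terms = tuple(
        DihedralTerm(force_constant=float(kj), multiplicity=n, offset=d)
        for (n, d), kj in zip(keys, k) if kj > 1e-12
    )
    report = FitReport(
        initial_error=float(initial), final_error=float(final),
        iterations=iterations, converged=bool(final <= tol),
        tol=float(tol), method=method,
        coefficients=tuple((n, d, float(kj)) for (n, d), kj in zip(keys, k)),
    )
    return DihedralSeries(terms), report


def fit_report_table(report: FitReport) -> str:
    """Render a :class:`FitReport` as deterministic, re-parseable text."""
    lines = [
        "torsion fit report",
        f"method: {report.method}",
        f"initial pairwise error (kcal/mol): {report.initial_error:.2f}",
        f"final pairwise error (kcal/mol): {report.final_error:.2f}",
        f"iterations: {report.iterations}",
        f"converged: {'yes' if report.converged else 'no'} (tol {report.tol:.2f} kcal/mol)",
        "terms (n, delta_deg, k_chi_kcal_mol):",
    ]
    nonzero = [(n, d, k) for n, d, k in report.coefficients if k > 1e-12]
    if not nonzero:
        lines.append("  no terms")
    else:
        for n, d, k in nonzero:
            lines.append(f"  {n:d}  {d:7.2f}  {k:.4f}")
    return "\n".join(lines) + "\n"


_REPORT_RE: dict[str, Callable[[str], object]] = {
    "method": str,
    "initial pairwise error (kcal/mol)": float,
    "final pairwise error (kcal/mol)": float,
    "iterations": int,
}


def parse_fit_report(text: str) -> dict:
    """Parse :func:`fit_report_table` output back into its fields."""
    out: dict = {"terms": []}
    in_terms = False
    for line in text.splitlines():
        line = line.rstrip()
        if line.startswith("terms"):
            in_terms = True
            continue
        if in_terms:
            s = line.strip()
            if s and s != "no terms":
                n, d, k = s.split()
                out["terms"].append((int(n), float(d), float(k)))
            continue
        m = re.match(r"^(.*): (.*)$", line)
        if not m:
            continue
        key, value = m.group(1), m.group(2)
        if key in _REPORT_RE:
            out[key.split(" (")[0].replace(" ", "_")] = _REPORT_RE[key](value)
        elif key == "converged":
            out["converged"] = value.startswith("yes")
            out["tol"] = float(re.search(r"tol ([\d.]+)", value).group(1))
    return out
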