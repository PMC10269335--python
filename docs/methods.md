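# Methods

## Torsion energy model and fitting

A dihedral's energy is the CHARMM periodic form

    E(φ) = Σ_terms  k_χ (1 + cos(n φ − δ)),

with force constants `k_χ ≥ 0` (kcal/mol), integer multiplicities `n`
(1–6 by default policy) and offsets `δ` (degrees). Non-negative `k_χ` with
`δ ∈ {0°, 180°}` is the standard CHARMM convention — the 180° offset absorbs
the sign a negative amplitude would otherwise carry. The default fitting
basis is therefore multiplicities {1, 2, 3, 6} × offsets {0°, 180°}; both
sets are configurable.

**Target and baseline.** The fit consumes two relative energy profiles on an
identical angle grid: the target (typically a quantum-mechanical dihedral
scan) and a molecular-mechanics baseline in which the fitted dihedral's own
contribution is absent or frozen. The baseline is an *input*: reproducing
restrained MM minimizations requires a complete force field and is out of
scope. `ScanSpec` records the scan protocol (grid, direction, and the
harmonic restraint constant, default 1e4 kcal/mol/radian², applied to the
scanned torsion during the minimizations) as provenance metadata only.

**Scan periodicity.** A relaxed forward scan can end at 360° in a different,
lower-energy conformer than it started in at 0°; the profile then fails to
close on itself. `check_scan_periodicity` measures the 0°/360° gap on the
raw (unwrapped) scan columns and, when the gap exceeds the tolerance, flags
the standard remedy: re-scan backward from 360° to 0° starting from the
ending geometry. The table reader wraps angles to [0°, 360°) and treats an
equal-energy 0°/360° collision as the periodic endpoint (deduplicated); a
differing-energy collision is a hard error so a nonperiodic scan cannot be
silently folded.

**Pairwise error.** Relative energy profiles are defined only up to an
additive constant, so the objective is the RMS over all unordered point
pairs (i, j) of `(model_i − model_j) − (target_i − target_j)`. This is
symmetric, non-negative, zero iff the two profiles differ by a constant, and
invariant to shifting either profile. It is evaluated through the identity
`Σ_{i<j}(d_i − d_j)² = n Σd² − (Σd)²` applied to the mean-centered residual
(centering avoids catastrophic cancellation when the residual carries a
large constant). A plain RMSD-after-min-alignment variant is available via
`method="min_aligned"` for comparison; it is sensitive to where each
profile's minimum sits and is not used by the fit.

**Fit.** Offset invariance reduces the problem to non-negative least
squares on mean-centered basis columns `cos(nφ − δ)`. The default method
solves that NNLS problem directly and polishes with coordinate descent; a
`scalar` mode starts from zero and tunes one amplitude at a time
(closed-form 1-D non-negative updates), mirroring iterative amplitude
refinement. Convergence means final pairwise error ≤ 0.2 kcal/mol by
default; non-convergence is reported in the `FitReport`, never silently
accepted (iteration cap 10 000). A grid with no more points than basis
functions is a hard error rather than an underdetermined fit. Terms whose
fitted amplitude is ≤ 1e-12 are dropped from the returned series; the full
coefficient table is kept in the report.

Planted-parameter recovery characterizes the fit: on 24-point, 15° grids
the noise-free fit is exact to machine precision, and at 0.05 kcal/mol
Gaussian noise the amplitude standard error is ≈ σ·√(2/n_points) ≈ 0.014
kcal/mol, far inside the 0.2 kcal/mol convergence band.

## Charge edits

When a substituent replaces a hydrogen on the γ-carbon, the displaced
hydrogen's +0.09 e is folded onto the carbon (`aggregate_hydrogen_charge`;
net charge conserved exactly, e.g. −0.02 e → +0.07 e), and the residue is
returned to its target net charge by adjusting one designated atom
(`repair_neutrality`; e.g. N2′ absorbing −0.03 e to reach −0.36 e). Both
edits are exact arithmetic on the charge table (sums via `math.fsum`) and
idempotent. A terminal methyl group with net zero charge is expressed as
`repair_neutrality` on the methyl atoms with target 0. Charges are carried
at full input precision; rounding (CHARMM's 2-decimal convention) happens
only at file-write time when requested — the default writer emits shortest
round-trip representations so write/read is the identity.

## Trajectory metrics

All analyses operate on `TrajectoryEnsemble` (frames × atoms × 3, Å, plus
per-atom metadata) with deterministic, 1-based residue selections. Duplex
analyses are normally restricted to the backbone atoms of the central base
pairs (for an 8+8 duplex, residues 2–7 and 10–15), since terminal pairs
fray; the selection is configuration, not hard-coded, and the precise
backbone atom-name list is left to the caller.

* **Superposition** is least-squares rigid-body (Kabsch, via scipy's
  rotational alignment), proper rotations only; the RMSD is recomputed from
  the fitted residuals because the library's reported residual carries
  ~1e-8 cancellation noise near perfect fits. Fewer than 3 selected atoms,
  or a collinear selection, is an error.
* **RMSD series** superposes each frame onto a chosen reference frame over
  the selection (a `fit=False` flag gives raw RMSD); **RMSF** superposes the
  windowed frames onto their running-average structure (align to the first
  window frame, average, re-align to that mean once) and reports per-atom
  RMS deviation from the final mean. `align=False` supports trajectories
  already free of rigid-body motion, where the two-point oscillation closed
  form holds exactly.
* **Hydrogen bonds**: a (D, H, A) triple is bonded in a frame iff
  dist(D, A) ≤ 3.5 Å and angle(D–H–A) ≥ 150°, i.e. within 30° of linearity
  measured *at the hydrogen* — note some tools measure H–D–A instead.
  Occupancy is the bonded-frame fraction, monotone in both cutoffs.
* **Torsions** use the standard atan2 construction with the IUPAC sign
  convention (cis = 0, positive clockwise viewed from the first atom), range
  (−180°, 180°]. An IUPAC torsion is symmetric under atom-order reversal
  and antisymmetric under mirror reflection; the implementation is
  cross-checked against an independent projection-based derivation and
  against MDAnalysis. Histograms cover (−180°, 180°] with a bin width that
  must divide 360°; interior bin edges follow numpy's left-closed rule.

## Conformational substates

Frames are rigid-body aligned (default: onto the first frame over the
analysis selection — alignment is mandatory by default because rigid-body
variance otherwise dominates the covariance), and the 3N Cartesian
coordinates of the N selected atoms form the sample vectors of the
covariance `c_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩`, normalized by 1/n by
default with a `ddof` switch for the sample convention. Eigenvalues are
reported descending with variance fractions (scree table); eigenvector signs
are fixed by making the largest-magnitude component positive so degenerate
spectra still reproduce. Dimensionality is chosen from the scree either by
cumulative-variance threshold (default 0.9) or by the maximum-curvature
(second-difference) elbow.

Clustering is scikit-learn KMeans (Lloyd) with 10 seeded restarts keeping
the lowest within-cluster sum of squares; `k` is user-specified (a
silhouette scan over k = 2…10 is provided as guidance only). The default
clusters on all kept components; a `project_first=2` mode reproduces strict
2D-projection clustering. Each substate's representative structure is the
member frame whose projection is nearest the cluster centroid, ties
resolving to the lowest frame index. The default master seed is 2023.

## Helical bend

For each designated base pair (by default the second and second-to-last,
e.g. G2–C15 and C7–G10 on an 8+8 duplex) a least-squares plane is fitted
through the N1 and N3 ring nitrogens of both bases (smallest-variance
principal direction of the four points); the bend is the angle between the
two plane normals folded to [0°, 90°], since plane normals carry no sign —
consistent with duplex bends in the 6–23° range. "Normal vectors of the
N1/N3 geometric centers" admits a second reading — the unit vector joining
the per-base N1/N3 midpoints — which is provided as `mode="midpoint"` for
sensitivity analysis; plane-normal is the default. Anchor atoms are matched
by deposited name with no renaming heuristics. Per-frame series report mean
and sample (ddof = 1) standard deviation.

A four-point plane fit is noise-sensitive: 0.02 Å isotropic coordinate
noise propagates to roughly 0.6° of bend for the fixture geometry, which
sets the tolerances the recovery tests use (per-model 2.5° ≈ 4σ; noise-free
recovery is exact to ≪ 1°).

## Synthetic fixtures

The generators emulate just enough structure for ground-truth validation:

* `synth_scan` plants a known torsion series on a smooth baseline
  (deliberately outside the default fitting basis) with optional Gaussian
  noise.
* `build_duplex` places rigid 6-atom pseudo-bases (N1, N3, backbone anchor
  C1, donor triplet ND/HD and acceptor OA) pairwise on a helical axis —
  default 8 base pairs, rise 3.2 Å, twist 20°/step, P-form-like values —
  with the programmed bend applied as a smooth axis curvature normalized so
  the second and second-to-last pair planes differ by exactly the programmed
  angle. Every pair carries two exactly linear 2.9 Å donor–acceptor
  contacts. Strand 1 is residues 1…n, strand 2 is n+1…2n with pair i
  joining residues (i+1, 2n−i).
* `build_trajectory` adds per-frame isotropic Gaussian thermal noise
  (default 0.1 Å) and scripted events: `BreakHBond` pushes a pair's
  acceptors 2 Å along the donor→acceptor direction for a frame range
  (occupancy margins ≈ 10σ at 0.02 Å noise, so scheduled fractions are
  recovered exactly; at the default 0.1 Å the hydrogen-bond geometry
  flickers by a few percent, which is realistic but not exact-count), and
  `ShiftBasin` displaces all strand-2 atoms by a fixed vector — an internal
  deformation that survives alignment and creates separable
  principal-component basins. The event schedule is returned as ground
  truth.
* `synthetic_nmr_ensemble` is a synthetic stand-in (not deposition data)
  for a multi-model NMR duplex ensemble: per-model programmed bends drawn
  from N(23.2°, 0.94°) at 0.02 Å coordinate noise, so the bend pipeline can
  be validated against an ensemble whose reported statistics it should
  recover.

What the fixtures do **not** model: real nucleobase chemistry and
stacking, sequence-dependent geometry, solvent, force-field dynamics,
anisotropic or correlated thermal motion, and conformer transitions that are
not step functions. Passing the recovery suites therefore demonstrates the
*estimators* are correct on data with known truth, not that any particular
real duplex behaves a given way.

All generators are deterministic under a fixed seed; every stochastic step
takes an explicit seed.

## Problem sizes and numerical choices

Fit-recovery suites use 50 planted single-term series on 24-point grids;
substate recovery uses 400 frames of an 8-base-pair duplex (96 atoms, 288
coordinates); occupancy and bend fixtures use 60–100 frames. Key tolerances:
basis amplitudes below 1e-12 are treated as zero; eigenvector orthonormality
is checked at 1e-8; covariance trace equals the eigenvalue sum to 1e-10;
PDB coordinates round-trip at the format's 1e-3 Å precision; parameter
streams round-trip exactly at their written precision (k_χ 4 decimals,
δ 2 decimals).

## Known limitations

* No MM energy evaluation: the baseline profile must be produced externally.
* The multi-model PDB path is the portable trajectory format; binary
  trajectory formats are not read.
* The bend estimator assumes the four anchor atoms are resolvable by name
  and non-collinear; it reports magnitude only (no major/minor-groove bend
  direction).
* KMeans substates inherit KMeans' bias toward blocky, similar-sized
  clusters; k is a user decision.
* Occupancies are plain frame fractions; no autocorrelation or error
  estimate is attached.
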