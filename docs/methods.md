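# Methods

This note documents the models and conventions behind each module, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer would want recorded.

## Reactivity panel

Given frontier-orbital energies ε_H < ε_L of one molecule, the panel is the
standard conceptual-DFT set evaluated by Koopmans-style finite differences:
gap = ε_L − ε_H, ionization potential I = −ε_H, electron affinity
A = −ε_L, chemical potential μ = (ε_L + ε_H)/2, hardness η = gap/2,
softness S = 1/(2η), electronegativity χ = −μ, electrophilicity
ω = μ²/(2η), and the electron-acceptor/donor powers

    ω⁺ = (I + 3A)² / (16 (I − A)),   ω⁻ = (3I + A)² / (16 (I − A)),

with net electrophilicity Δω± = ω⁺ + ω⁻. The ω± formulas follow the
standard acceptor/donor convention (ω⁻ ≥ ω⁺ ≥ 0 whenever I > A > 0); some
typeset sources state them with ε_L and ε_H swapped, which interchanges the
two powers — the convention here is the one consistent with the reference
descriptor table shipped in `flavodesc/data/`.

All outputs carry the unit of the inputs; conversions use
1 hartree = 627.5095 kcal/mol and 1 eV = 23.0609 kcal/mol, applied once at
I/O boundaries. Full double precision is kept internally; serialization
rounds to 3 decimals.

Two quirks of the reference table are handled explicitly:

* **Softness convention.** The physical S = 1/(2η) in (kcal/mol)⁻¹ is of
  order 10⁻². The reference table's softness row instead equals
  627.5095²/gap to ~3×10⁻⁵ relative — an inverse gap computed in hartree
  and then "converted" to kcal/mol as if it were an energy. Both values are
  exposed (`softness`, `softness_table`) so the table remains auditable
  without propagating the unit mishandling. The residual ~3×10⁻⁵
  discrepancy suggests the original conversion constant differed slightly;
  the audit tolerance is 10⁻³ relative.
* **One typo cell.** The ω⁻ entry of 3′ME5S prints identically to its ω⁺
  (21.140) and is inconsistent with the same column's printed
  Δω± = 120.609 (which implies ω⁻ ≈ 99.469, matching the recomputation).
  It is excluded from golden comparisons; the exclusion is itself tested.

## PCA similarity

Descriptor matrices are column-standardized (mean 0; nonconstant columns
scaled to unit **population** variance, ddof = 0 — the convention sklearn's
scalers use; constant columns become zero with a warning). PCA is sklearn's
full-SVD solver with a deterministic sign convention: the
largest-magnitude loading of each component is made positive. Similarity is
Euclidean distance in the retained score space, 2 components by default to
match the planar similarity map being reproduced; the softness columns are
excluded from the reference run because of the unit inconsistency above
(configurable). Which descriptors entered the original analysis is not
stated in the source; the fixture choice (the ten energy-valued
descriptors) is documented here, not asserted as the original's.

## MMGBSA bookkeeping

The three-trajectory end-point estimate: for each component
c ∈ {E_internal, E_ele, E_vdw, G_GB, G_SA},
Δc = mean_complex(c) − mean_receptor(c) − mean_ligand(c), each mean over
that system's own frames (frame counts may differ). Then
ΔE_MM = ΔE_internal + ΔE_ele + ΔE_vdw, ΔG_sol = ΔG_GB + ΔG_SA, and
ΔG_bind = ΔE_MM + ΔG_sol. The conformational entropy term −TΔS is always
excluded, as is common MMGBSA practice; the result object carries an
explicit zero with a provenance note rather than omitting the field.
Standard errors: per component, the three per-system SEs (sd/√n, 0 for
n = 1) combined in quadrature; for ΔG_bind, the SE of each system's
per-frame component *total* combined in quadrature across systems, which is
exact when frames are independent. Inputs are parsed component tables; a
two-column `step value` log converter is provided as a convenience only.

## Trajectory analysis

Coordinates are nm internally (XYZ files are Å on disk, converted on read).
Superposition is weighted least-squares (Kabsch via SVD with the
determinant correction, so the rotation is always proper); near-collinear
references are rejected because the in-line rotation is then undefined.
RMSD series superpose each frame on a reference frame (frame 0 by default)
over the selection; a `superpose=False` mode reports raw displacement RMSD,
which is the quantity with simple closed forms for planted perturbations
(a rigid wobble of amplitude a on one of N atoms gives a|sin θ|/√N only
*without* superposition — removing the centroid alone already changes it).
Rg is mass-weighted. RMSF is the fluctuation of each atom about its
time-mean position, optionally after superposition to frame 0; residue
values are unweighted means over the residue's atoms (the aggregation used
when only per-residue flexibility is reported). Clustering is the
gromos-style neighbor-count algorithm: repeatedly seed a cluster at the
frame with the most unassigned neighbors within the RMSD cutoff (ties →
lowest frame index), remove its neighborhood; the seed frame is the
cluster representative. The 0.1 nm default cutoff matches the analysis
being reproduced; the method flag of the original clustering tool is not
stated, and neighbor-count is that tool's default.

## Promolecular NCI

The promolecular density is a sum of spherical free-atom densities, each a
short exponential fit ρ_at(r) = Σ_k c_k e^(−r/z_k) (tabulated for H, C, N,
O, S; the leading term is the core with decay length ≈ 1/(2Z), the later
terms the valence shell). These fits are a display-grade model of the
density in the low-density regions NCI analysis probes; they are not
normalized SCF densities. Gradient and Hessian are analytic; distances are
clamped at 10⁻⁶ bohr so nuclear positions stay finite. The reduced density
gradient is s = |∇ρ| / (2(3π²)^(1/3) ρ^(4/3)); λ₂ is the middle eigenvalue
of the Hessian, and voxels are classified among attractive
(sign(λ₂)ρ < −ε), repulsive (> +ε) and van der Waals (otherwise, λ₂ = 0
resolving to the weak class) within the selection rdg < 0.5 and
|ρ| ≤ 0.05 a.u., with ε = 0.005 a.u. — the customary NCI defaults, all
configurable. Published figure color bounds of order ±0.6 are display
scalings, not densities, and are not used numerically. Internal units are
atomic (bohr); grids default to the bounding box plus a 4-bohr margin and
are guarded by a voxel budget (default 4×10⁶) so a typo'd spacing fails
fast instead of allocating.

## QSAR descriptors and regression

Molecules are hydrogen-suppressed heavy-atom graphs with per-atom implicit
hydrogen counts, caller-supplied partial charges (charge models are out of
scope), and optional 3D coordinates. Published descriptor software differs
in several dialect choices; the ones taken here (each exposed as a flag
where it matters, with no bit-compatibility claim):

* **RNCG** = (most negative atomic charge)/(total negative charge), both as
  magnitudes; in (0, 1].
* **Walk counts**: raw sum of the k-th adjacency power; log10(1+count)
  variant available.
* **Broto–Moreau autocorrelation** ATS_k = Σ w_i w_j over unordered pairs
  at topological distance k (self-pairs at k = 0); ATSC centers the weights
  first; disconnected pairs are excluded.
* **E-states**: Kier–Hall intrinsic state I = ((2/N)² δv + 1)/δ with
  δ = heavy-neighbor count, δv = valence electrons − attached hydrogens,
  N = principal quantum number; field perturbation Σ (I_i − I_j)/(d+1)².
  SssCH2 sums E-states over carbons with exactly two hydrogens and two
  single bonds to heavy atoms.
* **RDF**: f(R) = Σ_{i<j} w_i w_j exp(−β(R − r_ij)²) with β = 100 Å⁻² and
  the coded radius index/10 (105 → 10.5 Å); element weights relative to
  carbon.
* **TDB** lag k: average of w_i w_j r_ij (3D Euclidean) over pairs at
  topological distance k.

Model search is exhaustive over descriptor subsets of fixed size (≤ 3),
each fit by OLS and ranked by adjusted R², with deterministic lexicographic
tie-breaking — with 3-term models exhaustiveness is cheap and reproducible,
so no stochastic (genetic) search is needed. Collinear subsets are skipped
with a warning. At n ≈ 7 molecules a 3-term fit has 3 residual degrees of
freedom and adjusted R² near 1 is expected from overfitting alone; the fit
emits a `DegreesOfFreedomWarning` in that regime rather than presenting the
statistic as evidence, and LOO Q² = 1 − PRESS/TSS (TSS about the
full-sample mean; singular folds flagged, Q² then NaN) is the validation
statistic. The published per-molecule descriptor values are not available,
so the printed adjusted-R² values are not reproduction targets; the three
published models are shipped as built-in coefficient sets for evaluation.

## Synthetic generators

All randomness flows through `numpy.random.default_rng(seed)` per call —
no global state; a given (spec, seed) is bit-reproducible, and every
generator returns its planted truth. Defaults mirror the study conditions:
7 molecules with gaps spanning 114–133 kcal/mol and HOMO energies
−162…−134 kcal/mol; MMGBSA tables planted at −26.98 kcal/mol split over
components in fixed proportions (10/30/40/15/5% for
internal/ele/vdw/GB/SA) on top of realistic-magnitude receptor/ligand
baselines, with i.i.d. Gaussian per-frame noise (σ = 1 kcal/mol, 2000
frames); 7-row, 20-descriptor linear datasets for the regression regime.
The two-state trajectory generator calibrates its conformer displacement by
bisection so the *superposed* RMSD between states equals the requested
separation exactly.

What the generators do **not** emulate: correlated MD noise (frames are
i.i.d., so real standard errors would be larger by a correlation-time
factor), force-field physics, realistic protein geometry (trajectory
"atoms" are Gaussian point clouds), or descriptor distributions of real
chemical libraries. Passing tests therefore demonstrate correctness of the
bookkeeping, estimators and closed-form behaviors — not robustness to the
autocorrelation and anharmonicity of production simulations.

## Numerical choices and problem sizes

Golden-table comparisons use ±0.001 kcal/mol (the printed precision; two
cells differ by exactly one unit in the last place because the printed
HOMO/LUMO inputs are themselves rounded). Unit-equivariance is checked at
10⁻⁹ relative, analytic derivatives against central finite differences
(h = 10⁻⁵ bohr) at 10⁻⁶ relative, closed-form RDG at 10⁻¹⁰. The
verification runs use 50 replicates × 2000 frames for binding-energy
recovery, 40–60-frame toy trajectories, and a 41×21×21 diatomic NCI grid
at 0.2 bohr — sizes chosen so the whole verification sweep completes in
seconds while keeping Monte-Carlo standard errors far below the asserted
tolerances. The MMGBSA recovery statistic is calibrated, not clipped: over
many replicates its z-scores are standard normal, so individual ~3σ draws
occur at the textbook rate and the test suite checks the distribution
rather than any single draw.

## Known limitations

* Promolecular parameters cover H, C, N, O, S only; other elements are
  rejected by name.
* The cube writer emits orthogonal voxel axes only (diagonal spacing).
* PDB support is a minimal read-only ATOM/HETATM subset for masses and
  residue indices; binary trajectory formats are out of scope.
* Descriptor dialects are documented, not harmonized with any specific
  descriptor package; cross-package numeric agreement is not claimed.
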