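# Methods

This note documents the models, conventions, defaults and limitations of
`mpakit`. All empirical numbers quoted here are ones the test suite or the
acceptance script computes.

## Spectrum assembly

Per-snapshot excited-state records (energy, oscillator strength *f*, two-
and three-photon transition strengths δ) are broadened and summed per
snapshot, then averaged over the ensemble. The arithmetic mean — not the
sum — is used so intensities are per-chromophore and independent of the
number of snapshots; a well-decorrelated ensemble then gives
N-independent peak positions and heights, which the down-sampling study
checks directly.

**Lineshape.** A unit-area Lorentzian in the energy variable,
g(x; x₀, γ) = (γ/π)/((x−x₀)² + γ²), with γ the HWHM. γ defaults to 0.1 eV
for every state, a typical choice for condensed-phase electronic bands; it
may be set per state. Gaussian/vibronic lineshapes are out of scope.

**One-photon absorption.** The molar absorption coefficient uses the
(ω/ω_i)·f_i weighting of each state. The printed forms of this expression
in the literature are typographically ambiguous between (ω/ω_i)f_i and
ω·ω_i·f_i; the ratio form is adopted because it reduces exactly to the
standard integrated-cross-section sum rule
∫σ(ν)dν = e²f/(4ε₀m_ec) at the band center, which is also the independent
oracle used in the tests (both routes give 91 376 L mol⁻¹ cm⁻¹ at the peak
for f = 1, γ = 0.1 eV, n = 1). The SI result (m²/mol) is converted to
L mol⁻¹ cm⁻¹ by the factor 10 (10⁴ cm²/m² × 10⁻³ L/cm³). The refractive
index defaults to 1.

**Multiphoton cross sections.** TPA and 3PA sums are evaluated entirely in
Hartree atomic units; the broadening argument is 2ω (3ω) so a band peaks
near ω_i/2 (ω_i/3) on the photon-energy axis — "near" because the ω²/ω³
prefactor shifts the maximum slightly upward, which the brute-force peak
test quantifies. The conversion factors to Göppert-Mayer units
(2.505472×10⁻²) and to 10⁻⁸⁰ cm⁶ s²/photon² (7.781292×10⁻⁷) are frozen
literature values; `derive_k_tpa`/`derive_k_3pa` re-derive them from
CODATA-2018 constants as 8π³/c² · a₀⁴t₀/10⁻⁵⁰ and 16π⁴/c³ · a₀⁶t₀²/10⁻⁸⁰
(c in a.u.), reproducing the frozen values to about 1 part in 10⁶ — the
residual is consistent with the frozen values having been computed with
rounded constants.

**Grids, windows, peaks.** The default photon-energy grid is 0–6 eV in
0.002 eV steps. Band windows for peak tables default to ±3γ around the
ensemble-mean energy of each state (divided by the photon order).
Peak location is the grid argmax per window, ties broken toward lower
energy; a window with no positive intensity is an error, not a zero row.

## Snapshot decorrelation

The autocorrelation uses the population mean/variance and the truncated
sum with a 1/n prefactor: C(0) = 1 exactly, while C(k>0) is biased low by
a factor approaching (n−k)/n. The biased form is kept deliberately
(it is the conventional estimator in this workflow); the bias is
negligible at the k ≪ n lags used for fitting. The exponential fit
A·exp(−t/τ) uses nonlinear least squares initialized from C at the first
lag and the first 1/e crossing; a fit with τ below one frame spacing, or a
non-decaying C, is reported as "no decay detected". The recommended
spacing is the closed form t* = τ ln(A/tol) rounded up to the frame grid,
with tol defaulting to 0.01; no universally accepted rule maps τ to a
spacing, so the tolerance is an explicit user parameter.

## Structural descriptors

Conventions (stated in every output header): 0-based atom indices,
coordinates in Å, dihedrals in degrees in (−180, 180] with the IUPAC sign
convention. BLA is the mean single-bond minus mean double-bond length over
the five σ/five π backbone bonds named in the topology file. Planarity
maps each of the ten dihedrals through p = (| |θ| − 90 |)/90 and sums:
P = 10 fully planar, P = 0 fully twisted. |θ| is taken before the map so P
is continuous across the ±180° wrap and invariant under θ → −θ and
θ → θ±360° (property-tested). Which four atoms define each dihedral is
genuinely a modeling decision for real chromophores, so the topology JSON
makes it explicit user input rather than perceiving it from connectivity.
Histogram summaries use Freedman–Diaconis bins and are purely descriptive.

## Structure–energy correlation

Nearest-time joining tolerates half a structural frame interval by
default; unmatched records are dropped and counted. Only descriptive
statistics (Pearson r, Spearman ρ, OLS slope/intercept) are reported — no
p-values, because consecutive snapshots are autocorrelated and the nominal
n overstates the information content.

## Electrostatic coupling toy model

A rigid point-charge cloud is the stand-in for a quantum region's charge
density; environment atoms are point charges. Hybrid evaluation computes
exact Coulomb sums for environment atoms within R_exact of the cloud
centroid and a far-field approximation beyond, with no damping at the
shell (the energy is discontinuous exactly there, as documented).

Multipoles are traceless Cartesian tensors up to order 8, built from the
harmonic numerator polynomials of the derivatives of 1/r
(∂ⁿ(1/r) = Q(x,y,z)/r^(2n+1), generated by an exact polynomial recursion);
the traceless moment of a point charge is (−1)ⁿ/(2n−1)!! · qQ(a), which
makes tracelessness exact by construction. Far-field potentials and fields
contract these moments against the same derivative tensors. The
independent oracle in the tests is the per-charge Legendre-addition
expansion, which matches to machine precision order by order.

ESPF fitting solves a total-charge-constrained least-squares problem for
atom-centered charges reproducing the cloud's potential on atom-centered
shells (radii 2/3/4 bohr, pruned within 1.5 bohr of any atom). When the
fit centers coincide with the cloud's own point charges the fit is exact
by construction; the meaningful regime, exercised in the tests, fits a
many-point cloud onto fewer centers. Only order-0 (charge) fitting is
implemented; atom-centered dipoles and higher are out of scope, and
multipole-order convergence scans use the single-center scheme.

## Polarizable sites

Standard induced-point-dipole model: μ_a = α_a(F_ext + F_static + Σ T_ab μ_b)
with T_ab = (3r̂r̂−1)/r³ and all intra-fragment pairs excluded (fragment
membership via `fragment_id`). Quadrupoles use the Buckingham-normalized
traceless second moment Θ = Σq(3rr − r²1)/2, giving φ = Θ:RR/R⁵. The
system is solved as a dense linear problem up to 3000 sites and by
fixed-point iteration beyond, to a 10⁻⁸ residual; iteration failure
reports the spectral radius of αT, surfacing the polarization catastrophe
rather than masking it (no Thole damping). The induction energy is
−½Σ μ_a·F_perm,a. All polarization quantities, including positions, are in
Hartree atomic units end to end; the site-file dialect documents this.

## Synthetic generators

The generators define the study conditions for every test:

* **Ensembles**: each observable of each state follows an independent
  stationary AR(1) process — the minimal stationary process with the fast
  exponentially decaying autocorrelation these observables empirically
  show — with lag-1 coefficient exp(−dt/τ). Defaults: 200 snapshots at
  5 fs, τ = 15 fs, three states with energy means 2.81/4.13/5.20 eV
  (the first two at the retinal chromophore's one-photon peak energies;
  the third a weak higher transition), energy sd 0.1 eV, and strength
  means/sds chosen to produce tens-to-hundreds of GM at the TPA peaks.
  Strengths are truncated at zero — a negligible perturbation at default
  signal-to-noise.
* **Chains**: a 13-backbone-atom alternating chain built by
  internal-coordinate (NeRF) placement with 120° angles; a linear chain
  needs 13 atoms to host 10 consecutive descriptor bonds each flanked on
  both sides, which is why 13 (not 12) atoms are used. The prescribed
  internal coordinates are the ground truth; embedding and re-measuring
  round-trips to 10⁻⁶ (machine precision in practice). Defaults: bond
  means 1.46/1.36 Å, bond sd 0.01 Å, dihedral 180° ± 10°.
* **Coupled datasets**: E₁ = c₀ + c_bla·BLA + c_P·(10−P) + noise with
  defaults c₀ = 2.40 eV, c_bla = +4.0 eV/Å, c_P = +0.05 eV, noise sd
  0.05 eV — signs chosen so lower BLA and higher planarity lower E₁, and
  magnitudes so the OLS slope is recoverable within 15% at n = 200.
* **Charge clouds / sites**: uniform clouds with the net charge enforced
  exactly; water-like neutral 3-site fragments with isotropic LoProp-like
  polarizabilities (O 5.7, H 2.1 bohr³) on a jittered lattice whose
  spacing keeps the mutual-polarization spectral radius safely below 1.

What the generators do **not** emulate: force-field or QM/MM sampling
(no anharmonicity, no cross-correlation between observables beyond the
imposed structure coupling), real chromophore chemistry (no β-ionone
ring, no protonation states), conformational transitions, or continuous
charge densities. Passing tests therefore demonstrate the correctness of
the analysis layer under known ground truth, not the accuracy of any
upstream electronic-structure method.

## Problem sizes and numerics

Test and acceptance workloads are desk-scale by design: ensembles of
200–1000 snapshots, 20-seed replicate sets for the τ-recovery study,
10-seed sets for the coupling scans, ≤ 51 polarizable sites. Fits use
scipy `curve_fit` with positivity bounds; linear algebra is dense numpy.
Degenerate inputs (constant series, zero variance, collinear dihedral
atoms, coincident charges, rank-deficient ESP grids, tolerance ≥ A) raise
informative errors rather than returning NaN.

## Known limitations

* Peak energies are grid arguments; no sub-grid interpolation.
* The biased autocorrelation normalization slightly shortens fitted τ for
  short series (the replicate median stays within the tested 25%).
* The hybrid coupling energy is discontinuous at the R_exact shell.
* ESPF is charge-only; anisotropic site multipole fitting is not provided.
* The polarization module has no damping, so closely spaced highly
  polarizable sites legitimately fail with a diagnostic.
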