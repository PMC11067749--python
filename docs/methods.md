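# Methods

This note records the scientific conventions, numerical choices and known
limitations of `aspher`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pseudoatom model

Each atom is a Hansen–Coppens pseudoatom

ρ(r) = P_c ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_{l} κ′³ R_l(κ′ r) Σ_m P_lm d_lm(θ, φ)

* **Core and valence densities** are built from single-zeta Slater shells
  (H, C, N, O; exponents from the classic single-zeta SCF tabulation shipped
  in `data/slater_shells.json`, bohr⁻¹, converted once at load). Each shell
  density is normalized to one electron, so f_x(0) = P_c + P_val exactly.
  The same machinery with neutral populations and κ = 1 *is* the package's
  IAM; it satisfies f(0) = Z and monotone decay by construction and plays
  the role that parameterized free-atom tables play elsewhere.
* **Deformation radials** are normalized Slater functions
  R_l(r) = N r^{n_l} e^{−ζr} with element defaults n_l = (2,2,2,3,4) for
  C/N/O and (0,1,2) for H, ζ = 3.0/3.8/4.5 bohr⁻¹ (C/N/O) and 2.0 bohr⁻¹
  (H) — common multipole-refinement defaults, overridable per model in the
  parameter file. These are package defaults, not databank contents.
* **Angular functions** d_lm are real spherical harmonics under density
  normalization: ∫|d_lm| dΩ = 2 for l ≥ 1 and ∫d_00 dΩ = 1. The
  normalization constants were generated once by adaptive quadrature of
  |P_l^m| split at its sign changes and are frozen in `harmonics.py`; a test
  re-derives them numerically. scipy's associated Legendre functions carry
  the Condon–Shortley phase; population signs follow that convention
  consistently.
* The l = 0 deformation monopole (P_00) is supported by the machinery but
  zero in every shipped model, keeping f_x(0) = P_c + P_val exact.
* **Site symmetry** restricts (l, m): `m` (mirror = local xy plane) keeps
  l+|m| even; `3m` keeps cosine terms with m ∈ {0, 3}; `cyl` (bond-directed)
  keeps m = 0. Rules are analytic; tests check them pointwise against the
  generator matrices.
* **Local frames** are defined by two reference atoms (first axis along the
  first reference, Gram–Schmidt for the second). During structural
  refinement frames are frozen within a least-squares pass and rebuilt
  between passes until self-consistent, the usual treatment when local axes
  ride on the atoms.

## Transforms and structure factors

The Fourier–Bessel transform ⟨j_l⟩(s) of a Slater radial is evaluated in
closed form along two analytic routes: a damped sin/cos expansion of j_l
(exact, used for 4πs ≥ ζ/2) and the ascending series of j_l integrated term
by term (stable for 4πs < ζ/2, where the sin/cos route suffers catastrophic
cancellation of order (ζ/4πs)^l). Both routes agree with adaptive
quadrature of the defining integral to ~1e-13 relative.

Crystal structure factors are assembled over the asymmetric unit and all
symmetry operators: each operator contributes at the transformed index
h_eff = Mᵀh, which carries the rotation into the form factor direction, the
displacement tensor and the positional phase at once; sites are weighted by
occ · multiplicity / |ops| so special positions count once. Special-position
constraints (coordinates and U_ij components) are derived automatically from
the eigenvalue-1 subspace of the stabilizer's averaging projector. Electron
structure factors apply Mott–Bethe per atom before the Debye–Waller factor;
the constant 1/(8π²a₀) = 0.023934 is derived from CODATA values at import,
as is the 200 kV wavelength (0.02508 Å) and the relativistic factor.

Charged pseudoatoms and l = 1 deformation terms make f_e(s) grow like 1/s²
and 1/s at small s. This is physical (the long-range potential of monopoles
and dipoles) and is why low-resolution electron structure factors are so
sensitive to bonding effects; the 000 beam is excluded from all reflection
sets, and the s → 0 monopole limit is used only for the mean inner
potential of the dynamical module.

## Least squares

A Levenberg–Marquardt loop with numerical central differences
(steps: 1e-5 fractional for coordinates, 1e-5 Å² for U, 1e-4 for
populations and kappas) minimizes Σ w (Y_obs − (k·)Y_calc)² for Y = |F| or
|F|². Weights: unit, 1/σ², or the intensity-based scheme
w = 1/[σ²(F²) + (aP)² + bP] with P = max(0, F_o²)/3 + 2F_c²/3; a coarse
grid search for (a, b) flattens the binned mean weighted squared residual,
standing in for the automatic weight optimizers of production programs. A
constant σ(F²) = 1 option supports the theoretical-data protocol in which
only R_all is meaningful. Convergence is max |shift|/esd < 0.01 with a
100-cycle cap; esds come from the inverse weighted normal matrix without
goodness-of-fit scaling (so doubling all σ doubles esds; multiply by the
GoF if the conventional scaled esds are wanted). Singular normal matrices
raise an error naming the null-space parameters.

Multipole fitting works against phased amplitudes (complex residuals, unit
weights, frozen geometry/ADPs/scale). Starting from spherical atoms the κ′
derivatives vanish identically, so populations are staged in first; with
noise-free data the generator parameters are recovered to ~1e-8 e.

Bond-length comparison statistics: ME is the signed mean difference; RMSD
is the root of the mean squared difference (this is the convention that
reproduces standard comparison tables). U_eq is one third of the trace of
the Cartesianized U tensor.

## Dynamical diffraction

The Bloch-wave structure matrix has diagonal 2KS_g and off-diagonal
U_{g−h} = γ F_e(g−h)/(πV); with no absorption it is Hermitian and
intensities conserve ΣI = 1 to machine precision (the v1 scope excludes an
imaginary potential). The excitation error is S_g = (K² − |k₀+g|²)/2K
(positive inside the Ewald sphere; at a zone axis the zero-layer value is
−g²λ/2). RS_g is computed numerically as |S(central)|/max_α|S(α)| on a
360-point azimuth grid of the precession cone — the definition is stated
operationally because closed forms in the literature differ in edge cases.
Beam selection applies d ≥ d_min, |S_g| ≤ S_max (default 0.02 Å⁻¹) and
RS_g ≤ RS_max (default 0.75) with a deterministic |g|-then-lexicographic
order and a 500-beam cap. Precession averages the static solution over
equally spaced azimuths (default 64 for single calculations, 32 inside
refinement loops); intensities on the unit scale are stable to ~1e-4
against azimuth doubling. A single-scattering evaluator in the identical
geometry isolates multiple-scattering strength; zone-axis frames show by
far the largest deviation, and the kinematical limit is recovered
quadratically as t → 0.

Thickness refinement profiles one amplitude scale per frame analytically
and minimizes over one thickness per crystal with bounded Brent; t at the
lower bound flags the degenerate scale/thickness correlation of the t → 0
limit. With four synthetic frames at 2% noise, 120 nm is recovered to
better than 1 nm.

## Maps and fractal curves

Residual maps synthesize (|F_o| − k|F_c|)·exp(iφ_calc) over the measured
set (unique reflections are Laue-expanded to one hemisphere; model
amplitudes and phases are recomputed at every index; k is a fitted or given
scale), on an FFT grid with spacing ≤ d_min/3 per axis (aliasing is
rejected, never wrapped). With electron structure factors in Å the values
follow the residual-potential convention labelled e Å⁻¹ in this field; no
absolute potential calibration is claimed. Extrema use three-point
parabolic interpolation per axis and can be annotated with the nearest
atom. The 000 term is always excluded, so maps average to zero.

The fractal-dimension curve is d_f(ρ₀) = ln N(ρ₀)/ln(N_total^{1/3}) with
N(ρ₀) the voxel count of the value bin at ρ₀ (100 equal-width bins by
default); this is the fixed-grid specialization of box-counting residual
analysis. Note an intrinsic property of the definition: halving the bin
width halves every count and therefore lowers the entire curve by
ln2/ln(N^{1/3}) (~0.16 for desk-scale grids); only the curve *shape* is
bin-width stable, and the tests assess exactly that. A Gaussian-noise map
yields the characteristic parabola-like curve; a single bin covering every
voxel gives d_f = 3 identically.

## Synthetic study conditions

The fixture emulates a 1-methyluracil-like crystal: Ibam (operators shipped
as explicit triplets), a = 13.10, b = 13.90, c = 6.25 Å, one planar
molecule on the (x, y, 0) mirror with only the out-of-plane methyl hydrogen
H7b off the special position, and an intermolecular N3—H3⋯O4 hydrogen bond
(H⋯O 1.95 Å, 166°). Geometry was hand-built from standard bond lengths
with neutron-like X–H distances; the in-plane placement was chosen once by
a clash-free packing search and frozen. Cell constants, coordinates and
ADPs are invented plausible values, not literature or experimental data.

Three multipole tiers (databank-, tailored- and crystal-like) share the
same chemistry and differ mostly in the hydrogen-bond-directed dipole
populations of H3 and O4 (±0.035–0.08 e) plus small generic offsets,
emulating increasingly environment-specific parametrizations. The κ values
(1.25 for H, 1.00–1.03 for C/N/O) and the H bond-directed dipoles
(P₁₀ = 0.18) were calibrated once so that the fixture exhibits the
characteristic electron-diffraction IAM biases — X–H bonds refine too long,
non-H U_eq too small, H ADPs too large — and then frozen; they are design
constants of the synthetic study conditions, not refinable defaults.
Neutrality is enforced exactly per molecule (multiplicity-weighted, H7b
counted twice) by adjusting the carbon valence populations.

Default generation conditions: d_min 0.56 Å, 63% completeness (a 15°
missing-cone about c* plus seeded thinning to the exact count), Gaussian
intensity noise σ = max(floor, c·F²) (floor 0.1, c 0.02) — Gaussian rather
than Poisson to match the least-squares assumptions; a Poisson switch would
be a one-line change in `simulate_reflections`. Every generator is a pure
function of (spec, seed) and byte-reproducible. Test and validation runs
use reduced problem sizes (d_min 0.7–1.2 Å, ≤ 200-beam frames, four
frames per thickness fit) — the physics probed does not depend on pushing
to the full resolution range.

What passing tests show — and what they do not: the synthetic data contain
no experimental systematics (no beam damage, no mosaicity or bending, no
detector effects, no frame-scaling drift), so recovery tolerances here are
statements about the estimator and its implementation, not about what
experimental 3D ED data can deliver. The refinement-bias trends reproduce
the qualitative physics; their magnitudes depend on the invented multipole
parameters and should not be read as quantitative predictions for any real
compound.

## Known limitations

* Elements shipped: H, C, N, O (the shell table is user-extensible).
* No anomalous dispersion, absorption/extinction, twinning, disorder or
  restraint language; occupancies other than 1 are supported but exercised
  only trivially.
* Dynamical model: perfect crystal, no absorptive potential, no
  frame-orientation refinement, no mosaicity.
* The automatic (a, b) weight search and the RS_g definition are documented
  stand-ins for unpublished production-code internals.
* Space groups come in as explicit operator lists; there is no
  symbol-to-operators table beyond the shipped fixtures.
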