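# Methods

This note records the models implemented in `chargemc`, their assumptions,
the numerical choices behind them, and what the synthetic test systems do
and do not establish.

## The pseudoatom density model

Each atom contributes a Hansen–Coppens pseudoatom,

ρ_a(r) = ρ_core(r) + P_val κ³ ρ_val(κr)
        + Σ_{l≤lmax} κ′³ R_l(κ′r) Σ_m P_lm y_lm(θ, φ),

with density-normalized real spherical harmonics (∫|y_lm| dΩ = 2 for
l > 0, y_00 = 1/4π; normalization constants fixed numerically at import to
~1e-6 relative).  All radial functions are single-ζ Slater forms
C rⁿ e^(−ζr); the deformation radial powers are n_l = (2, 2, 3, 4) for
l = 0…3 and the deformation exponents default to the valence exponent of
the element.  Orbital exponents follow Slater's screening rules (density
exponent = 2 × orbital exponent); second-row atoms carry a frozen 1s² core,
hydrogen has none.  Multipole expansion defaults: octupoles for B/C/N/O,
dipoles for H.

This single-ζ radial model is deliberately self-contained.  It has the
correct structure (core/valence/deformation separation, κ-scaling laws,
multipolar angular behaviour) but its absolute densities differ from
multi-ζ Hartree–Fock atomic tables, so no result computed here should be
compared with published absolute density values for real compounds; the
package's validation against published numbers is restricted to quantities
computable from printed inputs.

Density, gradient and Hessian are analytic.  The angular polynomials,
their gradients and Hessians are generated symbolically at import and
evaluated as compiled numpy expressions, with the radial chain rule coded
by hand.  Symmetry images rotate the local multipole frame with the
Cartesian rotation of the operator; real-space evaluation includes images
within an 8–10 Å cutoff (the slowest shell decays as e^(−3.8 r/Å), so the
truncation error is below 1e-10 e Å⁻³).  Evaluation at a nucleus caps r at
1e-6 Å — finite, never a division by zero.

## Structure factors and refinement

Intensities are I_calc = scale·|F|², with F summed over all symmetry
images; no extinction, absorption or anomalous terms.  Scattering factors
are radial Fourier–Bessel transforms of the Slater shells, computed by
240-node Gauss–Legendre quadrature and cached per (power, effective ζ, l)
for a given reflection batch — the cache is what makes finite-difference
derivative columns affordable.  ADPs enter as
exp(−2π² Σ U_ij h_i h_j a*_i a*_j) with U stored in Å².

The least-squares objective is E = Σ_H W_H (I_calc − I_obs)² with
W = c/σ_I² (c configurable, default 1).  The Gauss–Newton normal matrix
A_ij = Σ_H W_H (∂I/∂x_i)(∂I/∂x_j) uses analytic derivatives for the scale
factor and the population parameters (linear in F) and central finite
differences for positions (1e-5 fractional), U (1e-5 Å²) and κ/κ′ (1e-4).
Refinement solves A·dX = V with step halving, declaring convergence when
every shift falls below 0.01 of its e.s.d. (falling back to unscaled
variances when the data are exact and the GOF vanishes); an optional
block-diagonal mode zeroes inter-atom blocks for the early cycles.
Covariances come from B = A⁻¹ (eigenvalue floor 1e-10 × largest for
near-singular directions) with e.s.d._i = GOF·√B_ii,
GOF² = E/(n_obs − n_par); degrees of freedom count no restraints because
the toy refinements are unrestrained.

In P1 the origin floats (a uniform translation leaves every |F| fixed), so
refinements pin one atom's coordinates through the parameter free/fixed
mask; e.s.d.'s are then relative to that choice of origin, as in any real
space group with a polar direction.

## Deviating models and SSD statistics

The square-root factor S = Q D^(−1/2) (times the GOF when the covariance
is GOF-scaled) satisfies S·Sᵀ = B by construction; eigenvalues below
1e-10 × the largest are clamped and counted, and an eigenvalue
significantly negative aborts with the highest-leverage parameter named.

Deviates are standard normals rejected outside ±4 and divided by the
truncated distribution's standard deviation, √(1 − 8φ(4)/(2Φ(4) − 1)), so
the population variance is exactly 1.  The renormalization is a global
scalar applied to the deviates; it widens the support to 4/√v in
standardized units (≈ 4.0003), a second-order effect.  Rejection sampling
was chosen over the ratio-of-uniforms generator for transparency — any
unit-variance generator satisfies the covariance-propagation argument.
One master seed spawns per-member substreams, so an ensemble is
reproducible and extensible without redrawing earlier members.

SSDs use the N−1 denominator, under which SSD·√(N−1)/σ follows a χ
distribution with N−1 degrees of freedom for Gaussian properties; the
expected relative precision of the SSD is computed from exact χ moments
(≈ 1/√(2(N−1)); 16 % at the default N = 20).  Property reports carry an
occurrence count: a property absent from a member (a critical point that
vanished) lowers the occurrence instead of failing, and fewer than two
occurrences yield no SSD.

## Topology

Critical points are found by Newton iteration on the analytic gradient
with the analytic Hessian (batched over seeds; steps capped at 0.3 Å;
singular Hessians perturbed and retried), seeded from midpoints of
(reference atom, any image) pairs within 3.5 Å, optionally densified with
a coarse grid.  Convergence requires |∇ρ| < 1e-7 e Å⁻⁴; duplicates merge
within 0.05 Å, one representative per symmetry orbit is kept, and
stationary points of the exponentially flat intermolecular tail
(ρ < 1e-4 e Å⁻³) are dropped.  Classification uses the Hessian signature
with a curvature-zero threshold of 1e-6 e Å⁻⁵.  Ellipticity is
ε = λ₁/λ₂ − 1 ≥ 0 at (3,−1) points.

Bond paths launch along ±the λ₃ eigenvector and integrate the normalized
gradient field with fixed-step (0.01 Å) fourth-order Runge–Kutta,
terminating within 0.3 Å of a nucleus *only when ascending towards it* —
without the direction gate, a path starting next to a hydrogen would
terminate immediately on its own donor atom.  The terminal gap to the
nucleus is added to the reported length.  Unterminated paths (10⁴ steps)
are flagged and leave the linkage empty.

Across an ensemble, each reference CP is re-located by Newton iteration
from its reference position (then from a local seed cloud if that fails)
and matched within 0.3 Å with the same Hessian signature; nucleus–CP
distances use the member's own nuclei (nearest symmetry image).  All
topological quantities are computed from the static density; U_ij still
participates in the covariance and therefore moves the nuclei between
members.

Energy densities at a CP follow Abramov's kinetic functional
G = (3/10)(3π²)^(2/3) ρ^(5/3) + ∇²ρ/6 and the local virial
V = ¼∇²ρ − 2G (atomic units; a₀ = 0.52917721 Å, 1 hartree =
2625.4996 kJ/mol).  The hydrogen-bond dissociation energy is reported
under both conventions −V and −V/2; the default is −V/2, the convention
that reproduces the published 37.9 kJ/mol value from the printed
ρ/∇²ρ pair (−V gives twice that).  Both remain available and labelled.

## Electrostatics

The potential of a pseudoatom density is evaluated *exactly*: every radial
term is an rⁿe^(−ζr) form whose interior/exterior Coulomb integrals reduce
to incomplete-gamma closed forms, including the multipolar terms through
the (2l+1)⁻¹ radial kernels.  This replaces quadrature of the density with
the direct integral it approximates; a brute grid integration of
ρ(r′)/|r−r′| is retained as an independent oracle path
(`method="grid"`), accurate only for cusps a grid can resolve.

Intermolecular energies decompose exactly by charge type:
nuclei(A)×everything(B) and electrons(A)×nuclei(B) use the closed-form
potentials; only the smooth electron–electron integral is quadratured, on
atom-centred spherical product grids (three radial panels to 9 Å ×
24 × 48 angles).  The A↔B asymmetry, a pure integration check, is below
1 %.  Molecules are extracted from the lattice as the asymmetric unit;
neighbour molecules are symmetry/lattice images.  Dimers are unique up to
f ↔ f⁻¹; an operator whose square (lattice part included) is the exact
identity is involutional — its two molecules map onto each other mutually
— and carries weight ½ in packing sums.  Screws, glides and pure
translations square to nonzero lattice translations and keep weight 1.

Isodensity surfaces (default level 0.001 a.u. = 0.0067 e Å⁻³) come from
marching cubes on a 0.1 Å molecular grid; the potential of the reference
and of every deviating model is evaluated per vertex, giving SSD(Φ) and
the significance ratio |Φ|/SSD (capped at 1e6 where the SSD vanishes;
vertices below ratio 1 are the "insignificant" zero-potential stripe).

Basin charges use on-grid steepest ascent (best ascending neighbour of 26,
pointer doubling to attractors) over a molecular grid with a 3 Å margin
(0.05 Å step for production numbers; coarser in tests).  Two refinements
matter at desk scale: voxels within 0.35 Å of a nucleus are subsampled 7³
because no affordable grid resolves the cusp (without this the integration
error is ~0.4 e per heavy atom), and the ascent field is quantized to 12
significant digits with two opposite tie-break passes averaged, so a
mirror-symmetric density splits its boundary plane exactly evenly.  The
residual integration deficit is reported and, on request, redistributed
evenly over the atomic basins — the same bookkeeping the reference study
applied to its 0.47 e deficit.  Attractors further than 0.5 Å from any
nucleus are counted as non-nuclear and kept.

## Synthetic study conditions

Three toy crystals define the test conditions; all have nonzero multipole
populations and κ ≠ 1 on every atom so each parameter kind has leverage:

- `diatomic_p1` — two C pseudoatoms 1.40 Å apart in a 6×6×7 Å P1 cell,
  antisymmetric dipoles and equal quadrupoles (the density has exact
  homonuclear mirror symmetry); 41 free parameters after origin pinning.
- `bent_triatomic_pminus1` — a bent O–H₂ molecule in P-1; the inversion
  supplies an involutional dimer.
- `hbond_chain_p1` — a water-like molecule in a 3 Å-axis P1 cell whose
  donor H points at the next image's O (O–H⋯O contact of 2.05 Å), giving
  an intermolecular (3,−1) CP and a translation dimer.

Simulated intensities are I_obs = scale·|F|² + Gaussian noise with
σ_I = √max(I, floor) × noise_level, matching the least-squares weighting
model exactly (not Poisson counting); the default noise_level 0.02 gives
strong data (⟨I/σ⟩ of order 50, GOF ≈ 1), like the very high-resolution
data sets this method targets.  Default resolution s_max = 0.8 Å⁻¹
(≈ 2200 unique reflections for the diatomic cell), reduced to 0.6 Å⁻¹ in
the 100-repeat recovery study, which refines the scale, positions and
valence populations; the full parameter set is refined in the
single-refinement fixtures.  The ensemble consistency checks use N = 200
(χ-precision ≈ 5 %) so SSD/e.s.d. ratios are tested within a 4-band
interval, and N = 20 for workflow-level tests.

What passing these tests shows: the covariance algebra, the sampling, the
SSD statistics, the topology and the electrostatics behave correctly under
conditions where the least-squares model is exact (the noise really is
Gaussian with known σ, the model really generated the data).  What they do
not show: robustness to systematic error, restraint bookkeeping, thermal
smearing of the density, or agreement with any published absolute density
value — real data violate the idealizations in all these ways, and the
method propagates precision, not accuracy.

## Known limitations

- Single-ζ radial functions; no multi-ζ atomic wavefunctions, anomalous
  dispersion, or anharmonic ADPs.
- No restraints or constraints; degrees of freedom are n_obs − n_par.
- Basin integration is grid-limited away from the subsampled cusp region;
  deficits of a few 0.01 e at 0.1 Å steps are expected and redistributed.
- The CP search seeds from atom-pair midpoints (plus an optional grid);
  cage/ring points far from any pair midpoint require the grid option.
- Periodic electrostatics are not implemented: potentials and energies are
  for molecules extracted from the lattice, as in the reference workflow.
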