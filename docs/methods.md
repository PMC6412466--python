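# Methods

## Model

`spinlrf` evaluates the *bare* (uncoupled) linear response of the electron
density to a static external-potential perturbation, from a single
unrestricted Kohn–Sham or Hartree–Fock determinant:

    χ0(r, r′) = Σ_σ Σ_i^occ Σ_a^virt ψ_iσ(r) ψ_aσ(r) ψ_iσ(r′) ψ_aσ(r′) / (ε_iσ − ε_aσ).

This is first-order orbital perturbation theory with frozen self-consistent
field: no coupled-perturbed (orbital-relaxation) terms, no
frequency dependence. The denominators are occupied-minus-virtual energies
and therefore strictly negative, so a *negative* condensed entry K[I, J]
means the density at atom I increases under an attractive perturbation at
atom J; the matrix is symmetric and negative semidefinite by construction,
and charge conservation (the perturbation moves charge, it does not create
it) forces every column to sum to zero up to quadrature error.

A convention note: for real orbitals the full first-order density change is
δρ = 2 Σ ψ_i ψ_a V_ai/(ε_i − ε_a); the response kernel here is written as
the single-sided orbital sum *without* that factor 2, which is the form the
condensed matrices and all closed-form fixture values use consistently. The
finite-difference oracle (below) halves the raw first-order change to sit
on the same scale.

The spin-density response to a virtual magnetic probe is the per-channel
kernel differenced, δρ_z/δv_m = χ0^α − χ0^β. For bit-identical channels it
is returned as an explicit zero matrix without summation — the
closed-shell limit is exact, not approximate. Because only orbitals and
orbital energies enter, both probes are *virtual*: no perturbing field is
ever constructed.

All sums include every virtual orbital present in the input orbital set.
An optional virtual-energy cutoff exists for experimentation; it defaults
to off and its use is recorded in the provenance metadata. Occupied–virtual
gaps below 1e-6 hartree abort with an error naming the pair rather than
regularizing the denominator: a silently regularized matrix would look
plausible and be wrong.

## Quadrature and condensation

Atom-condensed quantities integrate over **hard Wigner–Seitz cells**: the
cell of atom I is the set of points nearer to I than to any other atom
(perpendicular-bisector planes; exact ties, a measure-zero set, go to the
lowest atom index). Every grid point is owned by exactly one atom, so the
cells tile space and per-atom integrals sum to the whole-space integral
identically.

The underlying grid is the standard molecular product construction:

* **Radial**: Murray–Handy–Laming (m = 2) Euler–Maclaurin mapping
  r = R q²/(1−q)², q = k/n, k = 1..n−1, with weights 2R³q⁵/(1−q)⁷/n that
  absorb the r² Jacobian; n = 50 by default. R is the element's
  Bragg–Slater radius (H: 0.35 Å), converted with the CODATA-2014 bohr.
  The n = 50 rule integrates a unit Gaussian to ~8e-10 relative error.
* **Angular**: Lebedev rules via `scipy.integrate.lebedev_rule`, addressed
  by point count (default 302, algebraic degree 29).
* **Partition**: each point's weight carries the smooth Becke-style
  partition factor of its parent atom (three iterations of the polynomial
  switching function, no atomic-size adjustment), so the union of atomic
  grids is a single accurate whole-space quadrature — electron counts and
  numerical AO overlaps converge to ~1e-7 at the default grid. The smooth
  factors enter *only* the quadrature weights; the condensation domains
  remain hard cells. A design worth stating explicitly: with bare
  (unpartitioned) product weights, either space is counted once per atom or
  each atomic grid must be truncated at its own cell boundary, and the
  truncated scheme integrates even smooth functions only to ~1e-2–1e-3
  (measured on an H₂-type dimer) because Lebedev shells handle the
  boundary-cap discontinuity poorly. Hard cells for the *domains* plus a
  smooth partition for the *weights* keeps both the condensation semantics
  and the integral accuracy.

  Cell-resolved quantities still carry the intrinsic hard-boundary error of
  sampling an indicator function (~1e-4 at 50×302 on diffuse toy densities);
  sums over cells are free of it by exact cancellation.

* **Orientation**: angular sets are oriented in the molecule's principal
  frame (eigenvectors of the charge-weighted coordinate covariance, fixed
  ordering and sign convention). Lebedev sets are invariant under signed
  axis permutations, so the residual eigenvector ambiguities do not move
  the point set, and condensed quantities are invariant under global
  rotations to machine precision rather than to cap-error level. A
  `orient="fixed"` escape hatch keeps the laboratory frame.

The response matrices are assembled in factorized form: cell moments
M_σ[i, a, A] = ∫_A ψ_iσ ψ_aσ are computed once (O(N_occ · N_virt · M_points))
and contracted per atom pair; the two-point kernel χ(r, r′) is never formed
on a grid squared.

## Basis evaluation and orbital input

Contracted Gaussians up to l = 4 are evaluated in real solid-harmonic or
cartesian component form with Molden component ordering; cartesian
components are individually normalized, and shells read from Molden files
keep their coefficients in the Molden convention (primitive norms applied
at evaluation) so files round-trip verbatim. Contractions whose analytic
self-overlap deviates from 1 by more than 1e-4 are rejected naming the
shell; smaller deviations are renormalized. Occupations must be exactly
0/1 per spin channel (or 0/1/2 in restricted files, which are duplicated
into identical channels); fractional occupations are rejected rather than
thresholded, since the sum-over-states form assumes an integer-occupation
determinant. AO overlaps are computed numerically on the quadrature grid —
deliberately, as a built-in cross-check of basis evaluation and grid
quality (documented accuracy ~1e-6 at production grids); orbital
orthonormality is validated, reported, and never silently repaired.

## Broken-symmetry diagnostics

Corresponding-orbital overlaps T_i are the singular values of
C_α,occᵀ S C_β,occ, sorted ascending so the magnetic pair (smallest
overlap) is first. Derived indices: effective bond order b = Σ T_i,
natural occupations 1 ± T_i, spin-projected bond order
B = Σ 2T_i/(1+T_i²), diradical character reported per pair as
y_i = 1 − 2T_i/(1+T_i²) and in aggregate as the magnetic pair's y (both
appear in reports, since either convention is found in practice). For
net-spin systems only the min(N_α, N_β) paired overlaps enter the sums; the
excess spin-orbitals are counted separately as `n_unpaired_excess`.
Singular values may exceed 1 by the accuracy of the overlap matrix; values
within 1e-6 of the bound are clipped, larger excursions raise an error.

## Synthetic fixtures and what they do (not) show

All tests run on analytic model systems whose expected values come from
closed forms computed in the fixtures module, independent of the analysis
code:

* **Two-site dimer**: one normalized s-Gaussian per site (exponent 1.0,
  separation 1.4 bohr — a generic H₂-scale model), Löwdin-orthogonalized
  before forming bond/antibond combinations so the mixing-angle algebra is
  exact (inter-site overlap never enters the identities). Occupied
  α/β orbitals mix by θ; T = cos 2θ, spin density sin 2θ (χ̃₁² − χ̃₂²),
  and the Wigner-Seitz cell moments have erf closed forms. Orbital
  energies default to −0.5/−0.1 hartree (a 0.4-hartree HOMO–LUMO gap,
  typical of a small covalent model). The mirror-symmetric dimer has an
  exactly vanishing spin response (the even product φ_a² − φ_b² has zero
  cell moments); an asymmetric variant with per-site exponents (1.0, 1.8)
  provides the nonzero spin-response fixture.
* **Multi-pair toy**: k independent dimers 50 bohr apart, one mixing angle
  each — inter-pair overlaps < 1e-100, so the block construction is exact.
* **Chains/rings**: s-Gaussian sites with a tridiagonal model Hamiltonian
  in the Löwdin basis. Locality (near-sightedness) fixtures use
  *dimerized* couplings (−0.35/−0.05 alternating): a uniform half-filled
  chain is the small-gap limit where the response genuinely oscillates
  rather than decays, so monotone decay is tested where the physics
  predicts it — in the gapped, insulating regime.

These fixtures exercise every contract of the analysis (symmetry,
conservation, definiteness, oracle equivalence, parameter recovery) but
they are s-function models with few states: they do not probe d/f-shell
response, near-degenerate metal manifolds, or basis-set sensitivity of
real transition-metal clusters. Passing tests certify the machinery, not
the chemistry of any particular enzyme model.

## Independent checks

* **Finite-difference oracle**: V_J = λ·1_cell(J) built in the MO basis by
  quadrature, first-order orbital mixing applied non-self-consistently,
  densities recomputed and condensed; converges to column J of the
  condensed matrix as λ → 0 (λ = 1e-4 hartree default, guarded against
  orbital reordering). Agreement at the 1e-4 relative level.
* **Hand closed form**: the two-level dimer's K = (2s²/−Δ)[[1,−1],[−1,1]].
* **1-D brute force**: for collinear chains the Voronoi cells are slabs,
  so an independent dense 1-D quadrature (transverse directions integrated
  analytically) reproduces the full matrix with no shared code.

## QM-region rule

Selection is the OR of two per-atom tests — max over reaction-center atoms
of |K_ρ[I, J]| ≥ τ_ρ, likewise for the spin matrix and τ_m (defaults
0.01/0.01) — with the reaction center always included. The criteria are
stated as thresholds, not an algorithm, so the minimal monotone reading is
implemented: selections can only grow when thresholds drop or the reaction
center grows. Optional fragment completion expands the selection to whole
covalently connected fragments (bond = distance < 1.3 × sum of Cordero
2008 covalent radii, pinned in-source) and reports boundary-crossing bonds
as the capping list; geometry editing is out of scope. Model-error reports
are signed model − full over an explicit injective atom map.

## Numerical choices and limitations

* Default grid 50 × 302; every tolerance quoted above is at that grid.
* Internal units are strictly atomic (bohr, hartree); the
  Å↔bohr constant is pinned to CODATA 2014.
* 1-based atom indices in every user-facing report; 0-based internally.
* The response is bare: no self-consistent screening. Condensed values for
  strongly polarizable systems will differ from coupled-perturbed results;
  the method's use is comparative (which atoms couple above a threshold),
  where the bare kernel is the defined quantity.
* Reproducing published transition-metal cluster tables requires external
  large-scale DFT orbital sets (Molden input path) and is outside the test
  suite by design; the model-error machinery those comparisons need is
  fully implemented and tested on analytic models.
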