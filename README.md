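# spinlrf

Linear response functions of electron density and spin density for
open-shell molecular systems, and their use in choosing QM/MM boundaries.

## The problem

Hybrid QM/MM calculations of metalloenzymes stand or fall with the choice
of the QM region. When a peripheral group is replaced by point charges, the
modelling error acts on the reaction center like an external-potential
perturbation δv(r′), and the damage it does to the electron density at the
active site is governed by the *linear response function*

    χ(r, r′) = δρ(r) / δv(r′),

which `spinlrf` evaluates in the bare (uncoupled) sum-over-states form from
an unrestricted Kohn–Sham or Hartree–Fock solution:

    δρ(r)/δv(r′) = Σ_σ Σ_i^occ Σ_a^virt  ψ_iσ(r) ψ_aσ(r) ψ_iσ(r′) ψ_aσ(r′) / (ε_iσ − ε_aσ).

For spin-polarized (broken-symmetry) solutions the same machinery applied
per spin channel and differenced gives the response of the spin density
ρ_z = ρ_α − ρ_β to a virtual magnetic probe, δρ_z(r)/δv_m(r′).

Both kernels are *condensed* onto atoms by double integration over hard
Wigner–Seitz (nearest-atom Voronoi) cells,

    K[I, J] = ∫_I dr ∫_J dr′ χ(r, r′),

yielding an N×N atom-pair matrix whose entries measure how strongly atom J
is electronically coupled to atom I. Atoms whose coupling to the reaction
center RC satisfies |δρ(I)/δv(RC)| ≥ τ_ρ or |δρ_z(I)/δv_m(RC)| ≥ τ_m
(conventionally τ = 0.01) belong in the QM region.

The package also computes the standard broken-symmetry diagnostics that
make spin-density responses interpretable: corresponding-orbital overlaps
T_i, effective bond order b = Σ T_i, spin-projected bond order
B = Σ 2T_i/(1+T_i²), diradical character y = 1 − B, and the on-top pair
density ½(ρ² − ρ_z²).

## Worked example

A two-electron, two-site broken-symmetry model with mixing angle
θ = π/8 (the occupied α/β pair is cos θ·φ_bond ± sin θ·φ_anti):

```python
import math, numpy as np
import spinlrf as s

toy  = s.build_two_site_toy(math.pi / 8)          # H2-like dimer, 1.4 bohr
grid = s.assemble_ws_grid(toy.geometry, 50, 302)  # Euler-Maclaurin x Lebedev
ao   = s.eval_basis(toy.shells, toy.geometry, grid.points)

k = s.compute_lrf(toy.geometry, toy.shells, toy.mos, grid)
print(np.round(k.matrix, 6))
d = s.diagnose(toy.mos, s.numerical_overlap(ao, grid))
print(f"T = {d.T[0]:.6f}  b = {d.b:.6f}  y = {d.y:.6f}")
```

prints

```
[[-0.511264  0.511264]
 [ 0.511264 -0.511264]]
T = 0.707107  b = 0.707107  y = 0.057191
```

The diagonal entries are negative: an attractive perturbation on an atom
*increases* the density there, and charge conservation forces each column
to sum to ≈ 0, so the off-diagonals carry the compensating outflow from the
partner atom. T = cos 2θ = 1/√2 recovers the mixing angle exactly, and
y ≈ 0.057 quantifies the mild diradical character at this θ.

The same analysis runs on Molden files from any SCF engine:

```
spinlrf lrf-matrix orbitals.molden --grid 50x302 -o matrix.csv
spinlrf lrf-cube   orbitals.molden --atom 1 -o field.cube
spinlrf qm-region  orbitals.molden --rc 1,38 --tau-rho 0.01 --tau-spin 0.01
spinlrf bs-diag    orbitals.molden
```

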