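"""Evaluation of Gaussian basis functions, orbitals and densities on grids.

Supports contracted Gaussians up to l = 4 in both real-solid-harmonic (pure)
and cartesian component form with Molden component ordering.  Also provides
the numerical AO overlap matrix, Wigner-Seitz condensed densities, and a
Gaussian cube writer for visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma

from .grids import MolecularGrid, cell_sums
from .system_io import (
    Geometry, GaussianShell, SpinOrbitalSet, SPINS,
    UnsupportedInputError,
)

FIELD_KINDS = ("AO", "MO", "density", "spin-density", "LRF-field")


@dataclass
class FieldOnGrid:
    """Scalar field sampled on grid points."""

    values: np.ndarray
    kind: str = "density"

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# real solid harmonics r^l * Y_lm (orthonormal real Y), Molden m-order
# 0, +1, -1, +2, -2, ...
# ---------------------------------------------------------------------------

def _solid_harmonics(l: int, x, y, z, r2):
    if l == 0:
        return [0.28209479177387814 * np.ones_like(x)]
    if l == 1:
        c = 0.4886025119029199
        return [c * z, c * x, c * y]
    if l == 2:
        return [
            0.31539156525252005 * (3 * z * z - r2),
            1.0925484305920792 * x * z,
            1.0925484305920792 * y * z,
            0.5462742152960396 * (x * x - y * y),
            1.0925484305920792 * x * y,
        ]
    if l == 3:
        return [
            0.3731763325901154 * z * (5 * z * z - 3 * r2),
            0.4570457994644658 * x * (5 * z * z - r2),
            0.4570457994644658 * y * (5 * z * z - r2),
            1.445305721320277 * z * (x * x - y * y),
            2.890611442640554 * x * y * z,
            0.5900435899266435 * x * (x * x - 3 * y * y),
            0.5900435899266435 * y * (3 * x * x - y * y),
        ]
    if l == 4:
        z2 = z * z
        return [
            0.10578554691520431 * (35 * z2 * z2 - 30 * z2 * r2 + 3 * r2 * r2),
            0.6690465435572892 * x * z * (7 * z2 - 3 * r2),
            0.6690465435572892 * y * z * (7 * z2 - 3 * r2),
            0.47308734787878004 * (x * x - y * y) * (7 * z2 - r2),
            0.9461746957575601 * x * y * (7 * z2 - r2),
            1.7701307697799304 * z * x * (x * x - 3 * y * y),
            1.7701307697799304 * z * y * (3 * x * x - y * y),
            0.6258357354491761 * (x**4 - 6 * x * x * y * y + y**4),
            2.5033429417967046 * x * y * (x * x - y * y),
        ]
    raise UnsupportedInputError(f"l={l} beyond supported maximum (4)")


# Molden cartesian component orders
_CART_ORDER = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [(3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
        (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1)],
    4: [(4, 0, 0), (0, 4, 0), (0, 0, 4), (3, 1, 0), (3, 0, 1),
        (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3), (2, 2, 0),
        (2, 0, 2), (0, 2, 2), (2, 1, 1), (1, 2, 1), (1, 1, 2)],
}


def _dfact(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _pure_primitive_norm(l: int, alpha: np.ndarray) -> np.ndarray:
    """Norm of r^l Y_lm exp(-alpha r^2) with orthonormal real Y."""
    return np.sqrt(2.0 * (2.0 * alpha) ** (l + 1.5) / gamma(l + 1.5))


def _cart_primitive_norm(ijk, alpha: np.ndarray) -> np.ndarray:
    i, j, k = ijk
    n = i + j + k
    pref = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (n / 2.0)
    return pref / math.sqrt(_dfact(2 * i - 1) * _dfact(2 * j - 1) * _dfact(2 * k - 1))


def eval_basis(shells: list[GaussianShell], geom: Geometry,
               points: np.ndarray) -> np.ndarray:
    """AO value matrix (M x N_AO) with Molden component ordering per shell."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    cols = []
    for sh in shells:
        d = points - geom.coords[sh.atom]
        x, y, z = d[:, 0], d[:, 1], d[:, 2]
        r2 = x * x + y * y + z * z
        expo = np.exp(-np.outer(r2, sh.exponents))  # (M, nprim)
        if sh.pure:
            norms = _pure_primitive_norm(sh.l, sh.exponents)
            radial = expo @ (sh.coefficients * norms)
            for s in _solid_harmonics(sh.l, x, y, z, r2):
                cols.append(radial * s)
        else:
            for ijk in _CART_ORDER[sh.l]:
                norms = _cart_primitive_norm(ijk, sh.exponents)
                radial = expo @ (sh.coefficients * norms)
                i, j, k = ijk
                cols.append(radial * x**i * y**j * z**k)
    return np.column_stack(cols)


def mo_values(ao_values: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    return ao_values @ coefficients


def density_on_grid(mos: SpinOrbitalSet, ao_values: np.ndarray
                    ) -> tuple[FieldOnGrid, FieldOnGrid]:
    """Total density rho = rho_a + rho_b and spin density rho_z = rho_a - rho_b."""
    per_spin = {}
    for s in SPINS:
        occ = mo_values(ao_values, mos.occupied(s))
        per_spin[s] = (occ * occ).sum(axis=1) if occ.size else np.zeros(len(ao_values))
    rho = FieldOnGrid(per_spin["alpha"] + per_spin["beta"], "density")
    rhoz = FieldOnGrid(per_spin["alpha"] - per_spin["beta"], "spin-density")
    return rho, rhoz


def numerical_overlap(ao_values: np.ndarray, grid: MolecularGrid,
                      asym_warn_tol: float = 1e-8) -> np.ndarray:
    """AO overlap by quadrature; exactly symmetrized after a symmetry check."""
    s = ao_values.T @ (ao_values * grid.base_weights[:, None])
    asym = np.abs(s - s.T).max() if s.size else 0.0
    if asym > asym_warn_tol:
        import warnings

        warnings.warn(
            f"numerical overlap asymmetry {asym:.2e} exceeds {asym_warn_tol:.0e}; "
            "grid may not cover the basis support", stacklevel=2,
        )
    return 0.5 * (s + s.T)


def condensed_density(fld: FieldOnGrid, grid: MolecularGrid) -> np.ndarray:
    """Per-atom Wigner-Seitz cell integrals of a field (sums to the total)."""
    return cell_sums(fld.values, grid)


# ---------------------------------------------------------------------------
# cube export
# ---------------------------------------------------------------------------

def cube_lattice(geom: Geometry, shape: int | tuple[int, int, int] = 80,
                 padding: float = 4.0):
    """Regular lattice covering the nuclei plus ``padding`` bohr on each side.

    Returns (origin, axes (3,3) step vectors, shape, points (M,3)) with
    x fastest varying last as the cube format requires.
    """
    if isinstance(shape, int):
        shape = (shape, shape, shape)
    lo = geom.coords.min(axis=0) - padding
    hi = geom.coords.max(axis=0) + padding
    axes = np.diag((hi - lo) / (np.array(shape) - 1))
    grids = [lo[k] + axes[k, k] * np.arange(shape[k]) for k in range(3)]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    return lo, axes, shape, pts


def write_cube(path, geom: Geometry, origin, axes, shape, values,
               comment: str = "", metadata: str = "") -> None:
    """Write a Gaussian cube file (atomic units)."""
    values = np.asarray(values, dtype=float).reshape(shape)
    lines = [comment or "spinlrf field", metadata or "generated by spinlrf"]
    lines.append(f"{geom.natoms:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}")
    for k in range(3):
        lines.append(
            f"{shape[k]:5d} {axes[k][0]:12.6f} {axes[k][1]:12.6f} {axes[k][2]:12.6f}"
        )
    for z, xyz in zip(geom.charges, geom.coords):
        lines.append(
            f"{z:5d} {float(z):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
        )
    flat = values.reshape(shape[0] * shape[1], shape[2])
    for row in flat:
        for start in range(0, len(row), 6):
            lines.append("".join(f"{v:13.5e}" for v in row[start:start + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
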