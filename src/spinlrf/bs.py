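"""Broken-symmetry wavefunction diagnostics.

Corresponding-orbital overlaps T_i between the alpha- and beta-occupied
spaces, the effective bond order b = sum T_i, the spin-projected bond order
B = sum 2 T_i / (1 + T_i^2), the diradical character y = 1 - B, natural
occupations 1 +/- T_i, the two-site closed form of the spin density, and the
on-top pair density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldOnGrid
from .system_io import SpinOrbitalSet


@dataclass
class BSDiagnostics:
    """Overlap spectrum and derived bond-order / radical-character indices.

    ``T`` is sorted ascending, so the magnetic pair (smallest overlap) is
    first.  ``y`` is the diradical character of that magnetic pair;
    ``y_pairs`` reports 1 - 2T/(1+T^2) for every tracked pair.
    """

    T: np.ndarray
    b: float
    B: float
    y: float
    y_pairs: np.ndarray
    n_bond: np.ndarray          # natural occupations 1 + T_i
    n_anti: np.ndarray          # natural occupations 1 - T_i
    n_unpaired_excess: int = 0
    spin_populations: np.ndarray | None = field(default=None)

    def to_json(self, path=None):
        payload = {
            "T": self.T.tolist(),
            "effective_bond_order_b": self.b,
            "projected_bond_order_B": self.B,
            "diradical_character_y": self.y,
            "y_per_pair": self.y_pairs.tolist(),
            "natural_occ_bond": self.n_bond.tolist(),
            "natural_occ_antibond": self.n_anti.tolist(),
            "n_unpaired_excess": self.n_unpaired_excess,
        }
        if self.spin_populations is not None:
            payload["spin_populations"] = self.spin_populations.tolist()
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    def table(self) -> str:
        lines = [
            f"{'pair':>4} {'T_i':>12} {'n_bond':>10} {'n_anti':>10} {'y_i':>10}",
        ]
        for i, (t, nb, na, y) in enumerate(
            zip(self.T, self.n_bond, self.n_anti, self.y_pairs)
        ):
            lines.append(f"{i + 1:>4} {t:>12.8f} {nb:>10.6f} {na:>10.6f} {y:>10.6f}")
        lines.append(
            f"b = {self.b:.8f}   B = {self.B:.8f}   y(magnetic pair) = {self.y:.8f}"
        )
        if self.n_unpaired_excess:
            lines.append(f"unpaired excess spin-orbitals: {self.n_unpaired_excess}")
        return "\n".join(lines)


def corresponding_overlaps(mos: SpinOrbitalSet, overlap: np.ndarray,
                           clip_tol: float = 1e-6) -> np.ndarray:
    """Singular values of C_alpha,occ^T S C_beta,occ, sorted ascending.

    These are the corresponding-orbital overlaps T_i in [0, 1].  Values may
    exceed 1 by the accuracy of the overlap matrix itself (quadrature
    overlaps are good to ~1e-7 at production grids); excursions within
    ``clip_tol`` are clipped to the bound, anything larger marks an
    inconsistent overlap matrix.
    """
    c_a = mos.occupied("alpha")
    c_b = mos.occupied("beta")
    if c_a.shape[1] == 0 or c_b.shape[1] == 0:
        return np.zeros(0)
    block = c_a.T @ np.asarray(overlap, dtype=float) @ c_b
    t = np.linalg.svd(block, compute_uv=False)
    if t.size and t.max() > 1.0 + clip_tol:
        raise ValueError(
            f"corresponding-orbital overlap {t.max():.10f} > 1: "
            "overlap matrix inconsistent with the orbital sets"
        )
    t = np.minimum(np.clip(t, 0.0, None), 1.0)
    return np.sort(t)


def bond_order_indices(T: np.ndarray,
                       n_unpaired_excess: int = 0) -> BSDiagnostics:
    """Bond-order and diradical-character indices from an overlap spectrum."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any((T < 0) | (T > 1)):
        raise ValueError("corresponding overlaps must lie in [0, 1]")
    T = np.sort(T)
    b = float(T.sum())
    per_pair_B = 2.0 * T / (1.0 + T * T)
    B = float(per_pair_B.sum())
    y_pairs = 1.0 - per_pair_B
    y = float(y_pairs[0]) if T.size else 0.0
    return BSDiagnostics(
        T=T, b=b, B=B, y=y, y_pairs=y_pairs,
        n_bond=1.0 + T, n_anti=1.0 - T,
        n_unpaired_excess=n_unpaired_excess,
    )


def diagnose(mos: SpinOrbitalSet, overlap: np.ndarray) -> BSDiagnostics:
    """Full diagnostics from a spin-orbital set and an AO overlap matrix.

    For unequal occupation counts (net-spin systems) only the
    min(N_alpha, N_beta) corresponding pairs enter b, B and y; the excess
    spin-orbitals are counted separately.
    """
    t = corresponding_overlaps(mos, overlap)
    excess = abs(mos.n_occ("alpha") - mos.n_occ("beta"))
    return bond_order_indices(t, n_unpaired_excess=excess)


def two_site_spin_density(b: float, chi1_sq: np.ndarray,
                          chi2_sq: np.ndarray) -> FieldOnGrid:
    """Closed-form two-site spin density sqrt(1-b^2) (chi1^2 - chi2^2).

    The analytic reference against grid-evaluated spin densities for the
    two-site broken-symmetry model; b is the effective bond order.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("bond order b must lie in [0, 1]")
    amp = np.sqrt(1.0 - b * b)
    return FieldOnGrid(amp * (np.asarray(chi1_sq) - np.asarray(chi2_sq)),
                       "spin-density")


def ontop_pair_density(rho: FieldOnGrid, rhoz: FieldOnGrid) -> FieldOnGrid:
    """Same-point alpha-beta pair density (rho^2 - rho_z^2) / 2 = 2 rho_a rho_b."""
    if rho.values.shape != rhoz.values.shape:
        raise ValueError("density and spin density must share one grid")
    return FieldOnGrid(0.5 * (rho.values**2 - rhoz.values**2), "density")
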