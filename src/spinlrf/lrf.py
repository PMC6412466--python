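"""Sum-over-states linear response of electron density and spin density.

The bare (uncoupled) orbital response is assembled from occupied-virtual
orbital-product moments integrated over Wigner-Seitz cells,

    K[I, J] = sum_sigma sum_i sum_a  M[i,a,I] M[i,a,J] / (e_i - e_a),

with strictly negative denominators (occupied minus virtual energies), so a
negative K[I, J] means the density at atom I increases under an attractive
perturbation at atom J.  The spin-density response is the difference of the
per-channel sums, driven by a virtual magnetic-field probe.  Perturbations
are virtual: only the orbitals and their energies enter.

The factorized route (cell moments first, then an atom-pair contraction)
never forms the full two-point kernel chi(r, r'), which would be quadratic
in grid size.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldOnGrid, eval_basis, mo_values
from .grids import MolecularGrid
from .system_io import Geometry, SpinOrbitalSet, SPINS


class NearDegeneracyError(ArithmeticError):
    """Occupied-virtual gap too small for the sum-over-states formula."""


class OracleInvalidError(ValueError):
    """Finite-difference perturbation strong enough to reorder orbitals."""


LRF_KINDS = ("density", "spin")


@dataclass
class TransitionMoments:
    """Cell-integrated occupied x virtual orbital products per spin channel.

    moments[s][i, a, A] = integral over cell A of psi_i^s psi_a^s;
    denominators[s][i, a] = e_i^s - e_a^s < 0.
    """

    moments: dict[str, np.ndarray]
    denominators: dict[str, np.ndarray]
    natoms: int
    closed_shell: bool = False

    def channel_sum(self, spin: str) -> np.ndarray:
        m = self.moments[spin]
        if m.size == 0:
            n = self.natoms
            return np.zeros((n, n))
        return np.einsum("iaI,iaJ,ia->IJ", m, m, 1.0 / self.denominators[spin])


def transition_moments(mos: SpinOrbitalSet, grid: MolecularGrid,
                       ao_values: np.ndarray, gap_tol: float = 1e-6,
                       virtual_cutoff: float | None = None) -> TransitionMoments:
    """Integrate all occupied-virtual orbital products over every cell.

    ``virtual_cutoff`` (hartree) optionally drops virtuals above the cutoff
    energy; the default includes every unoccupied orbital.  Any
    occupied-virtual gap below ``gap_tol`` raises
    :class:`NearDegeneracyError` naming the pair, because the response
    formula diverges there; no silent regularization is applied.
    """
    moments: dict[str, np.ndarray] = {}
    denoms: dict[str, np.ndarray] = {}
    natoms = grid.natoms
    for s in SPINS:
        occ_c = mos.occupied(s)
        virt_c = mos.virtual(s)
        e = mos.energies[s]
        e_occ = e[mos.occupations[s] == 1]
        e_virt = e[mos.occupations[s] == 0]
        if virtual_cutoff is not None:
            keep = e_virt <= virtual_cutoff
            virt_c = virt_c[:, keep]
            e_virt = e_virt[keep]
        d = e_occ[:, None] - e_virt[None, :]
        if d.size:
            bad = np.argwhere(np.abs(d) < gap_tol)
            if len(bad):
                i, a = bad[0]
                raise NearDegeneracyError(
                    f"near-degenerate occupied-virtual pair in {s} channel: "
                    f"occ #{i + 1} (e={e_occ[i]:.8f}) vs virt #{a + 1} "
                    f"(e={e_virt[a]:.8f}), |gap| < {gap_tol:g} hartree"
                )
        occ_v = mo_values(ao_values, occ_c)     # (M, nocc)
        virt_v = mo_values(ao_values, virt_c)   # (M, nvirt)
        m = np.zeros((occ_v.shape[1], virt_v.shape[1], natoms))
        for atom in range(natoms):
            mask = grid.owner_atom == atom
            w = grid.base_weights[mask]
            m[:, :, atom] = occ_v[mask].T @ (virt_v[mask] * w[:, None])
        moments[s] = m
        denoms[s] = d
    return TransitionMoments(
        moments=moments, denominators=denoms, natoms=natoms,
        closed_shell=mos.is_closed_shell(),
    )


@dataclass
class CondensedLRF:
    """Atom-condensed response matrix K[I, J] with provenance metadata.

    The perturbing index J refers to the Wigner-Seitz cell of atom J; the
    probe potentials are virtual and carry no stored values.
    """

    matrix: np.ndarray
    kind: str
    atom_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LRF_KINDS:
            raise ValueError(f"kind must be one of {LRF_KINDS}")
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def natoms(self) -> int:
        return self.matrix.shape[0]

    def symmetry_residual(self) -> float:
        return float(np.abs(self.matrix - self.matrix.T).max())

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["atom"] + self.atom_labels)
            for label, row in zip(self.atom_labels, self.matrix):
                writer.writerow([label] + [f"{v:.12e}" for v in row])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "atom_labels": self.atom_labels,
                    "matrix": self.matrix.tolist(),
                    "provenance": self.metadata,
                },
                fh, indent=1,
            )

    @classmethod
    def from_csv(cls, path, kind: str = "density") -> "CondensedLRF":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        labels = rows[0][1:]
        matrix = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
        return cls(matrix=matrix, kind=kind, atom_labels=labels)


def _provenance(mos: SpinOrbitalSet, grid: MolecularGrid,
                virtual_cutoff: float | None) -> dict:
    h = hashlib.sha256()
    for s in SPINS:
        h.update(mos.coefficients[s].tobytes())
        h.update(mos.energies[s].tobytes())
    return {
        "orbital_hash": h.hexdigest()[:16],
        "n_radial": grid.n_radial,
        "n_angular": grid.n_angular,
        "virtual_cutoff": virtual_cutoff,
    }


def condensed_lrf_density(tm: TransitionMoments,
                          atom_labels: list[str] | None = None,
                          metadata: dict | None = None) -> CondensedLRF:
    """delta rho(I) / delta v(J): spin-summed condensed response matrix."""
    k = tm.channel_sum("alpha") + tm.channel_sum("beta")
    labels = atom_labels or [f"atom({i + 1})" for i in range(tm.natoms)]
    return CondensedLRF(matrix=k, kind="density", atom_labels=labels,
                        metadata=metadata or {})


def condensed_lrf_spin(tm: TransitionMoments,
                       atom_labels: list[str] | None = None,
                       metadata: dict | None = None) -> CondensedLRF:
    """delta rho_z(I) / delta v_m(J): alpha-channel minus beta-channel sums.

    For bit-identical channels the response vanishes identically and an
    explicit zero matrix is returned without summation.
    """
    labels = atom_labels or [f"atom({i + 1})" for i in range(tm.natoms)]
    if tm.closed_shell:
        k = np.zeros((tm.natoms, tm.natoms))
    else:
        k = tm.channel_sum("alpha") - tm.channel_sum("beta")
    return CondensedLRF(matrix=k, kind="spin", atom_labels=labels,
                        metadata=metadata or {})


def compute_lrf(geom: Geometry, shells, mos: SpinOrbitalSet,
                grid: MolecularGrid, spin: bool = False,
                gap_tol: float = 1e-6,
                virtual_cutoff: float | None = None) -> CondensedLRF:
    """End-to-end convenience: basis values -> moments -> condensed matrix."""
    ao = eval_basis(shells, geom, grid.points)
    tm = transition_moments(mos, grid, ao, gap_tol=gap_tol,
                            virtual_cutoff=virtual_cutoff)
    meta = _provenance(mos, grid, virtual_cutoff)
    build = condensed_lrf_spin if spin else condensed_lrf_density
    return build(tm, atom_labels=geom.labels(), metadata=meta)


def lrf_field(mos: SpinOrbitalSet, tm: TransitionMoments, geom: Geometry,
              shells, perturbing_atom: int, points: np.ndarray,
              spin: bool = False) -> FieldOnGrid:
    """Pointwise response field delta rho(r)/delta v(J) on arbitrary points.

    ``perturbing_atom`` is 0-based.  The field is the sum-over-states kernel
    contracted with the cell-J moments; integrating it over all cells
    reproduces column J of the condensed matrix.
    """
    if not 0 <= perturbing_atom < tm.natoms:
        raise IndexError(f"perturbing atom {perturbing_atom} out of range")
    ao = eval_basis(shells, geom, points)
    total = np.zeros(len(points))
    for s, sgn in (("alpha", 1.0), ("beta", -1.0 if spin else 1.0)):
        m = tm.moments[s]
        if m.size == 0:
            continue
        coef = m[:, :, perturbing_atom] / tm.denominators[s]  # (nocc, nvirt)
        occ_v = mo_values(ao, mos.occupied(s))
        virt_v = mo_values(ao, mos.virtual(s))
        nv = coef.shape[1]
        total += sgn * np.einsum("mi,ia,ma->m", occ_v, coef, virt_v[:, :nv])
    kind = "LRF-field"
    if spin and tm.closed_shell:
        total = np.zeros(len(points))
    return FieldOnGrid(total, kind)


def finite_difference_oracle(mos: SpinOrbitalSet, grid: MolecularGrid,
                             ao_values: np.ndarray, perturbing_atom: int,
                             lam: float = 1e-4) -> np.ndarray:
    """First-order perturbation-theory check of the condensed density response.

    Applies the one-electron perturbation V_J = lam * 1_{cell J}(r)
    non-self-consistently: occupied orbitals are mixed with virtuals by
    first-order theory, densities are recomputed on the grid and condensed,
    and the per-atom change divided by the perturbation strength is
    returned.  The raw first-order density change for real orbitals carries
    a factor 2 relative to the single-sided sum-over-states convention used
    by the condensed matrices, so the result is halved to sit on the same
    scale; it converges to column J of the condensed density response as
    lam -> 0.
    """
    if lam == 0.0:
        return np.zeros(grid.natoms)
    mask = grid.owner_atom == perturbing_atom
    w_cell = np.where(mask, grid.base_weights, 0.0)
    delta = np.zeros(grid.natoms)
    for s in SPINS:
        occ_c = mos.occupied(s)
        virt_c = mos.virtual(s)
        e = mos.energies[s]
        e_occ = e[mos.occupations[s] == 1]
        e_virt = e[mos.occupations[s] == 0]
        if e_occ.size and e_virt.size:
            min_gap = np.abs(e_occ[:, None] - e_virt[None, :]).min()
            if lam >= 0.5 * min_gap:
                raise OracleInvalidError(
                    f"perturbation strength {lam} is comparable to the minimal "
                    f"occupied-virtual gap {min_gap:.3e}; orbital ordering unsafe"
                )
        occ_v = mo_values(ao_values, occ_c)
        virt_v = mo_values(ao_values, virt_c)
        # V in the occ x virt block, V_ai = lam * <a| 1_cell |i>
        v_block = lam * (virt_v.T @ (occ_v * w_cell[:, None]))  # (nvirt, nocc)
        mix = v_block.T / (e_occ[:, None] - e_virt[None, :])    # (nocc, nvirt)
        occ_pert = occ_v + virt_v @ mix.T
        drho = (occ_pert * occ_pert).sum(axis=1) - (occ_v * occ_v).sum(axis=1)
        delta += np.bincount(grid.owner_atom,
                             weights=grid.base_weights * drho,
                             minlength=grid.natoms)
    return delta / (2.0 * lam)
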