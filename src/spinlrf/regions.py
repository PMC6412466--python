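"""Threshold sections, QM-region suggestion and model-error reports.

A "section" of a condensed response matrix is the set of atom pairs whose
entry exceeds a signed threshold; the conventional thresholds are 0.1, 0.01
and 0.001 and sections nest monotonically.  The QM-region rule selects every
atom whose maximal coupling to a reaction-center atom reaches the density or
spin threshold, optionally completed to whole covalent fragments so cut
bonds are chemically cappable.  All atom indices in the public API are
1-based, matching report and figure numbering.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .lrf import CondensedLRF
from .system_io import Geometry, BOHR_PER_ANGSTROM

# Covalent radii (Cordero et al. 2008), angstrom; pinned for reproducible
# connectivity in fragment completion.
COVALENT_RADII_ANGSTROM = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
}


@dataclass
class SectionSet:
    """Atom pairs whose response entries pass a signed threshold."""

    threshold: float
    sign: str
    mask: np.ndarray           # boolean (N, N)
    atom_counts: np.ndarray    # per-atom number of passing partners

    @property
    def n_pairs(self) -> int:
        return int(self.mask.sum())

    def contains(self, other: "SectionSet") -> bool:
        """True when every pair of ``other`` is also in this section."""
        return bool(np.all(~other.mask | self.mask))


def threshold_sections(k: CondensedLRF, tau: float, sign: str = "+") -> SectionSet:
    """Mark entries with K > tau (sign '+') or K < -tau (sign '-')."""
    if tau <= 0:
        raise ValueError("threshold must be positive")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    mask = k.matrix > tau if sign == "+" else k.matrix < -tau
    return SectionSet(threshold=tau, sign=sign, mask=mask,
                      atom_counts=mask.sum(axis=1))


@dataclass
class RegionSuggestion:
    """QM-region proposal from reaction-center couplings.

    ``selected`` holds 1-based atom indices; ``rule`` maps each selected
    atom to how it entered ('reaction-center', 'density', 'spin' or
    'fragment-completion').  ``cut_bonds`` lists covalent bonds crossing the
    boundary (capping sites); geometry editing is left to the user.
    """

    reaction_center: list[int]
    tau_rho: float
    tau_m: float
    coupling_rho: np.ndarray
    coupling_spin: np.ndarray
    selected: list[int]
    rule: dict[int, str] = field(default_factory=dict)
    cut_bonds: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self, path=None):
        payload = {
            "reaction_center": self.reaction_center,
            "tau_rho": self.tau_rho,
            "tau_m": self.tau_m,
            "selected": self.selected,
            "rule": {str(k): v for k, v in self.rule.items()},
            "cut_bonds": [list(b) for b in self.cut_bonds],
            "coupling_rho": self.coupling_rho.tolist(),
            "coupling_spin": self.coupling_spin.tolist(),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload


def covalent_bonds(geom: Geometry, scale: float = 1.3) -> list[tuple[int, int]]:
    """Bonded pairs (1-based) where distance < scale * sum of covalent radii."""
    radii = np.array([
        COVALENT_RADII_ANGSTROM.get(s, 1.5) * BOHR_PER_ANGSTROM
        for s in geom.symbols
    ])
    bonds = []
    for i in range(geom.natoms):
        for j in range(i + 1, geom.natoms):
            cut = scale * (radii[i] + radii[j])
            if np.linalg.norm(geom.coords[i] - geom.coords[j]) < cut:
                bonds.append((i + 1, j + 1))
    return bonds


def _fragments(natoms: int, bonds: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(natoms + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bonds:
        parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for a in range(1, natoms + 1):
        groups.setdefault(find(a), set()).add(a)
    return list(groups.values())


def suggest_qm_region(k_rho: CondensedLRF, k_spin: CondensedLRF,
                      reaction_center: list[int],
                      tau_rho: float = 0.01, tau_m: float = 0.01,
                      complete_fragments: bool = False,
                      geometry: Geometry | None = None) -> RegionSuggestion:
    """Select atoms coupled to the reaction center beyond either threshold.

    Atom J enters when max over RC atoms I of |K_rho[I, J]| >= tau_rho or
    the same for the spin matrix and tau_m; the reaction center itself is
    always included.  With ``complete_fragments`` (requires ``geometry``)
    the selection grows to whole covalently connected fragments.
    """
    if not reaction_center:
        raise ValueError("reaction center must be non-empty")
    n = k_rho.natoms
    if k_spin.natoms != n:
        raise ValueError("matrices must share atom labeling")
    rc0 = [a - 1 for a in reaction_center]
    for a in rc0:
        if not 0 <= a < n:
            raise IndexError(f"reaction-center atom {a + 1} outside system (1..{n})")

    c_rho = np.abs(k_rho.matrix[rc0, :]).max(axis=0)
    c_spin = np.abs(k_spin.matrix[rc0, :]).max(axis=0)

    rule: dict[int, str] = {a: "reaction-center" for a in reaction_center}
    for j in range(n):
        lab = j + 1
        if lab in rule:
            continue
        if c_rho[j] >= tau_rho:
            rule[lab] = "density"
        elif c_spin[j] >= tau_m:
            rule[lab] = "spin"
    selected = set(rule)

    cut_bonds: list[tuple[int, int]] = []
    if complete_fragments:
        if geometry is None:
            raise ValueError("fragment completion requires a geometry")
        bonds = covalent_bonds(geometry)
        for frag in _fragments(n, bonds):
            if frag & selected:
                for a in frag - selected:
                    rule[a] = "fragment-completion"
                selected |= frag
        cut_bonds = [b for b in bonds
                     if (b[0] in selected) != (b[1] in selected)]
    elif geometry is not None:
        cut_bonds = [b for b in covalent_bonds(geometry)
                     if (b[0] in selected) != (b[1] in selected)]

    return RegionSuggestion(
        reaction_center=sorted(reaction_center), tau_rho=tau_rho, tau_m=tau_m,
        coupling_rho=c_rho, coupling_spin=c_spin,
        selected=sorted(selected), rule=rule, cut_bonds=cut_bonds,
    )


@dataclass
class ModelErrorReport:
    """Per-atom density and spin-density errors of a cluster model.

    Errors are model minus full-model values over the mapped common atoms
    (the sign convention is stated in every exported header).
    """

    model_label: str
    atom_map: dict[int, int]           # model atom (1-based) -> full atom
    delta_rho: dict[int, float]        # keyed by full-model atom
    delta_rhoz: dict[int, float]
    max_abs_rho: float
    max_abs_rhoz: float

    def to_json(self, path=None):
        payload = {
            "model": self.model_label,
            "sign_convention": "model - full",
            "atom_map": {str(k): v for k, v in self.atom_map.items()},
            "delta_rho": {str(k): v for k, v in self.delta_rho.items()},
            "delta_rhoz": {str(k): v for k, v in self.delta_rhoz.items()},
            "max_abs_delta_rho": self.max_abs_rho,
            "max_abs_delta_rhoz": self.max_abs_rhoz,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload


def model_error_report(full_rho: np.ndarray, full_rhoz: np.ndarray,
                       model_rho: np.ndarray, model_rhoz: np.ndarray,
                       atom_map: dict[int, int],
                       model_label: str = "model") -> ModelErrorReport:
    """Differences (model - full) of condensed densities over mapped atoms.

    ``atom_map`` maps 1-based model atoms to 1-based full-model atoms and
    must be injective.
    """
    if len(set(atom_map.values())) != len(atom_map):
        raise ValueError("atom_map must be injective")
    d_rho: dict[int, float] = {}
    d_rhoz: dict[int, float] = {}
    for m_atom, f_atom in atom_map.items():
        if not 1 <= m_atom <= len(model_rho):
            raise KeyError(f"model atom {m_atom} outside model system")
        if not 1 <= f_atom <= len(full_rho):
            raise KeyError(f"full-model atom {f_atom} outside full system")
        d_rho[f_atom] = float(model_rho[m_atom - 1] - full_rho[f_atom - 1])
        d_rhoz[f_atom] = float(model_rhoz[m_atom - 1] - full_rhoz[f_atom - 1])
    return ModelErrorReport(
        model_label=model_label, atom_map=dict(atom_map),
        delta_rho=d_rho, delta_rhoz=d_rhoz,
        max_abs_rho=max((abs(v) for v in d_rho.values()), default=0.0),
        max_abs_rhoz=max((abs(v) for v in d_rhoz.values()), default=0.0),
    )


def heatmap_export(k: CondensedLRF, path, color_rule: dict | None = None) -> None:
    """Atom-labeled CSV of the matrix plus a JSON sidecar with metadata."""
    k.to_csv(path)
    sidecar = {
        "kind": k.kind,
        "thresholds": [0.1, 0.01, 0.001],
        "color_rule": color_rule or {"positive": "blue", "negative": "red"},
        "provenance": k.metadata,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
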