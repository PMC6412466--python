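"""Molecular geometries, Gaussian basis shells, and spin-resolved orbital sets.

Reads and writes Molden orbital files, reads XYZ geometries, and constructs
analytic broken-symmetry toy systems (two-site and multi-pair) whose orbitals
are exact linear combinations of symmetrically orthogonalized s-Gaussian site
functions.  Everything internal is in atomic units (bohr, hartree).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

# CODATA 2014, pinned for reproducibility
ANGSTROM_PER_BOHR = 0.52917721067
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

_ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe",
]
SYMBOL_TO_Z = {s: z for z, s in enumerate(_ELEMENTS) if z}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

_ANGMOM = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}
_ANGMOM_LETTER = {v: k for k, v in _ANGMOM.items()}

MAX_ANGULAR_MOMENTUM = 4


class MoldenParseError(ValueError):
    """Raised when a Molden file is missing sections or malformed."""


class UnsupportedInputError(ValueError):
    """Raised for inputs outside the supported model (fractional occupations, l > 4)."""


class ValidationError(ValueError):
    """Raised when loaded data fails a consistency check."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Atomic symbols, nuclear charges and positions (bohr).

    Atom indices are 0-based internally; all user-facing reports are 1-based.
    """

    symbols: list[str]
    charges: np.ndarray      # integer nuclear charges
    coords: np.ndarray       # (N, 3), bohr

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.symbols)
        if n < 1:
            raise ValidationError("geometry must contain at least one atom")
        if self.coords.shape != (n, 3) or self.charges.shape != (n,):
            raise ValidationError("inconsistent geometry array shapes")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite atomic coordinates")
        if n > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() <= 1e-6:
                raise ValidationError(
                    f"coincident atoms (min pairwise distance {d.min():.2e} bohr)"
                )

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    def labels(self) -> list[str]:
        """1-based atom labels such as 'Fe(1)'."""
        return [f"{s}({i + 1})" for i, s in enumerate(self.symbols)]


@dataclass
class GaussianShell:
    """One contracted Gaussian shell.

    ``coefficients`` follow the Molden convention: they multiply primitives
    that are individually normalized; primitive norms are applied at
    evaluation time so that files round-trip verbatim.
    """

    atom: int                # 0-based atom index
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray
    pure: bool = True        # real solid harmonics vs cartesian components

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.l < 0 or self.l > MAX_ANGULAR_MOMENTUM:
            raise UnsupportedInputError(f"angular momentum l={self.l} not supported")
        if self.exponents.size == 0:
            raise ValidationError("shell with no primitives")
        if np.any(self.exponents <= 0):
            raise ValidationError("non-positive primitive exponent")

    @property
    def n_functions(self) -> int:
        return 2 * self.l + 1 if self.pure else (self.l + 1) * (self.l + 2) // 2

    def self_overlap(self) -> float:
        """Analytic ⟨shell|shell⟩ for the contraction over normalized primitives."""
        a = self.exponents
        c = self.coefficients
        cross = (2.0 * np.sqrt(np.outer(a, a)) / np.add.outer(a, a)) ** (self.l + 1.5)
        return float(c @ cross @ c)


SPINS = ("alpha", "beta")


@dataclass
class SpinOrbitalSet:
    """Per-spin MO coefficients (AO x MO), energies (hartree), occupations (0/1).

    Within each channel, occupied orbitals precede virtuals; each block is
    sorted by orbital energy.
    """

    coefficients: dict[str, np.ndarray]
    energies: dict[str, np.ndarray]
    occupations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for s in SPINS:
            if s not in self.coefficients:
                raise ValidationError(f"missing spin channel {s!r}")
            self.coefficients[s] = np.asarray(self.coefficients[s], dtype=float)
            self.energies[s] = np.asarray(self.energies[s], dtype=float)
            occ = np.asarray(self.occupations[s])
            if not np.all(np.isin(occ, (0, 1))):
                raise UnsupportedInputError(
                    "occupations must be exactly 0 or 1 per spin channel"
                )
            self.occupations[s] = occ.astype(int)
            nao, nmo = self.coefficients[s].shape
            if nmo > nao:
                raise ValidationError("more MOs than AOs")
            if self.energies[s].shape != (nmo,) or occ.shape != (nmo,):
                raise ValidationError("MO metadata shape mismatch")
        self._canonical_sort()

    def _canonical_sort(self) -> None:
        for s in SPINS:
            occ = self.occupations[s]
            e = self.energies[s]
            # occupied first, then by energy (stable)
            order = np.lexsort((e, -occ))
            self.coefficients[s] = self.coefficients[s][:, order]
            self.energies[s] = e[order]
            self.occupations[s] = occ[order]

    @property
    def n_ao(self) -> int:
        return self.coefficients["alpha"].shape[0]

    def n_occ(self, spin: str) -> int:
        return int(self.occupations[spin].sum())

    def occupied(self, spin: str) -> np.ndarray:
        return self.coefficients[spin][:, self.occupations[spin] == 1]

    def virtual(self, spin: str) -> np.ndarray:
        return self.coefficients[spin][:, self.occupations[spin] == 0]

    @property
    def n_electrons(self) -> int:
        return self.n_occ("alpha") + self.n_occ("beta")

    def is_closed_shell(self) -> bool:
        """True when the two channels are bit-identical."""
        return all(
            np.array_equal(self.coefficients["alpha"], self.coefficients["beta"])
            and np.array_equal(self.energies["alpha"], self.energies["beta"])
            and np.array_equal(self.occupations["alpha"], self.occupations["beta"])
            for _ in (0,)
        )


@dataclass
class ToySystem:
    """Analytic broken-symmetry model built from s-Gaussian site functions.

    The alpha/beta occupied pairs follow the standard mixing
    psi_a = cos(theta) phi_bond + sin(theta) phi_anti,
    psi_b = cos(theta) phi_bond - sin(theta) phi_anti,
    with bond/antibond combinations of Loewdin-orthogonalized site functions,
    so corresponding-orbital overlaps are exactly cos(2 theta).
    """

    geometry: Geometry
    shells: list[GaussianShell]
    mos: SpinOrbitalSet
    thetas: np.ndarray                 # one mixing angle per magnetic pair
    eps_bond: float
    eps_anti: float
    separation: float
    exponent: float
    ao_overlap: np.ndarray = field(repr=False, default=None)  # analytic S

    @property
    def site_overlap(self) -> float:
        """Analytic overlap of two neighbouring normalized s sites."""
        z1, z2 = np.broadcast_to(np.asarray(self.exponent, dtype=float), (2,))
        return _s_overlap(z1, z2, self.separation)


def _s_overlap(z1: float, z2: float, r: float) -> float:
    """Two-center overlap of normalized s Gaussians (product theorem)."""
    return float(
        (4.0 * z1 * z2 / (z1 + z2) ** 2) ** 0.75
        * math.exp(-z1 * z2 / (z1 + z2) * r * r)
    )


# ---------------------------------------------------------------------------
# Molden reader / writer
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\s*\[([A-Za-z0-9 _]+)\]\s*(.*)$")


def _tokenize_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    header_args: dict[str, str] = {}
    current = None
    for raw in text.splitlines():
        m = _SECTION_RE.match(raw)
        if m:
            current = m.group(1).strip().lower()
            sections.setdefault(current, [])
            arg = m.group(2).strip()
            if arg:
                header_args[current] = arg
            continue
        if current is not None and raw.strip():
            sections[current].append(raw)
    sections["__args__"] = [f"{k}={v}" for k, v in header_args.items()]
    return sections


def _section_arg(sections: dict[str, list[str]], name: str) -> str:
    for entry in sections.get("__args__", []):
        k, _, v = entry.partition("=")
        if k == name:
            return v
    return ""


def read_molden(
    path,
    normalization_tol: float = 1e-4,
) -> tuple[Geometry, list[GaussianShell], SpinOrbitalSet]:
    """Parse a Molden file into geometry, basis shells and spin orbitals.

    Coordinates are converted to bohr; restricted files (occupations of 2)
    are duplicated into identical alpha/beta channels.  Shell contractions
    whose analytic self-overlap deviates from 1 by more than
    ``normalization_tol`` raise :class:`ValidationError`; smaller deviations
    are renormalized away.
    """
    with open(path) as fh:
        text = fh.read()
    sections = _tokenize_sections(text)

    for required in ("atoms", "gto", "mo"):
        if required not in sections:
            raise MoldenParseError(f"Molden file missing [{required.upper()}] section")

    # --- atoms ---
    unit = _section_arg(sections, "atoms").lower()
    to_bohr = 1.0 if unit.startswith("au") else BOHR_PER_ANGSTROM
    if unit and not (unit.startswith("au") or unit.startswith("angs")):
        raise MoldenParseError(f"unknown [Atoms] unit {unit!r}")
    symbols, charges, coords = [], [], []
    for line in sections["atoms"]:
        parts = line.split()
        if len(parts) < 6:
            raise MoldenParseError(f"bad [Atoms] line: {line!r}")
        symbols.append(parts[0].capitalize())
        charges.append(int(float(parts[2])))
        coords.append([float(x) * to_bohr for x in parts[3:6]])
    geom = Geometry(symbols, np.array(charges), np.array(coords))

    # --- spherical/cartesian flags ---
    pure_d = any(k in sections for k in ("5d", "5d7f", "5d10f"))
    pure_f = any(k in sections for k in ("7f", "5d7f"))
    pure_g = "9g" in sections

    def is_pure(l: int) -> bool:
        return {0: True, 1: True, 2: pure_d, 3: pure_f, 4: pure_g}[l]

    # --- GTO ---
    shells: list[GaussianShell] = []
    lines = sections["gto"]
    i = 0
    current_atom = None
    while i < len(lines):
        parts = lines[i].replace("D", "E").replace("d", "e").split()
        if len(parts) == 2 and parts[0].isdigit() and parts[1].isdigit():
            current_atom = int(parts[0]) - 1
            i += 1
            continue
        if parts[0].lower() in _ANGMOM:
            if current_atom is None:
                raise MoldenParseError("[GTO] shell before atom header")
            l = _ANGMOM[parts[0].lower()]
            nprim = int(parts[1])
            exps, coefs = [], []
            for k in range(nprim):
                i += 1
                p = lines[i].replace("D", "E").replace("d", "e").split()
                exps.append(float(p[0]))
                coefs.append(float(p[1]))
            shell = GaussianShell(current_atom, l, exps, coefs, pure=is_pure(l))
            s = shell.self_overlap()
            if abs(s - 1.0) > normalization_tol:
                raise ValidationError(
                    f"unnormalized contraction (self-overlap {s:.6f}) in "
                    f"{_ANGMOM_LETTER[l]} shell on atom {current_atom + 1}"
                )
            shell.coefficients = shell.coefficients / math.sqrt(s)
            shells.append(shell)
            i += 1
            continue
        if parts[0].lower() == "sp":
            raise UnsupportedInputError("sp shells not supported; split into s and p")
        raise MoldenParseError(f"unexpected [GTO] line: {lines[i]!r}")

    n_ao = sum(sh.n_functions for sh in shells)

    # --- MO ---
    entries = []  # (spin, energy, occ, coeff vector)
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        vec = np.zeros(n_ao)
        for idx, val in cur["coeffs"]:
            if not 1 <= idx <= n_ao:
                raise MoldenParseError(f"MO coefficient index {idx} out of range")
            vec[idx - 1] = val
        entries.append((cur["spin"], cur["energy"], cur["occ"], vec))
        cur = None

    for line in sections["mo"]:
        stripped = line.strip()
        key, _, val = stripped.partition("=")
        key_l = key.strip().lower()
        if key_l in ("sym", "ene", "spin", "occup") and _:
            if key_l == "sym" or (cur is not None and cur["coeffs"]):
                flush()
            if cur is None:
                cur = {"spin": "alpha", "energy": 0.0, "occ": 0.0, "coeffs": []}
            if key_l == "ene":
                cur["energy"] = float(val.replace("D", "E"))
            elif key_l == "spin":
                cur["spin"] = val.strip().lower()
            elif key_l == "occup":
                cur["occ"] = float(val.replace("D", "E"))
            continue
        parts = stripped.split()
        if len(parts) == 2:
            if cur is None:
                raise MoldenParseError("MO coefficient before MO header")
            cur["coeffs"].append((int(parts[0]), float(parts[1].replace("D", "E"))))
        else:
            raise MoldenParseError(f"unexpected [MO] line: {line!r}")
    flush()

    if not entries:
        raise MoldenParseError("no molecular orbitals found in [MO] section")

    has_beta = any(e[0] == "beta" for e in entries)
    coeffs = {s: [] for s in SPINS}
    energies = {s: [] for s in SPINS}
    occupations = {s: [] for s in SPINS}

    def push(spin, e, occ, vec):
        coeffs[spin].append(vec)
        energies[spin].append(e)
        occupations[spin].append(occ)

    for spin, e, occ, vec in entries:
        if spin not in SPINS:
            raise MoldenParseError(f"unknown spin label {spin!r}")
        if has_beta:
            if abs(occ - round(occ)) > 1e-8 or round(occ) not in (0, 1):
                raise UnsupportedInputError(
                    f"fractional occupation {occ} in unrestricted file"
                )
            push(spin, e, int(round(occ)), vec)
        else:
            # restricted file: duplicate into identical channels
            if abs(occ - round(occ)) > 1e-8 or round(occ) not in (0, 1, 2):
                raise UnsupportedInputError(f"fractional occupation {occ}")
            occ = int(round(occ))
            push("alpha", e, 1 if occ >= 1 else 0, vec)
            push("beta", e, 1 if occ == 2 else 0, vec)

    mos = SpinOrbitalSet(
        coefficients={s: np.array(coeffs[s]).T for s in SPINS},
        energies={s: np.array(energies[s]) for s in SPINS},
        occupations={s: np.array(occupations[s]) for s in SPINS},
    )
    return geom, shells, mos


def write_molden(path, geom: Geometry, shells: list[GaussianShell],
                 mos: SpinOrbitalSet) -> None:
    """Write a Molden file (AU coordinates, spherical-harmonic markers as needed)."""
    out = ["[Molden Format]"]
    if any(sh.pure for sh in shells if sh.l == 2):
        out.append("[5D]")
    if any(sh.pure for sh in shells if sh.l == 3):
        out.append("[7F]")
    if any(sh.pure for sh in shells if sh.l == 4):
        out.append("[9G]")
    out.append("[Atoms] AU")
    for i, (sym, z, xyz) in enumerate(zip(geom.symbols, geom.charges, geom.coords)):
        out.append(
            f"{sym:4s} {i + 1:4d} {z:4d} "
            f"{xyz[0]: .14e} {xyz[1]: .14e} {xyz[2]: .14e}"
        )
    out.append("[GTO]")
    for atom in range(geom.natoms):
        out.append(f"{atom + 1} 0")
        for sh in shells:
            if sh.atom != atom:
                continue
            out.append(f" {_ANGMOM_LETTER[sh.l]} {len(sh.exponents)} 1.00")
            for a, c in zip(sh.exponents, sh.coefficients):
                out.append(f"   {a: .14e} {c: .14e}")
        out.append("")
    out.append("[MO]")
    for spin in SPINS:
        c = mos.coefficients[spin]
        for k in range(c.shape[1]):
            out.append(f" Sym= a{k + 1}")
            out.append(f" Ene= {mos.energies[spin][k]: .14e}")
            out.append(f" Spin= {spin.capitalize()}")
            out.append(f" Occup= {mos.occupations[spin][k]:d}")
            for iao, val in enumerate(c[:, k]):
                out.append(f"  {iao + 1:4d} {val: .14e}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_xyz(path) -> Geometry:
    """Read an XYZ file (angstrom) into a :class:`Geometry` (bohr)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0].capitalize())
        coords.append([float(x) * BOHR_PER_ANGSTROM for x in parts[1:4]])
    charges = [SYMBOL_TO_Z[s] for s in symbols]
    return Geometry(symbols, np.array(charges), np.array(coords))


# ---------------------------------------------------------------------------
# analytic toy systems
# ---------------------------------------------------------------------------

def _two_site_mo_vectors(theta: float, s12: float) -> np.ndarray:
    """AO-basis coefficients for (occ_a, occ_b, virt_a, virt_b).

    AO basis is the two normalized, non-orthogonal s sites with overlap s12;
    bond/antibond combinations act on the Loewdin-orthogonalized sites.
    """
    nb = 1.0 / math.sqrt(2.0 * (1.0 + s12))
    na = 1.0 / math.sqrt(2.0 * (1.0 - s12))
    bond = np.array([nb, nb])
    anti = np.array([na, -na])
    c, s = math.cos(theta), math.sin(theta)
    occ_a = c * bond + s * anti
    occ_b = c * bond - s * anti
    virt_a = -s * bond + c * anti
    virt_b = s * bond + c * anti
    return np.array([occ_a, occ_b, virt_a, virt_b])


def build_two_site_toy(
    theta: float,
    eps_bond: float = -0.5,
    eps_anti: float = -0.1,
    separation: float = 1.4,
    exponent=1.0,
) -> ToySystem:
    """Two-electron two-site broken-symmetry model.

    One s-Gaussian site on each of two H-like centers ``separation`` bohr
    apart along z.  The occupied alpha/beta pair mixes the bond and antibond
    combinations by ``theta``; the virtuals are the orthogonal complements.
    ``exponent`` may be a pair (z1, z2) for an asymmetric dimer, which makes
    the spin response matrix nonzero (the symmetric dimer's vanishes by
    mirror symmetry).
    """
    if eps_bond >= eps_anti:
        raise ValueError(
            f"degenerate or inverted gap: eps_bond={eps_bond} >= eps_anti={eps_anti}"
        )
    if separation <= 0:
        raise ValueError("separation must be positive")
    z1, z2 = np.broadcast_to(np.asarray(exponent, dtype=float), (2,))
    geom = Geometry(
        ["H", "H"], np.array([1, 1]),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, separation]]),
    )
    shells = [
        GaussianShell(0, 0, [z1], [1.0]),
        GaussianShell(1, 0, [z2], [1.0]),
    ]
    s12 = _s_overlap(z1, z2, separation)
    occ_a, occ_b, virt_a, virt_b = _two_site_mo_vectors(theta, s12)
    mos = SpinOrbitalSet(
        coefficients={
            "alpha": np.column_stack([occ_a, virt_a]),
            "beta": np.column_stack([occ_b, virt_b]),
        },
        energies={s: np.array([eps_bond, eps_anti]) for s in SPINS},
        occupations={s: np.array([1, 0]) for s in SPINS},
    )
    return ToySystem(
        geometry=geom, shells=shells, mos=mos,
        thetas=np.array([theta]), eps_bond=eps_bond, eps_anti=eps_anti,
        separation=separation, exponent=exponent,
        ao_overlap=np.array([[1.0, s12], [s12, 1.0]]),
    )


def build_multi_pair_toy(
    thetas,
    eps_bond: float = -0.5,
    eps_anti: float = -0.1,
    separation: float = 1.4,
    exponent: float = 1.0,
    pair_spacing: float = 50.0,
) -> ToySystem:
    """Several independent two-site magnetic pairs, one mixing angle each.

    Pairs are placed ``pair_spacing`` bohr apart so inter-pair overlaps are
    negligible (< 1e-100 at the default spacing) and the block-diagonal
    construction is exact to machine precision.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    k = len(thetas)
    coords, shells = [], []
    s12 = math.exp(-exponent * separation**2 / 2.0)
    nao = 2 * k
    c_a = np.zeros((nao, nao))
    c_b = np.zeros((nao, nao))
    for p, th in enumerate(thetas):
        base = p * pair_spacing
        coords += [[base, 0.0, 0.0], [base, 0.0, separation]]
        shells += [
            GaussianShell(2 * p, 0, [exponent], [1.0]),
            GaussianShell(2 * p + 1, 0, [exponent], [1.0]),
        ]
        occ_a, occ_b, virt_a, virt_b = _two_site_mo_vectors(th, s12)
        sl = slice(2 * p, 2 * p + 2)
        c_a[sl, p] = occ_a
        c_a[sl, k + p] = virt_a
        c_b[sl, p] = occ_b
        c_b[sl, k + p] = virt_b
    # spread energies slightly so sorting is deterministic
    e_occ = eps_bond + 1e-3 * np.arange(k)
    e_virt = eps_anti + 1e-3 * np.arange(k)
    geom = Geometry(["H"] * nao, np.ones(nao, dtype=int), np.array(coords))
    s_full = np.eye(nao)
    for p in range(k):
        s_full[2 * p, 2 * p + 1] = s_full[2 * p + 1, 2 * p] = s12
    mos = SpinOrbitalSet(
        coefficients={"alpha": c_a, "beta": c_b},
        energies={s: np.concatenate([e_occ, e_virt]) for s in SPINS},
        occupations={s: np.array([1] * k + [0] * k) for s in SPINS},
    )
    return ToySystem(
        geometry=geom, shells=shells, mos=mos, thetas=thetas,
        eps_bond=eps_bond, eps_anti=eps_anti, separation=separation,
        exponent=exponent, ao_overlap=s_full,
    )


def validate_orbitals(mos: SpinOrbitalSet, overlap: np.ndarray,
                      tol: float = 1e-8) -> dict:
    """Check orthonormality C^T S C = 1 per spin channel.

    Returns a JSON-friendly report with the max deviation per channel and a
    flag when it exceeds ``tol``.
    """
    overlap = np.asarray(overlap, dtype=float)
    if overlap.shape != (mos.n_ao, mos.n_ao):
        raise ValidationError(
            f"overlap shape {overlap.shape} does not match n_ao={mos.n_ao}"
        )
    report: dict = {"tolerance": tol, "channels": {}}
    for s in SPINS:
        c = mos.coefficients[s]
        residual = c.T @ overlap @ c - np.eye(c.shape[1])
        dev = float(np.abs(residual).max()) if residual.size else 0.0
        report["channels"][s] = {"max_residual": dev, "ok": bool(dev <= tol)}
    report["ok"] = all(ch["ok"] for ch in report["channels"].values())
    return report
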