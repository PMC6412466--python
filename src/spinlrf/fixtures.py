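"""Synthetic test systems with closed-form expected values attached.

Every fixture carries its own expected diagnostics computed here from
closed forms (error functions, 2x2 algebra, explicit eigendecompositions)
and never from the analysis modules, so tests compare two independent
routes.  Fixture families:

* two-site broken-symmetry scans over the mixing angle theta,
* one-dimensional chains (and rings) of s-Gaussian sites with
  nearest-neighbour model couplings for locality studies,
* optional externally generated Molden files when an SCF engine hook is
  supplied (the suite never requires one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .system_io import (
    Geometry, GaussianShell, SpinOrbitalSet, SPINS, ToySystem,
    build_two_site_toy,
)


class EngineUnavailableError(RuntimeError):
    """No external SCF engine hook was provided."""


@dataclass
class FixtureSpec:
    """A generated system plus the closed-form quantities tests assert against."""

    kind: str                       # two_site | chain | ring | molden_external
    parameters: dict
    expected: dict = field(default_factory=dict)
    system: ToySystem | None = None


# ---------------------------------------------------------------------------
# closed forms (independent oracle code)
# ---------------------------------------------------------------------------

def two_site_expected(theta: float, separation: float, exponent: float,
                      eps_bond: float, eps_anti: float) -> dict:
    """Closed-form diagnostics of the two-site model at mixing angle theta.

    The half-space (Wigner-Seitz) integrals of the site densities are error
    functions; the cell moment of the bond-antibond product over cell 1 is
    s_cell = erf(sqrt(2 zeta) d / 2) / (2 sqrt(1 - S12^2)) with
    S12 = exp(-zeta d^2 / 2).
    """
    t = math.cos(2.0 * theta)
    s12 = math.exp(-exponent * separation**2 / 2.0)
    e_half = erf(math.sqrt(2.0 * exponent) * separation / 2.0)
    s_cell = e_half / (2.0 * math.sqrt(1.0 - s12**2))
    gap = eps_anti - eps_bond
    k11 = 2.0 * s_cell**2 * t**2 / (-gap)
    projected = 2.0 * t / (1.0 + t * t)
    # cell-1 spin population: integral of sin(2 theta) (chit1^2 - chit2^2)/ ... over z < d/2
    spin_pop_1 = math.sin(2.0 * theta) * 2.0 * s_cell
    return {
        "T": t,
        "b": t,
        "B": projected,
        "y": 1.0 - projected,
        "site_overlap": s12,
        "cell_moment": s_cell,
        "K_closed_shell": np.array([[k11, -k11], [-k11, k11]]),
        "spin_population_cell1": spin_pop_1,
        "ao_overlap": np.array([[1.0, s12], [s12, 1.0]]),
    }


def make_bs_scan(n_points: int = 11,
                 theta_range: tuple[float, float] = (0.0, math.pi / 4),
                 separation: float = 1.4, exponent: float = 1.0,
                 eps_bond: float = -0.5, eps_anti: float = -0.1
                 ) -> list[FixtureSpec]:
    """Evenly spaced theta scan across the closed-shell -> diradical range."""
    lo, hi = theta_range
    if not (0.0 <= lo <= hi <= math.pi / 4 + 1e-12):
        raise ValueError("theta range must lie within [0, pi/4]")
    out = []
    for theta in np.linspace(lo, hi, n_points):
        system = build_two_site_toy(
            float(theta), eps_bond=eps_bond, eps_anti=eps_anti,
            separation=separation, exponent=exponent,
        )
        out.append(FixtureSpec(
            kind="two_site",
            parameters={
                "theta": float(theta), "separation": separation,
                "exponent": exponent, "eps_bond": eps_bond,
                "eps_anti": eps_anti,
            },
            expected=two_site_expected(float(theta), separation, exponent,
                                       eps_bond, eps_anti),
            system=system,
        ))
    return out


# ---------------------------------------------------------------------------
# chain toys
# ---------------------------------------------------------------------------

def _chain_overlap(n: int, spacing: float, exponent: float,
                   ring: bool = False) -> np.ndarray:
    coords = np.arange(n) * spacing
    if ring:
        # place on a circle with the given arc spacing approximated by chords
        radius = spacing / (2.0 * math.sin(math.pi / n))
        ang = 2.0 * math.pi * np.arange(n) / n
        pts = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                        np.zeros(n)], axis=1)
    else:
        pts = np.stack([np.zeros(n), np.zeros(n), coords], axis=1)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return np.exp(-exponent * d**2 / 2.0), pts


def make_chain_toy(n_sites: int, spacing: float = 1.4, exponent: float = 1.0,
                   site_energy: float = -0.5, coupling=-0.15,
                   gap_profile: np.ndarray | None = None,
                   ring: bool = False) -> FixtureSpec:
    """Closed-shell chain (or ring) of s-Gaussian sites, half filled.

    The model Hamiltonian is tridiagonal in the Loewdin-orthogonalized site
    basis with nearest-neighbour ``coupling`` -- a scalar, or a per-bond
    array (length n-1, or n for a ring) for dimerized/insulating chains
    whose response decays monotonically with distance -- and optional
    per-site energies ``gap_profile``.  Its exact eigendecomposition
    provides the attached orbital energies.  The lowest ``n_sites // 2``
    levels are doubly occupied (closed shell), e.g. 2 electrons on 3 sites.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    s, pts = _chain_overlap(n_sites, spacing, exponent, ring)
    e_site = (np.full(n_sites, site_energy) if gap_profile is None
              else np.asarray(gap_profile, dtype=float))
    n_bonds = n_sites if ring else n_sites - 1
    t = np.broadcast_to(np.asarray(coupling, dtype=float), (n_bonds,))
    h = np.diag(e_site)
    for i in range(n_sites - 1):
        h[i, i + 1] = h[i + 1, i] = t[i]
    if ring:
        h[0, n_sites - 1] = h[n_sites - 1, 0] = t[n_sites - 1]
    evals, u = np.linalg.eigh(h)
    # AO coefficients: back-transform through S^{-1/2}
    sval, svec = np.linalg.eigh(s)
    s_inv_half = svec @ np.diag(sval**-0.5) @ svec.T
    c = s_inv_half @ u
    nocc = n_sites // 2
    occ = np.array([1] * nocc + [0] * (n_sites - nocc))
    geom = Geometry(["H"] * n_sites, np.ones(n_sites, dtype=int), pts)
    shells = [GaussianShell(i, 0, [exponent], [1.0]) for i in range(n_sites)]
    mos = SpinOrbitalSet(
        coefficients={sp: c.copy() for sp in SPINS},
        energies={sp: evals.copy() for sp in SPINS},
        occupations={sp: occ.copy() for sp in SPINS},
    )
    system = ToySystem(
        geometry=geom, shells=shells, mos=mos, thetas=np.zeros(1),
        eps_bond=float(evals[nocc - 1]), eps_anti=float(evals[nocc]),
        separation=spacing, exponent=exponent, ao_overlap=s,
    )
    expected: dict = {"orbital_energies": evals, "n_electrons": 2 * nocc}
    if gap_profile is None and not ring and np.ptp(t) == 0:
        k = np.arange(1, n_sites + 1)
        expected["analytic_energies"] = (
            site_energy + 2.0 * t[0] * np.cos(k * math.pi / (n_sites + 1))
        )
    return FixtureSpec(
        kind="ring" if ring else "chain",
        parameters={
            "n_sites": n_sites, "spacing": spacing, "exponent": exponent,
            "site_energy": site_energy, "coupling": coupling,
        },
        expected=expected, system=system,
    )


def chain_lrf_brute_force(fix: FixtureSpec, cell_edges: np.ndarray | None = None,
                          n_quad: int = 4000, box: float = 12.0) -> np.ndarray:
    """Independent sum-over-states evaluation for a linear chain.

    Uses dense 1-D quadrature along the chain axis for the cell moments
    (the transverse directions integrate out exactly for s-Gaussians since
    Voronoi cells of a linear chain are slabs) and an explicit double loop,
    with no code shared with the response modules.
    """
    if fix.kind != "chain":
        raise ValueError("brute-force oracle is for linear chains")
    n = fix.parameters["n_sites"]
    spacing = fix.parameters["spacing"]
    zeta = fix.parameters["exponent"]
    sys_ = fix.system
    z_sites = sys_.geometry.coords[:, 2]
    if cell_edges is None:
        cell_edges = 0.5 * (z_sites[:-1] + z_sites[1:])
    lo = z_sites[0] - box
    hi = z_sites[-1] + box
    z = np.linspace(lo, hi, n_quad)
    dz = z[1] - z[0]
    # 1-D reduced site functions: integrate x,y out of products analytically.
    # product of site i and j: marginal over (x,y) leaves gaussians in z.
    norm = (2.0 * zeta / math.pi) ** 0.75
    site_z = [norm * np.exp(-zeta * (z - zs) ** 2) for zs in z_sites]
    # transverse integral of exp(-zeta(x^2+y^2)) * exp(-zeta(x^2+y^2)) etc.
    trans = math.pi / (2.0 * zeta)
    edges = np.concatenate([[lo], cell_edges, [hi]])
    c = sys_.mos.coefficients["alpha"]
    e = sys_.mos.energies["alpha"]
    occ = sys_.mos.occupations["alpha"]
    iocc = np.where(occ == 1)[0]
    ivirt = np.where(occ == 0)[0]
    mo_z = [sum(c[s, k] * site_z[s] for s in range(n)) for k in range(n)]
    k_mat = np.zeros((n, n))
    for i in iocc:
        for a in ivirt:
            prod = mo_z[i] * mo_z[a] * trans
            m_cells = np.array([
                np.sum(prod[(z >= edges[t]) & (z < edges[t + 1])]) * dz
                for t in range(n)
            ])
            k_mat += 2.0 * np.outer(m_cells, m_cells) / (e[i] - e[a])
    return k_mat


def make_molden_fixture(molecule_spec: dict, engine_hook=None, path=None):
    """Generate a Molden file with an external unrestricted SCF engine.

    ``engine_hook(molecule_spec, path)`` must run the SCF and write the
    file; when no hook is given the fixture is unavailable and callers
    (tests) skip.
    """
    if engine_hook is None:
        raise EngineUnavailableError(
            "no external SCF engine available for Molden fixture generation"
        )
    return engine_hook(molecule_spec, path)
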