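"""Lebedev angular quadrature on the unit sphere.

Thin wrapper over :func:`scipy.integrate.lebedev_rule`, exposing the rules
by their conventional point counts (6, 26, 50, 110, 302, ...) with weights
normalized to sum to 1 (multiply by 4*pi for surface integrals).  The sets
are octahedrally symmetric and exact for spherical harmonics up to the
order's algebraic degree.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import lebedev_rule

__all__ = ["LEBEDEV_ORDERS", "lebedev_grid", "lebedev_degree"]

# point count -> algebraic degree of exactness (the published Lebedev family)
_ORDER_TO_DEGREE = {
    6: 3, 14: 5, 26: 7, 38: 9, 50: 11, 74: 13, 86: 15, 110: 17,
    146: 19, 170: 21, 194: 23, 230: 25, 266: 27, 302: 29, 350: 31,
    434: 35, 590: 41, 770: 47, 974: 53, 1202: 59, 1454: 65, 1730: 71,
    2030: 77, 2354: 83, 2702: 89, 3074: 95, 3470: 101, 3890: 107,
    4334: 113, 4802: 119, 5294: 125, 5810: 131,
}

LEBEDEV_ORDERS = tuple(sorted(_ORDER_TO_DEGREE))


def lebedev_degree(n: int) -> int:
    """Polynomial exactness degree of the order-n rule."""
    return _ORDER_TO_DEGREE[n]


def lebedev_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit points (n, 3) and weights (n,) summing to 1 for a supported order."""
    if n not in _ORDER_TO_DEGREE:
        supported = ", ".join(map(str, LEBEDEV_ORDERS))
        raise ValueError(
            f"unsupported Lebedev order {n}; supported orders: {supported}"
        )
    pts, w = lebedev_rule(_ORDER_TO_DEGREE[n])
    return pts.T.copy(), w / (4.0 * np.pi)
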