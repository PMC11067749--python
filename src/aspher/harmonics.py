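"""Density-normalized real spherical harmonics d_lm and site-symmetry rules.

The deformation density of a pseudoatom uses harmonics normalized such that
``integral |d_lm| dOmega = 2`` for l >= 1 (each function moves one electron
from its negative to its positive lobe per unit population) and
``integral d_00 dOmega = 1``.  The constants below were generated once by
adaptive quadrature of |P_l^m| split at its sign changes and are frozen here;
a test re-derives them numerically.

``d_lm = D_lm * P_l^|m|(cos theta) * cos(|m| phi)`` for m >= 0 and with
``sin`` for m < 0, using scipy's associated Legendre functions (which carry
the Condon-Shortley phase; population signs follow this convention
consistently throughout the package).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import lpmv

L_MAX = 4

#: frozen density-normalization constants D_(l,|m|)
DENSITY_NORM = {
    (0, 0): 1.0 / (4.0 * math.pi),
    (1, 0): 0.3183098861837907,
    (1, 1): 0.3183098861837907,
    (2, 0): 0.4134966762183143,
    (2, 1): 0.2500000000000000,
    (2, 2): 0.1250000000000000,
    (3, 0): 0.4897075383496027,
    (3, 1): 0.2135553972429738,
    (3, 2): 0.0666666666666667,
    (3, 3): 0.0282942121052258,
    (4, 0): 0.5553402321370046,
    (4, 1): 0.1896010116457013,
    (4, 2): 0.0440788463548837,
    (4, 3): 0.0119047619047619,
    (4, 4): 0.0044642857142857,
}


def density_normalized_harmonic(l: int, m: int, direction) -> np.ndarray | float:
    """d_lm evaluated at unit direction(s); ``direction`` is (..., 3)."""
    if not 0 <= l <= L_MAX or abs(m) > l:
        raise ValueError(f"(l, m) = ({l}, {m}) out of range")
    u = np.asarray(direction, dtype=float)
    scalar = u.ndim == 1
    u = np.atleast_2d(u)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise ValueError("directions must be unit vectors")
    cos_t = np.clip(u[..., 2], -1.0, 1.0)
    phi = np.arctan2(u[..., 1], u[..., 0])
    am = abs(m)
    val = DENSITY_NORM[(l, am)] * lpmv(am, l, cos_t)
    val = val * (np.cos(am * phi) if m >= 0 else np.sin(am * phi))
    return float(val[0]) if scalar else val


SUPPORTED_SITE_SYMMETRIES = ("1", "m", "3m", "cyl")


def allowed_multipoles(site_symmetry: str, l_max: int = L_MAX) -> list:
    """(l, m) pairs whose d_lm is invariant under the local point group.

    ``'m'``  - mirror plane = local xy plane (z -> -z): l + |m| even.
    ``'3m'`` - threefold about local z with a vertical mirror at phi = 0:
               cosine terms with m in {0, 3}.
    ``'cyl'``- cylindrical (bond-directed) symmetry about local z: m = 0.
    """
    if site_symmetry not in SUPPORTED_SITE_SYMMETRIES:
        raise ValueError(f"unsupported site-symmetry symbol {site_symmetry!r}")
    out = []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            if site_symmetry == "m" and (l + abs(m)) % 2:
                continue
            if site_symmetry == "3m" and m not in (0, 3):
                continue
            if site_symmetry == "cyl" and m != 0:
                continue
            out.append((l, m))
    return out


def point_group_generators(site_symmetry: str) -> list:
    """Cartesian generator matrices of the local point group (for tests).

    The cylindrical group is represented by a rotation through an angle
    incommensurate with 2*pi, which admits only m = 0 functions.
    """
    if site_symmetry not in SUPPORTED_SITE_SYMMETRIES:
        raise ValueError(f"unsupported site-symmetry symbol {site_symmetry!r}")

    def rot_z(deg):
        c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    if site_symmetry == "1":
        return []
    if site_symmetry == "m":
        return [np.diag([1.0, 1.0, -1.0])]
    if site_symmetry == "3m":
        return [rot_z(120.0), np.diag([1.0, -1.0, 1.0])]
    return [rot_z(360.0 * (math.sqrt(5) - 1) / 2)]  # 'cyl'
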