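"""Slater-type radial densities and their spherical-Bessel transforms.

A radial density ``R(r) = N r^n exp(-zeta r)`` with ``N = zeta^(n+3)/(n+2)!``
integrates to one over ``r^2 dr``.  Its transform

    <j_l>(s) = integral_0^inf R(r) j_l(4 pi s r) r^2 dr

is evaluated in closed form.  Two analytic routes are combined: a damped
sin/cos expansion of ``j_l`` (exact, but numerically cancellation-prone when
``4 pi s << zeta``) and the ascending series of ``j_l`` integrated term by
term, which is stable precisely in that regime.

All radial math is in Angstrom units; ``s = sin(theta)/lambda`` in 1/A.
Exponents quoted in bohr^-1 in the shipped shell table are converted once at
load time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .constants import BOHR_RADIUS_ANGSTROM


@dataclass(frozen=True)
class SlaterRadial:
    """Normalized radial density r^n exp(-zeta r); zeta in 1/A."""
    n: int
    zeta: float

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("radial power must be >= 0")
        if self.zeta <= 0:
            raise ValueError("radial exponent must be positive")

    @property
    def norm(self) -> float:
        return self.zeta ** (self.n + 3) / math.factorial(self.n + 2)

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.norm * r ** self.n * np.exp(-self.zeta * r)

    def fourier_bessel(self, l: int, s):
        return slater_fourier_bessel(l, self.n, self.zeta, s)


@lru_cache(maxsize=32)
def _sincos_coeffs(l: int):
    """Polynomial coefficients (in 1/x) of j_l(x) = A(1/x) sin x + B(1/x) cos x."""
    a = {1: 1.0}   # j_0 = sin(x)/x
    b = {}
    if l == 0:
        return a, b
    a1 = {2: 1.0}
    b1 = {1: -1.0}  # j_1 = sin/x^2 - cos/x
    if l == 1:
        return a1, b1
    for ell in range(2, l + 1):
        a2 = {k + 1: (2 * ell - 1) * v for k, v in a1.items()}
        b2 = {k + 1: (2 * ell - 1) * v for k, v in b1.items()}
        for k, v in a.items():
            a2[k] = a2.get(k, 0.0) - v
        for k, v in b.items():
            b2[k] = b2.get(k, 0.0) - v
        a, b, a1, b1 = a1, b1, a2, b2
    return a1, b1


def _transform_closed(l: int, n: int, zeta: float, b: np.ndarray) -> np.ndarray:
    """Sin/cos route: integral r^(n+2) e^(-zeta r) j_l(b r) dr, b = 4 pi s."""
    ca, cb = _sincos_coeffs(l)
    z = zeta - 1j * b
    out = np.zeros_like(b)
    for coeffs, part in ((ca, np.imag), (cb, np.real)):
        for j, c in coeffs.items():
            p = n + 2 - j
            if p < 0:
                raise ValueError(f"radial power n={n} too small for l={l}")
            out = out + c * b ** float(-j) * part(math.factorial(p) / z ** (p + 1))
    return out


def _transform_series(l: int, n: int, zeta: float, b: np.ndarray,
                      rtol: float = 1e-15, kmax: int = 80) -> np.ndarray:
    """Ascending-series route, stable for b << zeta.

    j_l(x) = sum_k (-1)^k x^(l+2k) / (2^k k! (2l+2k+1)!!); each term integrates
    to a factorial over a power of zeta; evaluated by term recursion.
    """
    term = (b ** l * math.factorial(n + l + 2)
            / zeta ** (n + l + 3) / _double_factorial(2 * l + 1))
    total = term.copy()
    for k in range(kmax):
        term = term * (-(b / zeta) ** 2) * (n + l + 2 * k + 4) * (n + l + 2 * k + 3) \
            / (2.0 * (k + 1) * (2 * l + 2 * k + 3))
        total += term
        if np.all(np.abs(term) <= rtol * (np.abs(total) + 1e-300)):
            break
    return total


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def slater_fourier_bessel(l: int, n: int, zeta: float, s):
    """<j_l>(s) for the normalized density r^n exp(-zeta r); s in 1/A."""
    if not 0 <= l <= 8:
        raise ValueError("l out of supported range")
    scalar = np.ndim(s) == 0
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    b = 4.0 * math.pi * s
    norm = zeta ** (n + 3) / math.factorial(n + 2)
    out = np.empty_like(b)
    small = b < 0.5 * zeta
    if np.any(small):
        out[small] = _transform_series(l, n, zeta, b[small])
    if np.any(~small):
        out[~small] = _transform_closed(l, n, zeta, b[~small])
    out *= norm
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Shipped single-zeta shell descriptions (H, C, N, O)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def shell_table() -> dict:
    """Element shell data: core/valence shells and deformation radial defaults.

    Orbital exponents are single-zeta values in bohr^-1 (see the data file for
    provenance); an orbital r^(nq-1) e^(-zeta r) contributes a shell density
    r^(2 nq - 2) e^(-2 zeta r), i.e. a SlaterRadial(2*nq-2, 2*zeta/a0).
    """
    text = resources.files("aspher.data").joinpath("slater_shells.json").read_text()
    return json.loads(text)


def _shell_radials(shells) -> list:
    out = []
    for nq, zeta_bohr, occ in shells:
        zeta = 2.0 * zeta_bohr / BOHR_RADIUS_ANGSTROM
        out.append((SlaterRadial(2 * (nq - 1), zeta), occ))
    return out


@lru_cache(maxsize=16)
def core_valence_radials(element: str) -> tuple:
    data = shell_table()[element]
    return tuple(_shell_radials(data["core"])), tuple(_shell_radials(data["valence"]))


def spherical_form_factor(element: str, s, which: str = "all"):
    """Spherical (IAM-like) X-ray form factor of the neutral Slater atom.

    ``which``: 'core', 'valence' or 'all'.  Electron counts come from shell
    occupancies, so f(0) = Z exactly.
    """
    core, val = core_valence_radials(element)
    parts = {"core": core, "valence": val, "all": core + val}[which]
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s, dtype=float)
    for radial, occ in parts:
        out = out + occ * radial.fourier_bessel(0, s)
    return out


def deformation_radial(element: str, l: int) -> SlaterRadial:
    """Default deformation radial R_l for the element (overridable per model)."""
    data = shell_table()[element]
    n_l = data["deformation"]["n_l"]  # indexed by l, starting at l=0
    if not 0 <= l < len(n_l):
        raise ValueError(f"no default deformation radial for l={l} of {element}")
    zeta = data["deformation"]["zeta_bohr"] / BOHR_RADIUS_ANGSTROM
    return SlaterRadial(n_l[l], zeta)


def element_number(element: str) -> int:
    return shell_table()[element]["Z"]
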