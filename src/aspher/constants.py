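"""Physical constants and electron-beam quantities.

All quantities are derived at import time from CODATA values rather than
hard-coded in crystallographic units, so that a unit-convention error in one
place cannot silently cancel elsewhere.  The momentum-transfer convention is
``s = sin(theta)/lambda`` in 1/Angstrom throughout the package.
"""

from __future__ import annotations

import math

# CODATA 2018 exact/recommended values (SI)
PLANCK_H = 6.62607015e-34          # J s
ELECTRON_MASS = 9.1093837015e-31   # kg
ELEMENTARY_CHARGE = 1.602176634e-19  # C
SPEED_OF_LIGHT = 299792458.0       # m/s
BOHR_RADIUS_ANGSTROM = 0.529177210903

#: Mott-Bethe prefactor for f_e(s) = C * (Z - f_x(s)) / s**2 with s in 1/A.
#: Equals 1/(8 pi^2 a0) = 0.023934 A^-1 in the sin(theta)/lambda convention.
MOTT_BETHE_CONSTANT = 1.0 / (8.0 * math.pi**2 * BOHR_RADIUS_ANGSTROM)


def electron_wavelength(kv: float) -> float:
    """Relativistic de Broglie wavelength (A) for an accelerating voltage in kV.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))
    """
    if kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    volts = kv * 1e3
    ev = ELEMENTARY_CHARGE * volts
    p2 = 2.0 * ELECTRON_MASS * ev * (1.0 + ev / (2.0 * ELECTRON_MASS * SPEED_OF_LIGHT**2))
    return PLANCK_H / math.sqrt(p2) * 1e10


def electron_wavelength_nonrelativistic(kv: float) -> float:
    """Classical h/sqrt(2 m0 e V) wavelength (A); low-voltage limit check."""
    if kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    volts = kv * 1e3
    return PLANCK_H / math.sqrt(2.0 * ELECTRON_MASS * ELEMENTARY_CHARGE * volts) * 1e10


def relativistic_gamma(kv: float) -> float:
    """Lorentz factor 1 + eV/(m0 c^2) of the beam electron."""
    return 1.0 + ELEMENTARY_CHARGE * kv * 1e3 / (ELECTRON_MASS * SPEED_OF_LIGHT**2)
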