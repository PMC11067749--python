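"""Hansen-Coppens pseudoatom models and the analytic aspherical form factor.

A pseudoatom density is

    rho(r) = P_c rho_core(r) + P_val kappa^3 rho_val(kappa r)
             + sum_l kappa'^3 R_l(kappa' r) sum_m P_lm d_lm(theta, phi)

with the radial functions of :mod:`aspher.slater` and the density-normalized
harmonics of :mod:`aspher.harmonics`, expressed in an atom-local Cartesian
frame.  Its Fourier transform (the aspherical X-ray form factor) is

    f_x(h) = P_c f_core(s) + P_val f_val(s/kappa)
             + sum_l 4 pi i^l <j_l>(s/kappa') sum_m P_lm d_lm(h_local)

where s = sin(theta)/lambda = |h*|/2 and h_local is the unit scattering
direction rotated into the local frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import slater
from .harmonics import L_MAX, allowed_multipoles, density_normalized_harmonic

_I_POW = [1.0, 1j, -1.0, -1j]


@dataclass(frozen=True)
class LocalFrame:
    """Atom-local axis definition from two reference atoms.

    ``axis1`` of the local frame points from the origin atom towards
    ``ref1``; the ``axis2`` direction is the Gram-Schmidt complement of the
    origin->``ref2`` vector; the third axis completes a right-handed set.
    Axis names are 'x', 'y' or 'z'.
    """
    ref1: str
    axis1: str
    ref2: str
    axis2: str

    def __post_init__(self):
        if self.axis1 == self.axis2 or {self.axis1, self.axis2} - {"x", "y", "z"}:
            raise ValueError("axis assignment must name two distinct axes of x, y, z")


def build_local_frame(e1_cart, e2_cart, axis1: str = "z", axis2: str = "x") -> np.ndarray:
    """Orthonormal right-handed rotation (columns = local axes in crystal
    Cartesian coordinates) from two non-collinear reference directions."""
    v1 = np.asarray(e1_cart, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    v2 = np.asarray(e2_cart, dtype=float)
    v2 = v2 - (v2 @ v1) * v1
    n2 = np.linalg.norm(v2)
    if n2 < 1e-8:
        raise ValueError("local-frame reference atoms are collinear")
    v2 = v2 / n2
    axes = {axis1: v1, axis2: v2}
    missing = ({"x", "y", "z"} - set(axes)).pop()
    order = "xyz"
    # third axis by right-handed completion in cyclic order
    trio = {}
    trio[axis1], trio[axis2] = v1, v2
    a, b, c = (order.index(axis1), order.index(axis2), order.index(missing))
    cross = np.cross(v1, v2)
    # ensure det(+1) for the column order x, y, z
    cols = [None, None, None]
    cols[order.index(axis1)] = v1
    cols[order.index(axis2)] = v2
    cols[order.index(missing)] = cross
    rot = np.column_stack(cols)
    if np.linalg.det(rot) < 0:
        cols[order.index(missing)] = -cross
        rot = np.column_stack(cols)
    return rot


@dataclass
class MultipoleAtomModel:
    """Hansen-Coppens parameters of one pseudoatom."""
    element: str
    p_core: float
    p_val: float
    kappa: float = 1.0
    kappa_prime: float = 1.0
    l_max: int = L_MAX
    p_lm: dict = field(default_factory=dict)       # {(l, m): population}
    radials: dict = field(default_factory=dict)    # {l: SlaterRadial}, defaults per element
    site_symmetry: str = "1"
    frame: LocalFrame | None = None
    kappa_prime_fixed: bool = False

    def __post_init__(self):
        if self.kappa <= 0 or self.kappa_prime <= 0:
            raise ValueError("kappa and kappa' must be positive")
        lim = 2 if self.element == "H" else L_MAX
        if self.l_max > lim:
            raise ValueError(f"l_max={self.l_max} too large for {self.element}")
        allowed = set(allowed_multipoles(self.site_symmetry, self.l_max))
        for lm, pop in self.p_lm.items():
            if lm not in allowed and pop != 0.0:
                raise ValueError(f"population {lm} forbidden by site symmetry "
                                 f"{self.site_symmetry!r}")

    @property
    def total_electrons(self) -> float:
        return self.p_core + self.p_val

    def radial(self, l: int) -> slater.SlaterRadial:
        if l in self.radials:
            return self.radials[l]
        return slater.deformation_radial(self.element, l)

    def allowed(self) -> list:
        return allowed_multipoles(self.site_symmetry, self.l_max)

    def copy(self) -> "MultipoleAtomModel":
        return replace(self, p_lm=dict(self.p_lm), radials=dict(self.radials))


def spherical_model(element: str) -> MultipoleAtomModel:
    """Neutral spherical (IAM) atom expressed as a monopole-only model."""
    data = slater.shell_table()[element]
    p_core = sum(occ for _, _, occ in data["core"])
    p_val = sum(occ for _, _, occ in data["valence"])
    return MultipoleAtomModel(element, p_core, p_val, l_max=2 if element == "H" else L_MAX)


def aspherical_form_factor(model: MultipoleAtomModel, s, direction_local=None):
    """Complex aspherical X-ray form factor.

    ``s`` is sin(theta)/lambda in 1/A (array ok); ``direction_local`` the
    matching unit scattering direction(s) in the atom's local frame, required
    whenever any l >= 1 population is non-zero.
    """
    s = np.asarray(s, dtype=float)
    out = np.zeros(s.shape, dtype=complex)
    if model.p_core:
        out += model.p_core * slater.spherical_form_factor(model.element, s, "core") \
            / _core_electrons(model.element)
    if model.p_val:
        out += model.p_val * slater.spherical_form_factor(model.element, s / model.kappa,
                                                          "valence") \
            / _valence_electrons(model.element)
    pops = {lm: p for lm, p in model.p_lm.items() if p != 0.0}
    if pops:
        if direction_local is None:
            raise ValueError("aspherical populations present: local direction required")
        u = np.asarray(direction_local, dtype=float)
        by_l = {}
        for (l, m), p in pops.items():
            by_l.setdefault(l, []).append((m, p))
        for l, terms in by_l.items():
            radial = model.radial(l)
            jl = radial.fourier_bessel(l, s / model.kappa_prime)
            ang = np.zeros(s.shape, dtype=float)
            for m, p in terms:
                ang = ang + p * density_normalized_harmonic(l, m, u)
            out = out + 4.0 * math.pi * _I_POW[l % 4] * jl * ang
    return out


def _core_electrons(element: str) -> float:
    data = slater.shell_table()[element]
    return sum(occ for _, _, occ in data["core"]) or 1.0


def _valence_electrons(element: str) -> float:
    data = slater.shell_table()[element]
    return sum(occ for _, _, occ in data["valence"]) or 1.0


# ---------------------------------------------------------------------------
# Plain-text multipole parameter file
# ---------------------------------------------------------------------------
# Grammar (one block per atom, blank-line separated, '#' comments):
#   atom <label> <element>
#   populations <P_core> <P_val>
#   kappa <kappa> <kappa_prime> [fixed]
#   symmetry <1|m|3m|cyl>
#   lmax <l_max>
#   frame <ref1> <axis1> <ref2> <axis2>
#   plm <l> <m> <population>            (repeatable)
#   radial <l> <n> <zeta_per_A>         (optional override, repeatable)

def write_parameter_file(models: dict, path) -> None:
    """``models`` maps atom labels to MultipoleAtomModel."""
    lines = ["# aspher multipole parameter file"]
    for label, m in models.items():
        lines.append("")
        lines.append(f"atom {label} {m.element}")
        lines.append(f"populations {m.p_core:.6f} {m.p_val:.6f}")
        fixed = " fixed" if m.kappa_prime_fixed else ""
        lines.append(f"kappa {m.kappa:.6f} {m.kappa_prime:.6f}{fixed}")
        lines.append(f"symmetry {m.site_symmetry}")
        lines.append(f"lmax {m.l_max}")
        if m.frame is not None:
            f = m.frame
            lines.append(f"frame {f.ref1} {f.axis1} {f.ref2} {f.axis2}")
        for (l, mm) in sorted(m.p_lm):
            lines.append(f"plm {l} {mm} {m.p_lm[(l, mm)]:.6f}")
        for l in sorted(m.radials):
            r = m.radials[l]
            lines.append(f"radial {l} {r.n} {r.zeta:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameter_file(path) -> dict:
    models = {}
    current = None

    def flush():
        nonlocal current
        if current is not None:
            label = current.pop("label")
            models[label] = MultipoleAtomModel(**current)
            current = None

    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            key = tok[0]
            if key == "atom":
                flush()
                current = dict(label=tok[1], element=tok[2], p_core=0.0, p_val=0.0,
                               p_lm={}, radials={})
            elif current is None:
                raise ValueError(f"directive {key!r} before any 'atom' block")
            elif key == "populations":
                current["p_core"], current["p_val"] = float(tok[1]), float(tok[2])
            elif key == "kappa":
                current["kappa"], current["kappa_prime"] = float(tok[1]), float(tok[2])
                current["kappa_prime_fixed"] = len(tok) > 3 and tok[3] == "fixed"
            elif key == "symmetry":
                current["site_symmetry"] = tok[1]
            elif key == "lmax":
                current["l_max"] = int(tok[1])
            elif key == "frame":
                current["frame"] = LocalFrame(tok[1], tok[2], tok[3], tok[4])
            elif key == "plm":
                current["p_lm"][(int(tok[1]), int(tok[2]))] = float(tok[3])
            elif key == "radial":
                current["radials"][int(tok[1])] = slater.SlaterRadial(int(tok[2]),
                                                                      float(tok[3]))
            else:
                raise ValueError(f"unknown directive {key!r} in parameter file")
    flush()
    return models
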