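"""Synthetic test inputs: fixture crystal, multipole tiers, reflection data.

Everything here is generated, self-contained and seeded; nothing is measured
data.  The fixture emulates a 1-methyluracil-like molecular crystal: Ibam
symmetry, a planar molecule on the (x, y, 0) mirror with only the
out-of-plane methyl hydrogen H7b off the special position, and an
N3-H3...O4 intermolecular hydrogen bond (H...O = 1.95 A).  The cell
constants and coordinates are hand-built plausible values (standard bond
lengths, neutron-like X-H distances, an in-plane packing chosen once by a
clash-free placement search) - they are NOT literature or experimental data.

Three multipole parameter tiers emulate increasingly specific aspherical
models (databank-like, tailored-like, crystal-like); the tiers differ mostly
in the hydrogen-bond-directed dipole populations of H3 and O4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import (AtomSite, CrystalStructure, SpaceGroup, UnitCell)
from .multipole import LocalFrame, MultipoleAtomModel, spherical_model
from .scattering import ReflectionSet, StructureFactorCalculator
from .slater import element_number

IBAM_TRIPLETS = [
    "x,y,z", "-x,-y,z", "x,-y,-z+1/2", "-x,y,-z+1/2",
    "-x,-y,-z", "x,y,-z", "-x,y,z+1/2", "x,-y,z+1/2",
    "x+1/2,y+1/2,z+1/2", "-x+1/2,-y+1/2,z+1/2", "x+1/2,-y+1/2,-z",
    "-x+1/2,y+1/2,-z", "-x+1/2,-y+1/2,-z+1/2", "x+1/2,y+1/2,-z+1/2",
    "-x+1/2,y+1/2,z", "x+1/2,-y+1/2,z",
]

FIXTURE_CELL = (13.10, 13.90, 6.25, 90.0, 90.0, 90.0)

# label, element, fractional coordinates (frozen from the placement search)
_FIXTURE_SITES = [
    ("N1", "N", 0.198066, 0.123493, 0.000000),
    ("C2", "C", 0.249025, 0.035716, 0.000000),
    ("O2", "O", 0.206773, -0.043206, 0.000000),
    ("N3", "N", 0.353551, 0.041388, 0.000000),
    ("H3", "H", 0.393054, -0.023512, 0.000000),
    ("C4", "C", 0.409989, 0.123832, 0.000000),
    ("O4", "O", 0.503505, 0.124392, 0.000000),
    ("C5", "C", 0.351535, 0.214207, 0.000000),
    ("H5", "H", 0.393921, 0.280933, 0.000000),
    ("C6", "C", 0.249775, 0.209954, 0.000000),
    ("H6", "H", 0.203907, 0.275208, 0.000000),
    ("C7", "C", 0.086977, 0.124873, 0.000000),
    ("H7a", "H", 0.057681, 0.052015, 0.000000),
    ("H7b", "H", 0.059216, 0.161828, 0.141015),
]

# anisotropic U (A^2) for non-H, CIF order U11 U22 U33 U12 U13 U23;
# the z = 0 mirror forces U13 = U23 = 0
_FIXTURE_ADPS = {
    "N1": (0.0180, 0.0200, 0.0250, 0.0020, 0.0, 0.0),
    "C2": (0.0170, 0.0190, 0.0240, 0.0010, 0.0, 0.0),
    "O2": (0.0220, 0.0240, 0.0340, 0.0040, 0.0, 0.0),
    "N3": (0.0170, 0.0190, 0.0260, 0.0020, 0.0, 0.0),
    "C4": (0.0160, 0.0190, 0.0240, 0.0010, 0.0, 0.0),
    "O4": (0.0200, 0.0230, 0.0360, 0.0030, 0.0, 0.0),
    "C5": (0.0190, 0.0210, 0.0270, 0.0010, 0.0, 0.0),
    "C6": (0.0190, 0.0200, 0.0270, 0.0020, 0.0, 0.0),
    "C7": (0.0230, 0.0260, 0.0300, 0.0030, 0.0, 0.0),
}
_FIXTURE_UISO = {"H3": 0.030, "H5": 0.033, "H6": 0.033, "H7a": 0.045, "H7b": 0.045}

#: the X-H bonds of the fixture molecule
XH_BONDS = [("N3", "H3"), ("C5", "H5"), ("C6", "H6"), ("C7", "H7a"), ("C7", "H7b")]


def fixture_structure(anisotropic: bool = True) -> CrystalStructure:
    """The Ibam fixture crystal (one molecule in the asymmetric unit)."""
    cell = UnitCell(*FIXTURE_CELL)
    sg = SpaceGroup.from_triplets("Ibam", IBAM_TRIPLETS)
    sites = []
    for label, element, x, y, z in _FIXTURE_SITES:
        if element != "H" and anisotropic:
            site = AtomSite(label, element, np.array([x, y, z]),
                            u_aniso=np.array(_FIXTURE_ADPS[label]))
        elif element != "H":
            u = _FIXTURE_ADPS[label]
            site = AtomSite(label, element, np.array([x, y, z]),
                            u_iso=float(np.mean(u[:3])))
        else:
            site = AtomSite(label, element, np.array([x, y, z]),
                            u_iso=_FIXTURE_UISO[label])
        sites.append(site)
    return CrystalStructure(cell, sg, sites)


# local frames: ring/carbonyl atoms have x, y in the molecular plane so the
# local z matches the crystal mirror normal ('m'); methyl carbon is '3m'
# about the N1-C7 axis; hydrogens are cylindrical about the X-H bond.
_FRAMES = {
    "N1": LocalFrame("C2", "x", "C6", "y"),
    "C2": LocalFrame("O2", "x", "N1", "y"),
    "O2": LocalFrame("C2", "x", "N1", "y"),
    "N3": LocalFrame("C4", "x", "C2", "y"),
    "C4": LocalFrame("O4", "x", "N3", "y"),
    "O4": LocalFrame("C4", "x", "N3", "y"),
    "C5": LocalFrame("C6", "x", "C4", "y"),
    "C6": LocalFrame("C5", "x", "N1", "y"),
    "C7": LocalFrame("N1", "z", "H7a", "x"),
    "H3": LocalFrame("N3", "z", "C4", "x"),
    "H5": LocalFrame("C5", "z", "C4", "x"),
    "H6": LocalFrame("C6", "z", "C5", "x"),
    "H7a": LocalFrame("C7", "z", "N1", "x"),
    "H7b": LocalFrame("C7", "z", "N1", "x"),
}

_SITE_SYMMETRY = {label: ("cyl" if label.startswith("H") else
                          "3m" if label == "C7" else "m")
                  for label, *_ in _FIXTURE_SITES}

# base (databank-like) populations: P_val, kappa, kappa', and P_lm entries.
# Values are chemically plausible magnitudes for first-row sp2 systems.
_BASE_PVAL = {
    "N1": 5.10, "C2": 3.75, "O2": 6.25, "N3": 5.10, "H3": 0.72,
    "C4": 3.75, "O4": 6.25, "C5": 4.05, "H5": 0.85, "C6": 3.95,
    "H6": 0.85, "C7": 4.10, "H7a": 0.90, "H7b": 0.90,
}
# valence contraction-expansion: hydrogens strongly contracted (free-H
# density is far too diffuse for a bonded atom), first-row atoms mildly
# contracted; calibrated once so the fixture exhibits the characteristic
# IAM-refinement biases of electron diffraction (long X-H bonds, small non-H
# ADPs, inflated H ADPs), then frozen
_KAPPA = {"H": (1.25, 1.25), "C": (1.03, 0.92), "N": (1.02, 0.95), "O": (1.00, 0.96)}

_BASE_PLM = {
    # planar atoms: in-plane dipoles/octupoles, z-quadrupole, hexadecapoles
    "N1": {(1, 1): 0.05, (2, 0): -0.15, (2, 2): 0.05, (3, 1): 0.10, (3, 3): 0.08,
           (4, 0): 0.02},
    "C2": {(1, 1): 0.08, (2, 0): -0.22, (2, 2): 0.06, (3, 1): 0.12, (3, 3): 0.18,
           (4, 0): 0.03},
    "O2": {(1, 1): 0.06, (1, -1): 0.02, (2, 0): -0.08, (2, 2): -0.06, (3, 1): 0.03,
           (4, 0): 0.01},
    "N3": {(1, 1): 0.04, (2, 0): -0.14, (2, 2): 0.04, (3, 1): 0.09, (3, 3): 0.10,
           (4, 0): 0.02},
    "C4": {(1, 1): 0.08, (2, 0): -0.22, (2, 2): 0.05, (3, 1): 0.12, (3, 3): 0.18,
           (4, 0): 0.03},
    "O4": {(1, 1): 0.06, (1, -1): 0.02, (2, 0): -0.08, (2, 2): -0.06, (3, 1): 0.03,
           (4, 0): 0.01},
    "C5": {(1, 1): 0.05, (2, 0): -0.20, (2, 2): 0.04, (3, 1): 0.10, (3, 3): 0.16,
           (4, 0): 0.02},
    "C6": {(1, 1): 0.05, (2, 0): -0.20, (2, 2): 0.04, (3, 1): 0.10, (3, 3): 0.16,
           (4, 0): 0.02},
    # methyl carbon, 3m about the N-C axis
    "C7": {(1, 0): -0.05, (2, 0): -0.10, (3, 0): 0.08, (3, 3): 0.12, (4, 0): 0.02},
    # hydrogens: bond-directed dipole + quadrupole
    "H3": {(1, 0): 0.18, (2, 0): 0.05},
    "H5": {(1, 0): 0.18, (2, 0): 0.04},
    "H6": {(1, 0): 0.18, (2, 0): 0.04},
    "H7a": {(1, 0): 0.18, (2, 0): 0.04},
    "H7b": {(1, 0): 0.18, (2, 0): 0.04},
}

TIERS = ("databank", "molecule", "crystal")

# tier perturbations: generic small P_lm offsets plus hydrogen-bond-directed
# dipole changes on H3/O4 that dominate by construction
_TIER_HB_DELTA = {"databank": 0.0, "molecule": 0.035, "crystal": 0.080}
_TIER_GENERIC = {"databank": 0.0, "molecule": 0.012, "crystal": 0.008}


def fixture_multipoles(level: str = "databank") -> dict:
    """Multipole models for every fixture atom at the requested tier."""
    if level not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    structure = fixture_structure()
    models = {}
    hb_delta = _TIER_HB_DELTA[level]
    gen = _TIER_GENERIC[level]
    for idx, (label, element, *_xyz) in enumerate(_FIXTURE_SITES):
        kappa, kappa_p = _KAPPA[element]
        p_lm = dict(_BASE_PLM[label])
        if gen:
            # deterministic small tier-dependent adjustments
            for j, lm in enumerate(sorted(p_lm)):
                p_lm[lm] += gen * math.sin(1.0 + 2.0 * idx + 3.0 * j) * 0.5
        if label == "H3":
            p_lm[(1, 0)] += hb_delta
        if label == "O4":
            p_lm[(1, 1)] += hb_delta  # dipole along local x = C4->O4, towards H3
        z = element_number(element)
        p_core = 0.0 if element == "H" else 2.0
        models[label] = MultipoleAtomModel(
            element, p_core, _BASE_PVAL[label], kappa, kappa_p,
            l_max=2 if element == "H" else 4, p_lm=p_lm,
            site_symmetry=_SITE_SYMMETRY[label], frame=_FRAMES[label])
    _neutralize(models, structure)
    return models


def _neutralize(models: dict, structure: CrystalStructure) -> None:
    """Adjust carbon valence populations so the crystal is exactly neutral.

    Neutrality is counted per molecule: site contributions are weighted by
    multiplicity relative to the molecular mirror copy (H7b counts twice).
    """
    weights = {s.label: structure.multiplicity(s) / 8.0 for s in structure.sites}
    electrons = sum(weights[s.label] * element_number(s.element)
                    for s in structure.sites)
    total = sum(weights[lab] * (m.p_core + m.p_val) for lab, m in models.items())
    carbons = [lab for lab, m in models.items() if m.element == "C"]
    w_c = sum(weights[lab] for lab in carbons)
    for lab in carbons:
        models[lab].p_val += (electrons - total) / w_c


@dataclass
class SyntheticSpec:
    """Generation conditions for synthetic reflection data."""
    d_min: float = 0.56
    completeness: float = 0.63
    cone_semi_deg: float = 15.0    # missing-wedge emulation about c*
    noise: str = "none"            # 'none' | 'gaussian'
    sigma_floor: float = 0.1       # on F^2
    sigma_frac: float = 0.02       # c in sigma = max(floor, c F^2)
    seed: int = 0
    radiation: str = "electron"

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")


def unique_reflections(cell: UnitCell, spacegroup: SpaceGroup, d_min: float) -> np.ndarray:
    """Symmetry-unique, non-extinct index set to d_min (000 excluded)."""
    hmax = [int(math.floor(length / d_min)) for length in (cell.a, cell.b, cell.c)]
    grid = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1,
                    -hmax[2]:hmax[2] + 1].reshape(3, -1).T
    grid = grid[np.any(grid != 0, axis=1)]
    inv_d2 = np.einsum('ni,ij,nj->n', grid.astype(float), cell.reciprocal_metric,
                       grid.astype(float))
    grid = grid[inv_d2 <= 1.0 / d_min**2 + 1e-12]
    rots = spacegroup.laue_rotations()
    reps = {}
    for h in grid:
        images = [tuple(int(v) for v in (r @ h)) for r in rots]
        rep = max(images)
        reps.setdefault(rep, None)
    out = []
    for h in reps:
        if not _is_extinct(np.array(h), spacegroup):
            out.append(h)
    arr = np.array(sorted(out), dtype=int)
    d = cell.d_spacing(arr)
    order = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0], -d))
    return arr[order]


def _is_extinct(h: np.ndarray, spacegroup: SpaceGroup) -> bool:
    for op in spacegroup.ops:
        if np.array_equal(op.rot_array.T @ h, h):
            phase = float(h @ op.tran_array)
            if abs(phase - round(phase)) > 1e-9:
                return True
    return False


def full_reflections(cell: UnitCell, spacegroup: SpaceGroup, d_min: float) -> np.ndarray:
    """All non-extinct indices to d_min (no Laue reduction; 000 excluded)."""
    hmax = [int(math.floor(length / d_min)) for length in (cell.a, cell.b, cell.c)]
    grid = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1,
                    -hmax[2]:hmax[2] + 1].reshape(3, -1).T
    grid = grid[np.any(grid != 0, axis=1)]
    inv_d2 = np.einsum('ni,ij,nj->n', grid.astype(float), cell.reciprocal_metric,
                       grid.astype(float))
    grid = grid[inv_d2 <= 1.0 / d_min**2 + 1e-12]
    return np.array([h for h in grid if not _is_extinct(h, spacegroup)], dtype=int)


def simulate_frames(structure: CrystalStructure, models: dict | None,
                    orientations, thickness_nm: float, phi_deg: float = 0.7,
                    wavelength: float = 0.0251, noise_frac: float = 0.0,
                    seed: int = 0, d_min: float = 1.2, s_max: float = 0.02,
                    rs_max: float = 0.75, n_azimuth: int = 32) -> tuple:
    """Synthetic precession frames with dynamical intensities plus noise.

    ``orientations`` is a sequence of (crystal_tag, unit beam direction in
    reciprocal Cartesian).  Returns (frames, ledger); the ledger records the
    true thickness and per-frame scales for recovery tests.
    """
    from .dynamical import BlochSolver, select_beams

    rng = np.random.default_rng(seed)
    pool = full_reflections(structure.cell, structure.spacegroup, d_min)
    frames = []
    scales = []
    for crystal, orientation in orientations:
        beams = select_beams(structure.cell, pool, orientation, wavelength,
                             phi_deg, d_min, s_max, rs_max, n_azimuth=72)
        solver = BlochSolver(structure, models, beams)
        intensities = solver.precession_intensities(thickness_nm, n_azimuth)[1:]
        scale = float(np.exp(rng.normal(0.0, 0.05)))
        i_true = scale * intensities
        sigma = np.maximum(noise_frac * i_true, 1e-12)
        i_obs = i_true + rng.normal(0.0, sigma) if noise_frac > 0 else i_true
        from .dynamical import Frame
        frames.append(Frame(str(crystal), np.asarray(orientation, float),
                            phi_deg, wavelength, beams.hkl[1:],
                            np.maximum(i_obs, 0.0), sigma))
        scales.append(scale)
    ledger = {"thickness_nm": thickness_nm, "scales": scales, "seed": seed,
              "noise_frac": noise_frac, "n_beams": [len(f.hkl) for f in frames]}
    return frames, ledger


def simulate_reflections(spec: SyntheticSpec, structure: CrystalStructure,
                         models: dict | None = None) -> tuple:
    """Reflection set from the chosen model plus a ground-truth ledger.

    Returns ``(ReflectionSet, ledger)``; the ledger records every quantity a
    recovery test needs (true coordinates, ADPs, model identity, spec, seed).
    """
    hkl = unique_reflections(structure.cell, structure.spacegroup, spec.d_min)
    calc = StructureFactorCalculator(structure, models, spec.radiation, hkl)
    f = calc.calculate()
    d = np.asarray(structure.cell.d_spacing(hkl))
    rng = np.random.default_rng(spec.seed)

    # completeness: cone exclusion about c* then seeded thinning to the target
    keep = np.ones(len(hkl), dtype=bool)
    if spec.completeness < 1.0:
        u = structure.cell.hkl_to_cart(hkl)
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        cstar = structure.cell.reciprocal_matrix[:, 2]
        cstar = cstar / np.linalg.norm(cstar)
        angle = np.degrees(np.arccos(np.clip(np.abs(u @ cstar), 0, 1)))
        keep &= angle > spec.cone_semi_deg
        target = int(round(spec.completeness * len(hkl)))
        idx = np.where(keep)[0]
        if target < len(idx):
            drop = rng.choice(idx, size=len(idx) - target, replace=False)
            keep[drop] = False
    hkl, f, d = hkl[keep], f[keep], d[keep]

    i_true = np.abs(f) ** 2
    if spec.noise == "gaussian":
        sigma = np.maximum(spec.sigma_floor, spec.sigma_frac * i_true)
        i_obs = i_true + rng.normal(0.0, sigma)
    elif spec.noise == "none":
        sigma = np.zeros_like(i_true)
        i_obs = i_true.copy()
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")

    df = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "d": d,
        "I_obs": i_obs, "sigma": sigma,
        "F_obs": np.sqrt(np.maximum(i_obs, 0.0)),
        "phase": np.angle(f),
    })
    refl = ReflectionSet(df).flag_observed()
    ledger = {
        "seed": spec.seed,
        "d_min": spec.d_min,
        "radiation": spec.radiation,
        "noise": spec.noise,
        "coordinates": {s.label: s.xyz.tolist() for s in structure.sites},
        "adps": {s.label: (s.u_aniso.tolist() if s.u_aniso is not None
                           else s.u_iso) for s in structure.sites},
        "n_reflections": int(len(df)),
    }
    return refl, ledger
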