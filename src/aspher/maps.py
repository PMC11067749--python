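"""Difference electrostatic-potential maps, extrema, omission and fractal curves.

The residual synthesis uses coefficients (|F_o| - |F_c|) exp(i phi_calc) over
the measured reflection set (optionally zero-filling nothing: absent
reflections simply contribute nothing), on an FFT grid with spacing at most
d_min/3 per axis:

    delta_phi(x) = (1/V) sum_h dF(h) exp(-2 pi i h.x)

Both Friedel mates of each stored unique reflection enter the sum, so the map
is real.  With electron structure factors in A the synthesized values are in
the conventional residual-potential units (labelled e/A in this field).

The fractal-dimension statistic of a map distribution is
``d_f(rho0) = ln N(rho0) / ln(N_total^(1/3))`` with N(rho0) the number of
voxels whose value falls in the bin at rho0 - the fixed-grid specialization
of the box-counting residual analysis; a featureless Gaussian residual map
yields the characteristic parabola-like curve peaking near d_f = 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .crystal import CrystalStructure, UnitCell
from .scattering import ReflectionSet


@dataclass
class PotentialMap:
    values: np.ndarray          # (n1, n2, n3) real
    cell: UnitCell
    provenance: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


def grid_dimensions(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple:
    """Smallest FFT-friendly grid with spacing <= d_min/factor per axis."""
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(math.ceil(factor * length / d_min))
        dims.append(next_fast_len(max(n, 4)))
    return tuple(dims)


def difference_map(refl: ReflectionSet, cell: UnitCell,
                   dims: tuple | None = None, d_min: float | None = None,
                   scale: float = 1.0) -> PotentialMap:
    """Fourier difference synthesis from F_obs, F_calc amplitude and phase.

    The reflection table needs ``F_obs``, a calculated amplitude (``F_calc``
    complex or ``F_calc_amp``) and ``phase`` (radians).  ``scale`` multiplies
    the calculated amplitudes before differencing; the 000 term is excluded
    by construction, so the map mean is zero.
    """
    df = refl.data
    if "phase" not in df:
        raise ValueError("difference synthesis needs calculated phases")
    if "F_calc" in df:
        f_calc_amp = np.abs(df["F_calc"].to_numpy())
    elif "F_calc_amp" in df:
        f_calc_amp = df["F_calc_amp"].to_numpy(dtype=float)
    else:
        raise ValueError("difference synthesis needs calculated amplitudes")
    if d_min is None:
        d_min = float(df["d"].min()) if "d" in df else float(np.min(cell.d_spacing(refl.hkl)))
    if dims is None:
        dims = grid_dimensions(cell, d_min)
    delta = df["F_obs"].to_numpy(dtype=float) - scale * f_calc_amp
    coeff = delta * np.exp(1j * df["phase"].to_numpy(dtype=float))
    hkl = refl.hkl
    if np.any(2 * np.abs(hkl) >= np.array(dims)):
        raise ValueError("grid too coarse for the index range (aliasing)")
    grid = np.zeros(dims, dtype=complex)
    for (h, k, l), c in zip(hkl, coeff):
        if (h, k, l) == (0, 0, 0):
            continue
        grid[-h % dims[0], -k % dims[1], -l % dims[2]] += c
        grid[h % dims[0], k % dims[1], l % dims[2]] += np.conj(c)
    rho = np.fft.ifftn(grid) * np.prod(dims) / cell.volume
    return PotentialMap(np.real(rho), cell,
                        {"n_coefficients": int(len(coeff)), "scale": scale,
                         "d_min": d_min})


def expand_to_hemisphere(refl: ReflectionSet, spacegroup) -> ReflectionSet:
    """Laue-expand a unique set to one representative per Friedel pair.

    Only amplitude columns (F_obs/I_obs/sigma) propagate - symmetry
    equivalents share amplitudes; phases must be recomputed by a model.
    """
    cols = [c for c in ("F_obs", "I_obs", "sigma") if c in refl.data]
    rows = {}
    for _, row in refl.data.iterrows():
        h = np.array([row.h, row.k, row.l], dtype=int)
        for rot in spacegroup.laue_rotations():
            h2 = rot.T @ h
            rep = tuple(h2) if tuple(h2) >= tuple(-h2) else tuple(-h2)
            if rep not in rows:
                rows[rep] = [row[c] for c in cols]
    data = pd.DataFrame([list(k) + v for k, v in sorted(rows.items())],
                        columns=["h", "k", "l"] + cols)
    return ReflectionSet(data)


def residual_map(structure: CrystalStructure, models: dict | None,
                 refl: ReflectionSet, radiation: str = "electron",
                 dims: tuple | None = None, fit_scale: bool = True,
                 expand: bool = True) -> PotentialMap:
    """Residual synthesis for a model against measured unique amplitudes.

    Expands the unique set over the Laue group, computes model amplitudes and
    phases at every index, places the observed amplitude on the symmetry
    orbit, optionally fits the scale minimizing sum(|Fo| - k|Fc|)^2, and
    synthesizes (|Fo| - k|Fc|) exp(i phi_calc).
    """
    from .scattering import StructureFactorCalculator

    work = expand_to_hemisphere(refl, structure.spacegroup) if expand else refl.copy()
    calc = StructureFactorCalculator(structure, models, radiation, work.hkl)
    f_calc = calc.calculate()
    df = work.data.copy()
    df["F_calc_amp"] = np.abs(f_calc)
    df["phase"] = np.angle(f_calc)
    df["d"] = structure.cell.d_spacing(work.hkl)
    scale = 1.0
    if fit_scale:
        fo = df["F_obs"].to_numpy(dtype=float)
        fc = df["F_calc_amp"].to_numpy(dtype=float)
        scale = float(fo @ fc / (fc @ fc))
    return difference_map(ReflectionSet(df), structure.cell, dims=dims, scale=scale)


def map_extrema(pmap: PotentialMap, structure: CrystalStructure | None = None) -> dict:
    """Global minimum and maximum with sub-voxel parabolic interpolation.

    If a structure is given, each extremum is annotated with its nearest atom
    (over all symmetry images).
    """
    v = pmap.values
    if v.size == 0:
        raise ValueError("empty map")
    out = {}
    for kind, idx_flat in (("min", int(np.argmin(v))), ("max", int(np.argmax(v)))):
        idx = np.array(np.unravel_index(idx_flat, v.shape))
        value = float(v[tuple(idx)])
        frac = idx.astype(float)
        for axis in range(3):
            im = idx.copy()
            ip = idx.copy()
            im[axis] = (im[axis] - 1) % v.shape[axis]
            ip[axis] = (ip[axis] + 1) % v.shape[axis]
            y0, y1, y2 = float(v[tuple(im)]), value, float(v[tuple(ip)])
            denom = y0 - 2.0 * y1 + y2
            if abs(denom) > 1e-30:
                delta = 0.5 * (y0 - y2) / denom
                frac[axis] += np.clip(delta, -0.5, 0.5)
                value = max(value, y1 - 0.25 * (y0 - y2) * np.clip(delta, -0.5, 0.5)) \
                    if kind == "max" else min(value, y1 - 0.25 * (y0 - y2)
                                              * np.clip(delta, -0.5, 0.5))
        position = frac / np.array(v.shape)
        rec = {"value": value, "position": position.tolist()}
        if structure is not None:
            rec["nearest_atom"] = _nearest_atom(structure, position)
        out[kind] = rec
    return out


def _nearest_atom(structure: CrystalStructure, frac_pos) -> str:
    best, best_d = None, np.inf
    p = np.asarray(frac_pos)
    for site in structure.sites:
        for image in structure.spacegroup.orbit(site.xyz):
            delta = np.mod(image - p + 0.5, 1.0) - 0.5
            d = float(np.linalg.norm(structure.cell.frac_to_cart(delta)))
            if d < best_d:
                best, best_d = site.label, d
    return best


def omit_reflections(refl: ReflectionSet, groups, spacegroup) -> tuple:
    """Remove every Laue-equivalent of each listed index group.

    Returns (filtered ReflectionSet, number removed); a listed group with no
    member in the set triggers a warning, not an error.
    """
    import warnings

    rots = spacegroup.laue_rotations()
    targets = set()
    for g in groups:
        g = np.asarray(g, dtype=int)
        found = False
        equivalents = {tuple(int(x) for x in (r @ g)) for r in rots}
        targets |= equivalents
        present = {tuple(row) for row in refl.hkl}
        if not (equivalents & present):
            warnings.warn(f"omission group {tuple(g)} absent from the reflection set")
    mask = np.array([tuple(row) not in targets for row in refl.hkl])
    removed = int((~mask).sum())
    return ReflectionSet(refl.data[mask].reset_index(drop=True)), removed


def fractal_dimension_curve(pmap: PotentialMap, n_bins: int = 100) -> pd.DataFrame:
    """d_f(rho0) over equal-width value bins; empty bins yield gaps (NaN)."""
    if n_bins < 20:
        raise ValueError("need at least 20 bins")
    v = pmap.values.ravel()
    n_total = v.size
    counts, edges = np.histogram(v, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        d_f = np.where(counts > 0, np.log(np.maximum(counts, 1))
                       / math.log(n_total ** (1.0 / 3.0)), np.nan)
    return pd.DataFrame({"rho0": centers, "count": counts, "d_f": d_f})


def write_xplor(pmap: PotentialMap, path, title: str = "aspher residual map") -> None:
    """X-PLOR formatted text map covering one unit cell."""
    n1, n2, n3 = pmap.shape
    cell = pmap.cell
    with open(path, "w") as fh:
        fh.write("\n       1\n")
        fh.write(f" {title}\n")
        fh.write(f"{n1:8d}{0:8d}{n1 - 1:8d}{n2:8d}{0:8d}{n2 - 1:8d}"
                 f"{n3:8d}{0:8d}{n3 - 1:8d}\n")
        fh.write(f"{cell.a:12.5E}{cell.b:12.5E}{cell.c:12.5E}"
                 f"{cell.alpha:12.5E}{cell.beta:12.5E}{cell.gamma:12.5E}\n")
        fh.write("ZYX\n")
        for k in range(n3):
            fh.write(f"{k:8d}\n")
            sect = pmap.values[:, :, k].ravel(order="F")  # x fastest
            for i in range(0, len(sect), 6):
                fh.write("".join(f"{x:12.5E}" for x in sect[i:i + 6]) + "\n")
        fh.write(f"{-9999:8d}\n")
        fh.write(f"{pmap.values.mean():12.4E}{pmap.values.std():12.4E}\n")


def write_ccp4(pmap: PotentialMap, path) -> None:
    """Binary CCP4/MRC export via gemmi (runtime output for viewers)."""
    import gemmi

    grid = gemmi.FloatGrid(*pmap.shape)
    grid.set_unit_cell(gemmi.UnitCell(pmap.cell.a, pmap.cell.b, pmap.cell.c,
                                      pmap.cell.alpha, pmap.cell.beta,
                                      pmap.cell.gamma))
    arr = np.array(grid, copy=False)
    arr[...] = pmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
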