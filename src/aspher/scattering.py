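"""Kinematical structure factors for IAM and multipole models.

The crystal structure factor is assembled over the asymmetric unit and all
symmetry operators.  For an operator ``x' = M x + t`` the contribution of a
site is evaluated at the transformed index ``h_eff = M^T h`` (with the extra
phase ``exp(2 pi i h . t)``), which carries the rotation into the atomic form
factor, the displacement tensor and the positional phase at once.  Atoms on
special positions are weighted by ``occ * multiplicity / |ops|`` so the
symmetrized sum counts each image exactly once.

Electron structure factors apply the Mott-Bethe conversion atom by atom
(before the Debye-Waller factor, which attenuates the atomic potential the
same way it attenuates the electron density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MOTT_BETHE_CONSTANT
from .crystal import CrystalStructure, u_vector_to_matrix
from .multipole import (MultipoleAtomModel, aspherical_form_factor,
                        build_local_frame, spherical_model)
from .slater import element_number


def mott_bethe(z: float, f_x, s):
    """Electron scattering factor f_e(s) = C (Z - f_x(s)) / s^2, in A.

    The s = 0 monopole limit is not taken here; reflection sets exclude 000
    and the mean inner potential is handled by the dynamical module.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("Mott-Bethe conversion requires s > 0")
    return MOTT_BETHE_CONSTANT * (z - np.asarray(f_x)) / s**2


def debye_waller(site, hkl, cell):
    """Attenuation exp(-2 pi^2 sum U_ij h_i h_j a*_i a*_j) in (0, 1]."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    rec = cell.reciprocal_lengths
    if site.u_aniso is not None:
        u = u_vector_to_matrix(site.u_aniso)
        if np.linalg.eigvalsh(u).min() < -1e-10:
            raise ValueError("U tensor not positive semidefinite")
        q = hkl * rec[None, :]
        expo = 2.0 * math.pi**2 * np.einsum('ni,ij,nj->n', q, u, q)
    else:
        u_iso = site.u_iso or 0.0
        inv_d2 = np.einsum('ni,ij,nj->n', hkl, cell.reciprocal_metric, hkl)
        expo = 2.0 * math.pi**2 * u_iso * inv_d2
    out = np.exp(-expo)
    return out if out.size > 1 else float(out[0])


class StructureFactorCalculator:
    """Cached evaluator of F(h) for a fixed index set.

    Geometry-independent parts (form factors on the op x reflection grid) are
    cached per atom so that coordinate/ADP refinement loops pay only for the
    phase and Debye-Waller updates.
    """

    def __init__(self, structure: CrystalStructure, models: dict | None = None,
                 radiation: str = "electron", hkl=None):
        if radiation not in ("xray", "electron"):
            raise ValueError("radiation must be 'xray' or 'electron'")
        self.structure = structure
        self.radiation = radiation
        self.models = dict(models or {})
        for site in structure.sites:
            self.models.setdefault(site.label, spherical_model(site.element))
        self.set_hkl(hkl if hkl is not None else np.zeros((0, 3), dtype=int))

    # -- geometry ---------------------------------------------------------
    def set_hkl(self, hkl) -> None:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        self.hkl = hkl
        cell = self.structure.cell
        ops = self.structure.spacegroup.ops
        self._ops = ops
        n_ops, n_ref = len(ops), len(hkl)
        self._h_eff = np.empty((n_ops, n_ref, 3))
        self._op_phase = np.empty((n_ops, n_ref), dtype=complex)
        for i, op in enumerate(ops):
            self._h_eff[i] = hkl @ op.rot_array.astype(float)
            self._op_phase[i] = np.exp(2j * math.pi * (hkl @ op.tran_array))
        if n_ref:
            self.s = 0.5 / np.asarray(cell.d_spacing(hkl))
            ucart = self._h_eff @ cell.reciprocal_matrix.T
            norm = np.linalg.norm(ucart, axis=-1, keepdims=True)
            self._u_cart = ucart / np.where(norm == 0, 1.0, norm)
        else:
            self.s = np.zeros(0)
            self._u_cart = np.zeros((n_ops, 0, 3))
        self._ff_cache = {}
        self._contrib = {}
        self._dirty = {site.label for site in self.structure.sites}

    def local_rotation(self, label: str) -> np.ndarray:
        model = self.models[label]
        if model.frame is None:
            return np.eye(3)
        st = self.structure
        cell = st.cell
        origin = st.site(label).xyz
        v1 = cell.frac_to_cart(st.site(model.frame.ref1).xyz - origin)
        v2 = cell.frac_to_cart(st.site(model.frame.ref2).xyz - origin)
        return build_local_frame(v1, v2, model.frame.axis1, model.frame.axis2)

    # -- caches -----------------------------------------------------------
    def invalidate_form_factors(self, label: str | None = None) -> None:
        if label is None:
            self._ff_cache.clear()
            self._dirty = {s.label for s in self.structure.sites}
        else:
            self._ff_cache.pop(label, None)
            self._dirty.add(label)

    def invalidate_frames(self) -> None:
        """Call after coordinate changes if any local frame must follow."""
        self.invalidate_form_factors()

    def mark_dirty(self, label: str) -> None:
        """Flag a site whose position/ADP changed (form factors kept)."""
        self._dirty.add(label)

    def _form_factor(self, label: str) -> np.ndarray:
        """X-ray form factor on the (ops, reflections) grid."""
        if label not in self._ff_cache:
            model = self.models[label]
            rot = self.local_rotation(label)
            u_local = self._u_cart @ rot  # rows . columns-of-rot = local comps
            shape = self._u_cart.shape[:2]
            s_grid = np.broadcast_to(self.s, shape)
            ff = aspherical_form_factor(model, s_grid.reshape(-1),
                                        u_local.reshape(-1, 3)).reshape(shape)
            self._ff_cache[label] = ff
        return self._ff_cache[label]

    # -- evaluation -------------------------------------------------------
    def calculate(self) -> np.ndarray:
        """Complex F for every reflection of the current index set.

        Per-site contributions are cached; only sites flagged dirty (changed
        position, ADP or model) are recomputed.
        """
        st = self.structure
        cell = st.cell
        rec = cell.reciprocal_lengths
        n_ops = len(self._ops)
        s2 = self.s**2
        for site in st.sites:
            if site.label not in self._dirty and site.label in self._contrib:
                continue
            weight = site.occupancy * st.multiplicity(site) / n_ops
            fx = self._form_factor(site.label)
            if self.radiation == "electron":
                z = element_number(site.element)
                f = MOTT_BETHE_CONSTANT * (z - fx) / s2[None, :]
            else:
                f = fx
            if site.u_aniso is not None:
                u = u_vector_to_matrix(site.u_aniso)
                q = self._h_eff * rec[None, None, :]
                dw = np.exp(-2.0 * math.pi**2 * np.einsum('oni,ij,onj->on', q, u, q))
            else:
                dw = np.exp(-8.0 * math.pi**2 * (site.u_iso or 0.0) * s2)[None, :]
            phase = np.exp(2j * math.pi * (self._h_eff @ site.xyz)) * self._op_phase
            self._contrib[site.label] = weight * np.sum(f * dw * phase, axis=0)
        self._dirty.clear()
        return np.sum(list(self._contrib.values()), axis=0)


def structure_factor(structure: CrystalStructure, hkl, models: dict | None = None,
                     radiation: str = "electron") -> np.ndarray:
    """One-shot F(h) for an index array; see StructureFactorCalculator."""
    calc = StructureFactorCalculator(structure, models, radiation, hkl)
    out = calc.calculate()
    return out


# ---------------------------------------------------------------------------
# Reflection sets
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Indexed reflection table.

    The underlying DataFrame has integer columns h, k, l plus d (A) and any
    of: F_obs, I_obs, sigma, F_calc (complex), phase (rad), observed (bool),
    tag.  The observed flag follows I > 3 sigma(I) when intensities and
    sigmas are present.
    """
    data: pd.DataFrame

    def __post_init__(self):
        for col in ("h", "k", "l"):
            if col not in self.data:
                raise ValueError("reflection table needs h, k, l columns")
        if "d" in self.data and np.any(self.data["d"] <= 0):
            raise ValueError("non-positive d-spacing in reflection set")
        if "sigma" in self.data and np.any(self.data["sigma"] < 0):
            raise ValueError("negative sigma in reflection set")

    def __len__(self):
        return len(self.data)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy(dtype=int)

    def with_d(self, cell) -> "ReflectionSet":
        df = self.data.copy()
        df["d"] = cell.d_spacing(self.hkl)
        return ReflectionSet(df)

    def flag_observed(self, n_sigma: float = 3.0) -> "ReflectionSet":
        df = self.data.copy()
        if "I_obs" in df and "sigma" in df:
            df["observed"] = df["I_obs"] > n_sigma * df["sigma"]
        else:
            df["observed"] = True
        return ReflectionSet(df)

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.data.copy())


def write_shelx_hkl(refl: ReflectionSet, path, hklf: int = 4) -> None:
    """SHELX fixed-width list; HKLF 3 writes F/sigma, HKLF 4 writes F^2/sigma."""
    if hklf not in (3, 4):
        raise ValueError("hklf dialect must be 3 or 4")
    col = "F_obs" if hklf == 3 else "I_obs"
    if col not in refl.data:
        raise ValueError(f"reflection set lacks {col} needed for HKLF {hklf}")
    with open(path, "w") as fh:
        for _, row in refl.data.iterrows():
            sigma = row.get("sigma", 0.0)
            fh.write(f"{int(row.h):4d}{int(row.k):4d}{int(row.l):4d}"
                     f"{row[col]:8.2f}{sigma:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_shelx_hkl(path, hklf: int = 4) -> ReflectionSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            if len(line.rstrip("\n")) < 28:
                continue
            h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
            if (h, k, l) == (0, 0, 0):
                break
            val, sig = float(line[12:20]), float(line[20:28])
            rows.append((h, k, l, val, sig))
    df = pd.DataFrame(rows, columns=["h", "k", "l", "value", "sigma"])
    df = df.rename(columns={"value": "F_obs" if hklf == 3 else "I_obs"})
    return ReflectionSet(df)


def write_phased_hkl(refl: ReflectionSet, path) -> None:
    """Extended text format ``h k l F phase_deg sigma`` for theoretical sets."""
    if "F_obs" not in refl.data or "phase" not in refl.data:
        raise ValueError("phased output needs F_obs and phase columns")
    with open(path, "w") as fh:
        fh.write("# h k l F phase_deg sigma\n")
        for _, row in refl.data.iterrows():
            fh.write(f"{int(row.h):4d}{int(row.k):4d}{int(row.l):4d}"
                     f"{row.F_obs:12.5f}{math.degrees(row.phase):10.3f}"
                     f"{row.get('sigma', 0.0):10.5f}\n")


def read_phased_hkl(path) -> ReflectionSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#") or not line.strip():
                continue
            h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
            f, ph, sig = float(line[12:24]), float(line[24:34]), float(line[34:44])
            rows.append((h, k, l, f, math.radians(ph), sig))
    return ReflectionSet(pd.DataFrame(rows, columns=["h", "k", "l", "F_obs",
                                                     "phase", "sigma"]))


def delta_f_table(refl_a: ReflectionSet, refl_b: ReflectionSet,
                  cell=None) -> pd.DataFrame:
    """Per-reflection amplitude difference |F_A| - |F_B|, sorted by |delta|.

    Reproduces the worst-matching-reflection ranking: the first rows are the
    reflections a model gets most wrong on the absolute scale.
    """
    cols_a = refl_a.data.set_index(["h", "k", "l"])
    cols_b = refl_b.data.set_index(["h", "k", "l"])
    if not cols_a.index.equals(cols_b.index):
        if set(cols_a.index) != set(cols_b.index):
            raise ValueError("reflection index sets do not match")
        cols_b = cols_b.loc[cols_a.index]

    def amplitude(df):
        if "F_obs" in df:
            return df["F_obs"].to_numpy(dtype=float)
        if "F_calc" in df:
            return np.abs(df["F_calc"].to_numpy())
        raise ValueError("no amplitude column (F_obs or F_calc)")

    out = pd.DataFrame(index=cols_a.index)
    out["delta_F"] = amplitude(cols_a) - amplitude(cols_b)
    if cell is not None:
        out["d"] = cell.d_spacing(np.array(list(out.index)))
    elif "d" in cols_a:
        out["d"] = cols_a["d"]
    return out.reindex(out["delta_F"].abs().sort_values(ascending=False).index).reset_index()
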