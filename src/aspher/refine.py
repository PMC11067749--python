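"""Weighted least-squares refinement and agreement statistics.

A Levenberg-Marquardt minimizer with numerical central-difference derivatives
(per-parameter-type step sizes) drives two modes:

* structural refinement: per-atom coordinates and displacement parameters
  plus an overall scale, against |F| or |F|^2, honoring special-position
  constraints derived from each site's stabilizer;
* multipole refinement: valence/deformation populations and kappas against
  phased amplitudes with frozen geometry, honoring site-symmetry rules.

Derivative steps: 1e-5 (fractional) for coordinates, 1e-5 A^2 for U, 1e-4
for populations and kappas.  Convergence is max |shift|/esd below threshold;
esds come from the inverse of the weighted normal matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import (CrystalStructure, adp_free_basis, position_free_basis,
                      u_equivalent)
from .scattering import ReflectionSet, StructureFactorCalculator


class RefinementError(RuntimeError):
    pass


@dataclass
class RefinementSpec:
    refine_xyz: bool = True
    refine_adp: bool = True
    refine_scale: bool = True
    target: str = "F2"              # 'F' | 'F2'
    weighting: str = "sigma"        # 'unit' | 'sigma' | 'shelx'
    weight_a: float = 0.0
    weight_b: float = 0.0
    sigma_f2_constant: float | None = None   # e.g. 1.0 to mimic unit-sigma F^2 data
    radiation: str = "electron"
    max_cycles: int = 100
    shift_esd_tol: float = 0.01
    fixed_atoms: tuple = ()

    def __post_init__(self):
        if self.target not in ("F", "F2"):
            raise ValueError("target must be 'F' or 'F2'")
        if self.weighting not in ("unit", "sigma", "shelx"):
            raise ValueError("weighting must be unit, sigma or shelx")
        if self.max_cycles <= 0 or self.shift_esd_tol <= 0:
            raise ValueError("cycle cap and convergence threshold must be positive")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    models: dict
    scale: float
    parameter_names: list
    values: np.ndarray
    esds: np.ndarray
    covariance: np.ndarray
    r_obs: float
    r_all: float
    wr2: float
    history: list
    max_shift_esd: float
    n_cycles: int
    params: list | None = None   # parameter accessors, for esd propagation
    state: object | None = None


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def weight(f_obs2, f_calc2, sigma_f2, a: float = 0.0, b: float = 0.0):
    """SHELX-style weight 1/[sigma^2(F^2) + (aP)^2 + bP].

    P = (1/3) max(0, F_obs^2) + (2/3) F_calc^2; negative measured intensities
    are clamped out of P but retained in the residual.
    """
    f_obs2 = np.asarray(f_obs2, dtype=float)
    f_calc2 = np.asarray(f_calc2, dtype=float)
    sigma_f2 = np.asarray(sigma_f2, dtype=float)
    if np.any(sigma_f2 < 0):
        raise ValueError("sigma(F^2) must be non-negative")
    p = np.maximum(0.0, f_obs2) / 3.0 + 2.0 * f_calc2 / 3.0
    denom = sigma_f2**2 + (a * p) ** 2 + b * p
    if np.any(denom <= 0):
        raise ValueError("weight denominator not positive; adjust a, b or sigmas")
    return 1.0 / denom


def auto_weight_parameters(f_obs2, f_calc2, sigma_f2, n_bins: int = 10) -> tuple:
    """Coarse grid search for (a, b) flattening binned <w delta^2>.

    Emulates automatic weight optimization: the chosen pair minimizes the
    spread of the mean weighted squared residual across intensity bins.
    """
    f_obs2 = np.asarray(f_obs2, float)
    f_calc2 = np.asarray(f_calc2, float)
    order = np.argsort(f_calc2)
    bins = np.array_split(order, n_bins)
    delta2 = (f_obs2 - f_calc2) ** 2
    best = (np.inf, 0.0, 0.0)
    for a in (0.0, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2):
        for b in (0.0, 0.1, 0.5, 1.0, 2.0, 5.0):
            w = weight(f_obs2, f_calc2, sigma_f2, a, b)
            means = np.array([np.mean(w[idx] * delta2[idx]) for idx in bins])
            if np.any(means <= 0):
                continue
            spread = means.max() / means.min()
            # prefer flat bins with overall scale near one
            score = spread + abs(math.log(np.mean(w * delta2)))
            if score < best[0]:
                best = (score, a, b)
    return best[1], best[2]


def r_factor(f_obs, f_calc_amp, scale: float = 1.0, mask=None) -> float:
    """R = 100 * sum | |Fo| - k |Fc| | / sum |Fo| over the selected subset."""
    f_obs = np.asarray(f_obs, dtype=float)
    f_calc_amp = np.asarray(f_calc_amp, dtype=float)
    if mask is not None:
        f_obs, f_calc_amp = f_obs[mask], f_calc_amp[mask]
    if f_obs.size == 0:
        raise ValueError("empty reflection subset for R factor")
    return 100.0 * float(np.sum(np.abs(f_obs - scale * f_calc_amp)) / np.sum(f_obs))


def shell_statistics(refl: ReflectionSet, f_calc_amp, scale: float = 1.0,
                     n_shells: int = 8) -> pd.DataFrame:
    """Equal-count resolution shells (d descending) with per-shell R."""
    if len(refl) < n_shells:
        raise ValueError("fewer reflections than shells")
    d = refl.data["d"].to_numpy(dtype=float)
    f_obs = refl.data["F_obs"].to_numpy(dtype=float)
    f_calc_amp = np.asarray(f_calc_amp, dtype=float)
    order = np.argsort(-d)
    rows = []
    for shell in np.array_split(order, n_shells):
        rows.append({
            "d_max": d[shell].max(), "d_min": d[shell].min(), "n": len(shell),
            "r_percent": r_factor(f_obs[shell], f_calc_amp[shell], scale),
        })
    return pd.DataFrame(rows)


def mean_error(refined, reference) -> float:
    refined = np.asarray(refined, dtype=float)
    reference = np.asarray(reference, dtype=float)
    return float(np.mean(refined - reference))


def rmsd(refined, reference) -> float:
    """Root of the mean squared deviation (the convention that reproduces
    standard bond-length comparison tables)."""
    refined = np.asarray(refined, dtype=float)
    reference = np.asarray(reference, dtype=float)
    return float(np.sqrt(np.mean((refined - reference) ** 2)))


def bond_length_stats(structure: CrystalStructure, bonds, reference) -> dict:
    """Bond lengths vs reference values with ME and RMSD.

    ``bonds``: sequence of (label_a, label_b); ``reference``: matching lengths
    (A) or a dict keyed by the (label_a, label_b) tuples.
    """
    lengths = []
    refs = []
    for pair in bonds:
        a, b = pair
        va = structure.cell.frac_to_cart(structure.site(a).xyz)
        vb = structure.cell.frac_to_cart(structure.site(b).xyz)
        lengths.append(float(np.linalg.norm(va - vb)))
        if isinstance(reference, dict):
            if pair not in reference:
                raise ValueError(f"no reference length for bond {pair}")
            refs.append(reference[pair])
    if not isinstance(reference, dict):
        refs = list(reference)
        if len(refs) != len(lengths):
            raise ValueError("bond list and reference lengths differ in length")
    return {
        "bonds": list(bonds),
        "lengths": lengths,
        "reference": refs,
        "me": mean_error(lengths, refs),
        "rmsd": rmsd(lengths, refs),
    }


def adp_stats(structure: CrystalStructure, reference: CrystalStructure) -> dict:
    """U_eq comparison (ME/RMSD), reported separately for non-H and H."""
    out = {}
    for group, selector in (("non_h", lambda s: s.element != "H"),
                            ("h", lambda s: s.element == "H")):
        labels = [s.label for s in structure.sites if selector(s)]
        refined = [u_equivalent(structure.site(lab), structure.cell) for lab in labels]
        refs = [u_equivalent(reference.site(lab), reference.cell) for lab in labels]
        out[group] = {"labels": labels, "u_eq": refined, "reference": refs,
                      "me": mean_error(refined, refs), "rmsd": rmsd(refined, refs)}
    return out


# ---------------------------------------------------------------------------
# parameter mapping
# ---------------------------------------------------------------------------

_STEP_XYZ = 1e-5
_STEP_U = 1e-5
_STEP_POP = 1e-4


class _Param:
    __slots__ = ("name", "step", "getter", "setter")

    def __init__(self, name, step, getter, setter):
        self.name, self.step = name, step
        self.getter, self.setter = getter, setter


def _structural_parameters(structure: CrystalStructure, spec: RefinementSpec) -> list:
    params = []
    sg, cell = structure.spacegroup, structure.cell
    for site in structure.sites:
        if site.label in spec.fixed_atoms:
            continue
        if spec.refine_xyz:
            basis = position_free_basis(sg, site.xyz)
            for i, bvec in enumerate(basis):
                def getter(st, lab=site.label, b=bvec):
                    return float(b @ st.site(lab).xyz)

                def setter(st, v, lab=site.label, b=bvec):
                    s = st.site(lab)
                    s.xyz = s.xyz + b * (v - b @ s.xyz)
                params.append(_Param(f"{site.label}.xyz{i}", _STEP_XYZ, getter, setter))
        if spec.refine_adp:
            if site.u_aniso is not None:
                basis = adp_free_basis(sg, cell, site.xyz)
                for i, bvec in enumerate(basis):
                    def getter(st, lab=site.label, b=bvec):
                        return float(b @ st.site(lab).u_aniso)

                    def setter(st, v, lab=site.label, b=bvec):
                        s = st.site(lab)
                        s.u_aniso = s.u_aniso + b * (v - b @ s.u_aniso)
                    params.append(_Param(f"{site.label}.U{i}", _STEP_U, getter, setter))
            else:
                def getter(st, lab=site.label):
                    return float(st.site(lab).u_iso)

                def setter(st, v, lab=site.label):
                    st.site(lab).u_iso = v
                params.append(_Param(f"{site.label}.Uiso", _STEP_U, getter, setter))
    return params


def _multipole_parameters(models: dict, refine_kappa: bool = True,
                          refine_kappa_prime: bool = True) -> list:
    params = []
    for label, model in models.items():
        def g_pval(ms, lab=label):
            return ms[lab].p_val

        def s_pval(ms, v, lab=label):
            ms[lab].p_val = v
        params.append(_Param(f"{label}.Pval", _STEP_POP, g_pval, s_pval))
        for lm in model.allowed():
            if lm[0] == 0:
                continue
            model.p_lm.setdefault(lm, 0.0)

            def g_plm(ms, lab=label, key=lm):
                return ms[lab].p_lm.get(key, 0.0)

            def s_plm(ms, v, lab=label, key=lm):
                ms[lab].p_lm[key] = v
            params.append(_Param(f"{label}.P{lm[0]}{lm[1]:+d}", _STEP_POP,
                                 g_plm, s_plm))
        if refine_kappa:
            def g_k(ms, lab=label):
                return ms[lab].kappa

            def s_k(ms, v, lab=label):
                ms[lab].kappa = v
            params.append(_Param(f"{label}.kappa", _STEP_POP, g_k, s_k))
        if refine_kappa_prime and not model.kappa_prime_fixed:
            def g_kp(ms, lab=label):
                return ms[lab].kappa_prime

            def s_kp(ms, v, lab=label):
                ms[lab].kappa_prime = v
            params.append(_Param(f"{label}.kappa_prime", _STEP_POP, g_kp, s_kp))
    return params


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core
# ---------------------------------------------------------------------------

def _lm_minimize(residual_fn, params, state, max_cycles, tol):
    """Generic damped Gauss-Newton loop over _Param objects.

    ``residual_fn(state)`` returns the weighted residual vector for the
    current parameter values; parameters read/write ``state`` through their
    accessors.  Returns (covariance, esds, history, max_shift_esd, cycles).
    """
    n = len(params)
    if n == 0:
        raise RefinementError("no free parameters")
    r = residual_fn()
    chi2 = float(r @ r)
    history = [chi2]
    lam = 1e-4
    max_shift_esd = np.inf
    cycles = 0
    cov = None
    for cycles in range(1, max_cycles + 1):
        jac = np.empty((len(r), n))
        for j, p in enumerate(params):
            v0 = p.getter(state)
            p.setter(state, v0 + p.step)
            r_plus = residual_fn()
            p.setter(state, v0 - p.step)
            r_minus = residual_fn()
            p.setter(state, v0)
            jac[:, j] = (r_plus - r_minus) / (2.0 * p.step)
        normal = jac.T @ jac
        grad = jac.T @ r
        diag = np.diag(normal).copy()
        if np.any(diag <= 0):
            bad = [params[j].name for j in range(n) if diag[j] <= 0]
            raise RefinementError(f"singular normal matrix; null parameters: {bad}")
        accepted = False
        for _ in range(12):
            try:
                shift = np.linalg.solve(normal + lam * np.diag(diag), grad)
            except np.linalg.LinAlgError as exc:
                raise RefinementError(f"normal matrix not solvable: {exc}") from exc
            v0s = [p.getter(state) for p in params]
            for p, v, dv in zip(params, v0s, shift):
                p.setter(state, v - dv)
            r_new = residual_fn()
            chi2_new = float(r_new @ r_new)
            if chi2_new <= chi2 * (1.0 + 1e-12):
                r, chi2 = r_new, chi2_new
                lam = max(lam / 4.0, 1e-12)
                accepted = True
                break
            for p, v in zip(params, v0s):
                p.setter(state, v)
            lam *= 10.0
        if not accepted:
            raise RefinementError("refinement diverged: residual cannot decrease")
        history.append(chi2)
        try:
            cov = np.linalg.inv(normal)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(normal)
            bad = [params[int(np.argmax(np.abs(v[:, i])))].name
                   for i in range(n) if w[i] < 1e-12 * w.max()]
            raise RefinementError(f"singular normal matrix; null parameters: {bad}")
        # esds straight from the inverse normal matrix (weights carry the
        # sigmas, so doubling all sigmas doubles esds); goodness-of-fit
        # normalization is applied by callers that want it
        esds = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.abs(shift) / np.where(esds > 0, esds, np.inf)
        max_shift_esd = float(np.max(ratios))
        if max_shift_esd < tol:
            break
    esds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return cov, esds, history, max_shift_esd, cycles


# ---------------------------------------------------------------------------
# public refinement drivers
# ---------------------------------------------------------------------------

def refine(refl: ReflectionSet, structure: CrystalStructure,
           models: dict | None = None,
           spec: RefinementSpec | None = None) -> RefinementResult:
    """Structural least-squares refinement against |F| or |F|^2."""
    spec = spec or RefinementSpec()
    structure = structure.copy()
    calc = StructureFactorCalculator(structure, models, spec.radiation, refl.hkl)
    params = _structural_parameters(structure, spec)
    for p in params:
        label = p.name.split(".", 1)[0]
        orig = p.setter

        def setter(st, v, _orig=orig, _lab=label):
            _orig(st, v)
            calc.mark_dirty(_lab)
        p.setter = setter
    n_params = len(params) + (1 if spec.refine_scale else 0)
    if n_params >= len(refl):
        raise RefinementError("more parameters than reflections")

    f_obs = refl.data["F_obs"].to_numpy(dtype=float)
    has_i = "I_obs" in refl.data
    i_obs = refl.data["I_obs"].to_numpy(dtype=float) if has_i else f_obs**2
    sigma = refl.data["sigma"].to_numpy(dtype=float) if "sigma" in refl.data \
        else np.zeros(len(refl))
    if spec.sigma_f2_constant is not None:
        sigma = np.full(len(refl), spec.sigma_f2_constant)
    observed = refl.data["observed"].to_numpy(dtype=bool) \
        if "observed" in refl.data else np.ones(len(refl), bool)

    scale_box = {"k": 1.0}
    if spec.refine_scale:
        def g_scale(st):
            return scale_box["k"]

        def s_scale(st, v):
            scale_box["k"] = v
        params = [_Param("scale", 1e-4, g_scale, s_scale)] + params

    def weights_for(y_calc):
        if spec.weighting == "unit":
            return np.ones(len(refl))
        if spec.weighting == "sigma":
            sig = np.where(sigma > 0, sigma, 1.0)
            return 1.0 / sig**2
        return weight(i_obs, y_calc, sigma, spec.weight_a, spec.weight_b)

    def residual():
        f_calc = np.abs(calc.calculate())
        k = scale_box["k"]
        if spec.target == "F2":
            y_obs, y_calc = i_obs, (k * f_calc) ** 2
        else:
            y_obs, y_calc = f_obs, k * f_calc
        return np.sqrt(weights_for(y_calc)) * (y_obs - y_calc)

    # local multipole frames follow the coordinates: they are frozen within
    # an LM pass and rebuilt between passes until self-consistent
    history = []
    cycles = 0
    for _ in range(6):
        cov, esds, pass_hist, max_se, pass_cycles = _lm_minimize(
            residual, params, structure, spec.max_cycles, spec.shift_esd_tol)
        history.extend(pass_hist)
        cycles += pass_cycles
        calc.invalidate_frames()
        r = residual()
        chi2 = float(r @ r)
        if abs(chi2 - pass_hist[-1]) <= 1e-10 * max(chi2, 1.0) + 1e-20:
            break
    f_calc = np.abs(calc.calculate())
    k = scale_box["k"]
    r_all = r_factor(f_obs, f_calc, k)
    r_obs = r_factor(f_obs, f_calc, k, observed) if observed.any() else float("nan")
    w_final = weights_for((k * f_calc) ** 2 if spec.target == "F2" else k * f_calc)
    y_obs = i_obs if spec.target == "F2" else f_obs
    y_calc = (k * f_calc) ** 2 if spec.target == "F2" else k * f_calc
    wr2 = 100.0 * math.sqrt(float(np.sum(w_final * (y_obs - y_calc) ** 2)
                                  / np.sum(w_final * y_obs**2)))
    return RefinementResult(structure, calc.models, k,
                            [p.name for p in params],
                            np.array([p.getter(structure) for p in params]),
                            esds, cov, r_obs, r_all, wr2, history, max_se, cycles,
                            params, structure)


def refine_multipoles(refl: ReflectionSet, structure: CrystalStructure,
                      models: dict, refine_kappa: bool = True,
                      refine_kappa_prime: bool = True,
                      max_cycles: int = 100,
                      shift_esd_tol: float = 0.01,
                      radiation: str = "xray") -> RefinementResult:
    """Fit multipole populations and kappas to phased amplitudes.

    Geometry, ADPs and scale stay frozen (the standard protocol for fitting
    pseudoatom parameters to theoretical structure factors: unit weights, all
    reflections, constrained phases).  Input must carry a ``phase`` column.
    """
    if "phase" not in refl.data:
        raise ValueError("multipole refinement needs phased amplitudes")
    models = {lab: m.copy() for lab, m in models.items()}
    calc = StructureFactorCalculator(structure, models, radiation, refl.hkl)
    params = _multipole_parameters(models, refine_kappa, refine_kappa_prime)
    # wrap setters so only the touched atom's cached form factors refresh
    for p in params:
        label = p.name.split(".", 1)[0]
        orig = p.setter

        def setter(ms, v, _orig=orig, _lab=label):
            _orig(ms, v)
            calc.invalidate_form_factors(_lab)
        p.setter = setter
    f_target = refl.data["F_obs"].to_numpy(dtype=float) * np.exp(
        1j * refl.data["phase"].to_numpy(dtype=float))

    def residual():
        delta = f_target - calc.calculate()
        return np.concatenate([delta.real, delta.imag])

    # stage the kappas in after the populations: with all-zero deformation
    # populations the kappa' derivatives vanish identically
    if (refine_kappa or refine_kappa_prime) and all(
            p == 0.0 for m in models.values() for p in m.p_lm.values()):
        pop_params = [p for p in params if "kappa" not in p.name]
        _lm_minimize(residual, pop_params, models, min(10, max_cycles), shift_esd_tol)
    cov, esds, history, max_se, cycles = _lm_minimize(
        residual, params, models, max_cycles, shift_esd_tol)
    f_calc = np.abs(calc.calculate())
    r_all = r_factor(np.abs(f_target), f_calc, 1.0)
    return RefinementResult(structure, models, 1.0, [p.name for p in params],
                            np.array([p.getter(models) for p in params]),
                            esds, cov, float("nan"), r_all, float("nan"),
                            history, max_se, cycles, params, models)


def bond_esd(result: RefinementResult, pair) -> float:
    """Standard deviation of a bond length from the parameter covariance."""
    if result.params is None:
        raise ValueError("refinement result carries no parameter accessors")
    st = result.structure

    def length():
        va = st.cell.frac_to_cart(st.site(pair[0]).xyz)
        vb = st.cell.frac_to_cart(st.site(pair[1]).xyz)
        return float(np.linalg.norm(va - vb))

    grad = np.zeros(len(result.params))
    for j, p in enumerate(result.params):
        v0 = p.getter(result.state)
        p.setter(result.state, v0 + p.step)
        lp = length()
        p.setter(result.state, v0 - p.step)
        lm = length()
        p.setter(result.state, v0)
        grad[j] = (lp - lm) / (2.0 * p.step)
    return float(math.sqrt(max(grad @ result.covariance @ grad, 0.0)))
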