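"""N-beam Bloch-wave intensities and thickness/scale refinement.

The structure matrix A has diagonal 2 K S_g and off-diagonal elements
U_(g-h), where K = 1/lambda, S_g is the excitation error (signed distance of
the reciprocal-lattice point from the Ewald sphere, S_g > 0 inside the
sphere) and U_g = gamma F_e(g) / (pi V_cell) in 1/A^2 with the electron
structure factor F_e in A and the relativistic factor gamma derived from the
wavelength.  With no absorption the matrix is Hermitian and intensities

    I_g(t) = | sum_j C_gj C*_0j exp(2 pi i gamma_j t) |^2,  gamma_j = w_j/(2K)

conserve sum_g I_g = 1 at every thickness t.

A precessing beam (semi-angle phi) is handled by averaging the static
intensities over equally spaced azimuths of the tilted incident beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import (ELECTRON_MASS, ELEMENTARY_CHARGE, PLANCK_H,
                        SPEED_OF_LIGHT)
from .crystal import CrystalStructure
from .scattering import StructureFactorCalculator

MAX_BEAMS = 500


def gamma_from_wavelength(lam: float) -> float:
    """Relativistic factor of an electron with de Broglie wavelength lam (A)."""
    p = PLANCK_H / (lam * 1e-10)
    return math.sqrt(1.0 + (p / (ELECTRON_MASS * SPEED_OF_LIGHT)) ** 2)


def excitation_error(cell, orientation, lam: float, hkl) -> np.ndarray | float:
    """S_g = (K^2 - |k0 + g|^2) / (2K); positive inside the Ewald sphere.

    ``orientation`` is the unit incident-beam direction in the crystal's
    reciprocal Cartesian frame; tilting the beam towards g reduces |S_g|
    until the reflection crosses the sphere.
    """
    n = np.asarray(orientation, dtype=float)
    n = n / np.linalg.norm(n)
    K = 1.0 / lam
    g = cell.hkl_to_cart(np.atleast_2d(hkl))
    k0 = K * n
    kg = k0[None, :] + g
    s = (K**2 - np.einsum('ni,ni->n', kg, kg)) / (2.0 * K)
    return float(s[0]) if np.asarray(hkl).ndim == 1 else s


def _precession_directions(orientation, phi_deg: float, n_azimuth: int) -> np.ndarray:
    n = np.asarray(orientation, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    phi = math.radians(phi_deg)
    alphas = 2.0 * math.pi * np.arange(n_azimuth) / n_azimuth
    return (math.cos(phi) * n[None, :]
            + math.sin(phi) * (np.cos(alphas)[:, None] * e1[None, :]
                               + np.sin(alphas)[:, None] * e2[None, :]))


def relative_excitation_error(cell, orientation, lam: float, phi_deg: float,
                              hkl, n_azimuth: int = 360) -> np.ndarray | float:
    """RS_g = |S_g(central)| / max_alpha |S_g(alpha)| over the precession cycle."""
    if phi_deg <= 0:
        raise ValueError("RS_g undefined for zero precession angle")
    hkl2 = np.atleast_2d(hkl)
    s_central = np.abs(np.atleast_1d(excitation_error(cell, orientation, lam, hkl2)))
    s_max = np.zeros(len(hkl2))
    for direction in _precession_directions(orientation, phi_deg, n_azimuth):
        s = np.abs(np.atleast_1d(excitation_error(cell, direction, lam, hkl2)))
        s_max = np.maximum(s_max, s)
    out = s_central / np.where(s_max > 0, s_max, np.inf)
    return float(out[0]) if np.asarray(hkl).ndim == 1 else out


@dataclass
class BeamSet:
    """Beams of one diffraction geometry: indices, excitation errors, metadata."""
    hkl: np.ndarray                  # (N, 3) int, row 0 is 000
    s_g: np.ndarray                  # (N,) 1/A at the central orientation
    rs_g: np.ndarray | None
    orientation: np.ndarray          # unit incident-beam direction
    wavelength: float                # A
    phi_deg: float = 0.0

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        if len(self.hkl) < 2:
            raise ValueError("a beam set needs the 000 beam and at least one reflection")
        if np.any(self.hkl[0] != 0):
            raise ValueError("first beam must be 000")
        if len(self.hkl) > MAX_BEAMS:
            raise ValueError(f"beam count {len(self.hkl)} exceeds cap {MAX_BEAMS}")


def select_beams(cell, hkl_pool, orientation, lam: float, phi_deg: float = 0.0,
                 d_min: float = 0.56, s_max: float = 0.02,
                 rs_max: float = 0.75, n_azimuth: int = 360) -> BeamSet:
    """Apply the resolution, S_g and RS_g cuts and order the surviving beams.

    Ordering is deterministic: by |g| then lexicographic hkl; 000 leads.
    """
    if d_min <= 0 or s_max <= 0 or rs_max <= 0:
        raise ValueError("selection thresholds must be positive")
    hkl_pool = np.atleast_2d(np.asarray(hkl_pool, dtype=int))
    nonzero = np.any(hkl_pool != 0, axis=1)
    hkl_pool = hkl_pool[nonzero]
    d = np.asarray(cell.d_spacing(hkl_pool))
    keep = d >= d_min
    s = np.atleast_1d(excitation_error(cell, orientation, lam, hkl_pool))
    keep &= np.abs(s) <= s_max
    if phi_deg > 0 and np.isfinite(rs_max):
        rs = np.atleast_1d(relative_excitation_error(cell, orientation, lam,
                                                     phi_deg, hkl_pool, n_azimuth))
        keep &= rs <= rs_max
    else:
        rs = np.full(len(hkl_pool), np.nan)
    if not np.any(keep):
        raise ValueError("no beams survive the selection cuts")
    hkl_sel = hkl_pool[keep]
    g = np.linalg.norm(cell.hkl_to_cart(hkl_sel), axis=1)
    order = np.lexsort((hkl_sel[:, 2], hkl_sel[:, 1], hkl_sel[:, 0], g))
    hkl_sel = hkl_sel[order]
    hkl_all = np.vstack([[0, 0, 0], hkl_sel])
    s_all = np.concatenate([[0.0], s[keep][order]])
    rs_all = np.concatenate([[0.0], rs[keep][order]]) if phi_deg > 0 else None
    return BeamSet(hkl_all, s_all, rs_all, np.asarray(orientation, float),
                   lam, phi_deg)


class BlochSolver:
    """Caches the U_g table of a structure for repeated intensity evaluations."""

    def __init__(self, structure: CrystalStructure, models: dict | None,
                 beams: BeamSet):
        self.structure = structure
        self.beams = beams
        self.K = 1.0 / beams.wavelength
        n = len(beams.hkl)
        diff = beams.hkl[:, None, :] - beams.hkl[None, :, :]
        flat = diff.reshape(-1, 3)
        uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
        nonzero = np.any(uniq != 0, axis=1)
        f_e = np.zeros(len(uniq), dtype=complex)
        if np.any(nonzero):
            calc = StructureFactorCalculator(structure, models, "electron",
                                             uniq[nonzero])
            f_e[nonzero] = calc.calculate()
        gamma = gamma_from_wavelength(beams.wavelength)
        u = gamma * f_e / (math.pi * structure.cell.volume)
        self._u_matrix = u[inverse].reshape(n, n)
        np.fill_diagonal(self._u_matrix, 0.0)

    def intensities(self, thickness_nm: float, s_g=None) -> np.ndarray:
        """I_g at the exit face for every beam; thickness in nm."""
        if thickness_nm < 0:
            raise ValueError("thickness must be non-negative")
        s = self.beams.s_g if s_g is None else s_g
        a = self._u_matrix + np.diag(2.0 * self.K * s).astype(complex)
        if np.abs(a - a.conj().T).max() > 1e-10:
            raise RuntimeError("structure matrix not Hermitian (internal error)")
        w, c = np.linalg.eigh(a)
        t = 10.0 * thickness_nm  # nm -> A
        phase = np.exp(1j * math.pi * w * t / self.K)
        amp = c @ (phase * c[0].conj())
        return np.abs(amp) ** 2

    def kinematical_intensities(self, thickness_nm: float, s_g=None) -> np.ndarray:
        """First-order (single-scattering) intensities in the same geometry.

        I_g = (pi U_g t / K)^2 sinc^2(t S_g); the difference from the Bloch
        result isolates multiple scattering with identical beam geometry.
        """
        s = self.beams.s_g if s_g is None else s_g
        t = 10.0 * thickness_nm
        u_row = np.abs(self._u_matrix[0])
        out = (math.pi * u_row * t / self.K) ** 2 * np.sinc(np.asarray(s) * t) ** 2
        out[0] = max(0.0, 1.0 - out[1:].sum())
        return out

    def precession_intensities(self, thickness_nm: float, n_azimuth: int = 64,
                               kinematical: bool = False) -> np.ndarray:
        """Intensities averaged over the precession cone (phi from the BeamSet)."""
        evaluate = self.kinematical_intensities if kinematical else self.intensities
        if self.beams.phi_deg <= 0:
            return evaluate(thickness_nm)
        if n_azimuth < 4:
            raise ValueError("need at least 4 azimuths")
        cell = self.structure.cell
        total = np.zeros(len(self.beams.hkl))
        for direction in _precession_directions(self.beams.orientation,
                                                self.beams.phi_deg, n_azimuth):
            s = np.atleast_1d(excitation_error(cell, direction,
                                               self.beams.wavelength,
                                               self.beams.hkl))
            s[0] = 0.0
            total += evaluate(thickness_nm, s)
        return total / n_azimuth


def bloch_intensities(structure: CrystalStructure, models: dict | None,
                      beams: BeamSet, thickness_nm: float) -> np.ndarray:
    return BlochSolver(structure, models, beams).intensities(thickness_nm)


def two_beam_intensity(u_g: float, s_g: float, K: float, thickness_a: float) -> float:
    """Analytic pendelloesung for the restricted two-beam case (oracle).

    I_g = (U_g / (2 K s_eff))^2 sin^2(pi t s_eff),
    s_eff = sqrt(S_g^2 + (U_g/K)^2).
    """
    s_eff = math.sqrt(s_g**2 + (u_g / K) ** 2)
    if s_eff == 0:
        return 0.0
    return (u_g / (K * s_eff)) ** 2 * math.sin(math.pi * thickness_a * s_eff) ** 2


# ---------------------------------------------------------------------------
# frames and thickness refinement
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One synthetic diffraction frame: geometry plus measured intensities."""
    crystal: str
    orientation: np.ndarray
    phi_deg: float
    wavelength: float
    hkl: np.ndarray
    i_obs: np.ndarray
    sigma: np.ndarray

    def beam_set(self, cell) -> BeamSet:
        s = np.atleast_1d(excitation_error(cell, self.orientation,
                                           self.wavelength, self.hkl))
        hkl = np.vstack([[0, 0, 0], self.hkl])
        return BeamSet(hkl, np.concatenate([[0.0], s]), None,
                       self.orientation, self.wavelength, self.phi_deg)


def write_frames(frames, path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"frame crystal={fr.crystal} "
                     f"orientation={fr.orientation[0]:.8f},{fr.orientation[1]:.8f},"
                     f"{fr.orientation[2]:.8f} phi={fr.phi_deg:.4f} "
                     f"lambda={fr.wavelength:.6f}\n")
            for hkl, i, sig in zip(fr.hkl, fr.i_obs, fr.sigma):
                fh.write(f"{hkl[0]:4d}{hkl[1]:4d}{hkl[2]:4d}{i:14.6e}{sig:14.6e}\n")


def read_frames(path) -> list:
    frames = []
    current = None

    def flush():
        if current is not None:
            frames.append(Frame(current["crystal"], current["orientation"],
                                current["phi"], current["lambda"],
                                np.array(current["hkl"], dtype=int),
                                np.array(current["i"]), np.array(current["sig"])))

    with open(path) as fh:
        for line in fh:
            if line.startswith("frame "):
                flush()
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                current = {"crystal": fields["crystal"],
                           "orientation": np.array([float(v) for v in
                                                    fields["orientation"].split(",")]),
                           "phi": float(fields["phi"]),
                           "lambda": float(fields["lambda"]),
                           "hkl": [], "i": [], "sig": []}
            elif line.strip():
                current["hkl"].append([int(line[0:4]), int(line[4:8]), int(line[8:12])])
                current["i"].append(float(line[12:26]))
                current["sig"].append(float(line[26:40]))
    flush()
    return frames


@dataclass
class ThicknessResult:
    thickness_nm: dict              # per crystal
    scales: list                    # per frame
    r_obs: float
    r_all: float
    per_frame_r: list


def refine_thickness_scale(frames, structure: CrystalStructure,
                           models: dict | None = None,
                           t_bounds=(5.0, 400.0),
                           n_azimuth: int = 32) -> ThicknessResult:
    """Fit one thickness per crystal and one scale per frame to |F| residuals.

    The per-frame scale is profiled analytically inside the 1-D thickness
    search (bounded Brent).  A thickness hitting the lower bound signals the
    degenerate scale/thickness correlation of the t -> 0 kinematical limit.
    """
    if not frames:
        raise ValueError("no frames supplied")
    solvers = [BlochSolver(structure, models, fr.beam_set(structure.cell))
               for fr in frames]
    by_crystal = {}
    for idx, fr in enumerate(frames):
        by_crystal.setdefault(fr.crystal, []).append(idx)

    def frame_residual(idx, t_nm):
        fr = frames[idx]
        i_model = solvers[idx].precession_intensities(t_nm, n_azimuth)[1:]
        f_model = np.sqrt(np.maximum(i_model, 0.0))
        f_obs = np.sqrt(np.maximum(fr.i_obs, 0.0))
        denom = float(f_model @ f_model)
        scale = float(f_obs @ f_model) / denom if denom > 0 else 0.0
        return f_obs - scale * f_model, scale, f_obs, f_model

    thickness = {}
    for crystal, idxs in by_crystal.items():
        def cost(t_nm):
            total = 0.0
            for i in idxs:
                resid = frame_residual(i, t_nm)[0]
                total += float(resid @ resid)
            return total
        res = minimize_scalar(cost, bounds=t_bounds, method="bounded",
                              options={"xatol": 0.01})
        thickness[crystal] = float(res.x)
        if res.x <= t_bounds[0] * 1.01:
            import warnings
            warnings.warn(f"crystal {crystal}: thickness at lower bound; "
                          "scale/thickness degenerate near t = 0")

    scales, num_all, den_all, num_obs, den_obs = [], 0.0, 0.0, 0.0, 0.0
    per_frame_r = []
    for idx, fr in enumerate(frames):
        resid, scale, f_obs, f_model = frame_residual(idx, thickness[fr.crystal])
        scales.append(scale)
        num = float(np.sum(np.abs(resid)))
        den = float(np.sum(f_obs))
        per_frame_r.append(100.0 * num / den if den else float("nan"))
        num_all += num
        den_all += den
        observed = fr.i_obs > 3.0 * fr.sigma
        if observed.any():
            num_obs += float(np.sum(np.abs(resid[observed])))
            den_obs += float(np.sum(f_obs[observed]))
    return ThicknessResult(thickness, scales,
                           100.0 * num_obs / den_obs if den_obs else float("nan"),
                           100.0 * num_all / den_all, per_frame_r)


def mean_inner_potential(structure: CrystalStructure, models: dict | None = None) -> float:
    """Mean inner potential (V) from the s -> 0 Mott-Bethe monopole limit.

    Uses f_e(0) = C (4 pi)^2 <r^2> / 6 per atom, with <r^2> of the model
    electron density; V_0 = h^2 F_e(0) / (2 pi m0 e V_cell).
    """
    from .multipole import spherical_model
    from .slater import shell_table

    models = dict(models or {})
    total = 0.0
    st_p1 = structure.expand_to_unit_cell() if len(structure.spacegroup) > 1 \
        else structure
    for site in st_p1.sites:
        model = models.get(site.label) or spherical_model(site.element)
        r2 = 0.0
        data = shell_table()[model.element]
        for part, pop, scale in (("core", model.p_core, 1.0),
                                 ("valence", model.p_val, model.kappa)):
            shells = data[part]
            n_el = sum(occ for _, _, occ in shells)
            if not shells or n_el == 0 or pop == 0:
                continue
            for nq, zeta_bohr, occ in shells:
                from .constants import BOHR_RADIUS_ANGSTROM
                zeta = 2.0 * zeta_bohr / BOHR_RADIUS_ANGSTROM * scale
                n = 2 * (nq - 1)
                r2 += pop * (occ / n_el) * (n + 4) * (n + 3) / zeta**2
        from .constants import MOTT_BETHE_CONSTANT
        total += site.occupancy * MOTT_BETHE_CONSTANT * (4.0 * math.pi) ** 2 * r2 / 6.0
    v_cell = structure.cell.volume
    return PLANCK_H**2 / (2.0 * math.pi * ELECTRON_MASS * ELEMENTARY_CHARGE) \
        * (total * 1e-10) / (v_cell * 1e-30)
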