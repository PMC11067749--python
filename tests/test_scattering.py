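"""Wavelength, Mott-Bethe, Debye-Waller and crystal structure factors."""

import math

import numpy as np
import pytest

from aspher.constants import (MOTT_BETHE_CONSTANT, electron_wavelength,
                              electron_wavelength_nonrelativistic)
from aspher.crystal import AtomSite, CrystalStructure, P1, UnitCell
from aspher.fixtures import unique_reflections
from aspher.multipole import aspherical_form_factor, spherical_model
from aspher.scattering import (ReflectionSet, StructureFactorCalculator,
                               debye_waller, delta_f_table, mott_bethe,
                               read_phased_hkl, read_shelx_hkl,
                               structure_factor, write_phased_hkl,
                               write_shelx_hkl)
from aspher.slater import element_number, spherical_form_factor


class TestWavelength:
    def test_200_kv_value(self):
        # 3 s.f. check of the relativistic formula
        assert electron_wavelength(200.0) == pytest.approx(0.0251, abs=5e-5)

    def test_low_voltage_classical_limit(self):
        rel = electron_wavelength(1.0)
        cls = electron_wavelength_nonrelativistic(1.0)
        assert abs(rel - cls) / rel < 1e-3

    def test_100_kv_against_symbolic_evaluation(self):
        # oracle: term-by-term evaluation with CODATA constants
        h, m0, e, c = 6.62607015e-34, 9.1093837015e-31, 1.602176634e-19, 299792458.0
        v = 100e3
        expected = h / math.sqrt(2 * m0 * e * v * (1 + e * v / (2 * m0 * c * c))) * 1e10
        assert electron_wavelength(100.0) == pytest.approx(expected, rel=1e-14)

    def test_mott_bethe_constant_value(self):
        assert MOTT_BETHE_CONSTANT == pytest.approx(0.023934, abs=1e-6)


class TestMottBethe:
    def test_zero_for_fully_screened_atom(self):
        assert mott_bethe(6.0, 6.0, 0.5) == pytest.approx(0.0)

    def test_s_zero_rejected(self):
        with pytest.raises(ValueError):
            mott_bethe(6.0, 5.0, 0.0)

    def test_linearity_over_atoms(self, rng):
        s = 0.31
        f1 = float(spherical_form_factor("C", s))
        f2 = float(spherical_form_factor("O", s))
        combined = mott_bethe(6 + 8, f1 + f2, s)
        separate = mott_bethe(6, f1, s) + mott_bethe(8, f2, s)
        assert combined == pytest.approx(separate, abs=1e-12)

    def test_neutral_atom_small_s_limit(self):
        """Oracle: series expansion Z - f(s) ~ (4 pi s)^2 <r^2>/6 near zero."""
        from aspher.slater import core_valence_radials
        shells = sum(core_valence_radials("C"), ())
        r2 = sum(occ * (rad.n + 4) * (rad.n + 3) / rad.zeta**2
                 for rad, occ in shells)
        limit = MOTT_BETHE_CONSTANT * (4 * math.pi) ** 2 * r2 / 6.0
        s = 1e-4
        val = mott_bethe(6.0, float(spherical_form_factor("C", s)), s)
        assert val == pytest.approx(limit, rel=1e-5)


class TestDebyeWaller:
    def setup_method(self):
        self.cell = UnitCell(7.0, 9.0, 11.0)

    def test_zero_u_gives_unity(self):
        site = AtomSite("X", "C", [0, 0, 0], u_iso=0.0)
        assert debye_waller(site, (3, 1, 2), self.cell) == pytest.approx(1.0)

    def test_isotropic_tensor_equals_isotropic_formula(self):
        u = 0.025
        aniso = AtomSite("X", "C", [0, 0, 0], u_aniso=[u, u, u, 0, 0, 0])
        iso = AtomSite("Y", "C", [0, 0, 0], u_iso=u)
        for hkl in [(1, 0, 0), (2, 3, 1), (0, 0, 5)]:
            assert debye_waller(aniso, hkl, self.cell) == pytest.approx(
                debye_waller(iso, hkl, self.cell), rel=1e-12)

    def test_random_tensor_matches_gaussian_smearing_ft(self, rng):
        """Oracle: numerical FT of a Gaussian-smeared point scatterer."""
        a = rng.normal(size=(3, 3))
        u_cart = a @ a.T * 0.004
        n = self.cell.orthogonalization @ np.diag(self.cell.reciprocal_lengths)
        n_inv = np.linalg.inv(n)
        u_cif = n_inv @ u_cart @ n_inv.T
        site = AtomSite("X", "C", [0, 0, 0],
                        u_aniso=[u_cif[0, 0], u_cif[1, 1], u_cif[2, 2],
                                 u_cif[0, 1], u_cif[0, 2], u_cif[1, 2]])
        hkl = np.array([2, -1, 3])
        q = 2.0 * math.pi * self.cell.hkl_to_cart(hkl)
        expected = math.exp(-0.5 * q @ u_cart @ q)   # Gaussian characteristic fn
        assert debye_waller(site, hkl, self.cell) == pytest.approx(expected, rel=1e-10)

    def test_non_psd_tensor_rejected(self):
        with pytest.raises(ValueError):
            AtomSite("X", "C", [0, 0, 0], u_aniso=[0.01, 0.01, -0.05, 0, 0, 0])


class TestStructureFactor:
    def test_single_atom_at_origin(self):
        cell = UnitCell(10, 10, 10)
        st = CrystalStructure(cell, P1, [AtomSite("C1", "C", [0, 0, 0], u_iso=0.0)])
        hkl = np.array([[1, 0, 0], [2, 1, 0], [1, 1, 1]])
        f = structure_factor(st, hkl, radiation="xray")
        s = 0.5 / np.asarray(cell.d_spacing(hkl))
        np.testing.assert_allclose(f.real, spherical_form_factor("C", s), rtol=1e-10)
        np.testing.assert_allclose(f.imag, 0.0, atol=1e-12)

    def test_centrosymmetric_phases_and_real_electron_f(self, structure,
                                                        models_databank):
        hkl = unique_reflections(structure.cell, structure.spacegroup, 1.3)
        f = structure_factor(structure, hkl, models_databank, "electron")
        assert np.abs(f.imag).max() < 1e-8 * np.abs(f).max()

    def test_friedel_pairs_conjugate(self, structure, models_databank):
        hkl = np.array([[1, 1, 0], [2, 1, 1], [3, -2, 1], [0, 2, 2]])
        calc_p = structure_factor(structure, hkl, models_databank, "xray")
        calc_m = structure_factor(structure, -hkl, models_databank, "xray")
        np.testing.assert_allclose(calc_m, np.conj(calc_p), rtol=1e-10)

    def test_symmetry_equivalent_amplitudes_equal(self, structure, models_databank):
        h = np.array([2, 3, 1])
        equivalents = {tuple(r.T @ h) for r in structure.spacegroup.laue_rotations()}
        f = structure_factor(structure, np.array(sorted(equivalents)),
                             models_databank, "electron")
        amps = np.abs(f)
        np.testing.assert_allclose(amps, amps[0], rtol=1e-10)

    def test_ibam_matches_brute_force_p1_expansion(self, structure,
                                                   models_databank, rng):
        """Oracle: explicit sum over every symmetry image with individually
        rotated local frames, ADP tensors and positions."""
        from aspher.crystal import u_vector_to_matrix

        hkl_all = unique_reflections(structure.cell, structure.spacegroup, 1.0)
        hkl = hkl_all[rng.choice(len(hkl_all), 200, replace=False)]
        calc = StructureFactorCalculator(structure, models_databank,
                                         "electron", hkl)
        engine = calc.calculate()

        cell = structure.cell
        A = cell.orthogonalization
        rec = cell.reciprocal_lengths
        dstar = np.diag(rec)
        s = 0.5 / np.asarray(cell.d_spacing(hkl))
        u_hat = cell.hkl_to_cart(hkl)
        u_hat /= np.linalg.norm(u_hat, axis=1, keepdims=True)
        total = np.zeros(len(hkl), dtype=complex)
        for site in structure.sites:
            frame = calc.local_rotation(site.label)
            seen = []
            for op in structure.spacegroup.ops:
                x = op.apply(site.xyz)
                key = tuple(np.round(np.mod(x, 1), 6))
                if key in seen:
                    continue
                seen.append(key)
                m = op.rot_array.astype(float)
                r_cart = A @ m @ np.linalg.inv(A)
                fx = aspherical_form_factor(models_databank[site.label], s,
                                            u_hat @ (r_cart @ frame))
                fe = MOTT_BETHE_CONSTANT * (element_number(site.element) - fx) / s**2
                u = u_vector_to_matrix(site.u_aniso) if site.u_aniso is not None \
                    else np.eye(3) * (site.u_iso or 0.0)
                c2 = m @ (dstar @ u @ dstar) @ m.T
                ui = np.diag(1 / rec) @ c2 @ np.diag(1 / rec)
                q = hkl.astype(float) * rec
                dw = np.exp(-2 * math.pi**2 * np.einsum('ni,ij,nj->n', q, ui, q))
                total += site.occupancy * fe * dw * np.exp(2j * math.pi * (hkl @ x))
        assert np.abs(total - engine).max() < 1e-10 * np.abs(total).max()

    def test_dirty_tracking_consistent_with_fresh_calculation(self, structure,
                                                              models_databank):
        hkl = unique_reflections(structure.cell, structure.spacegroup, 1.4)
        # spherical models carry no local frame, so an incremental update
        # must match a from-scratch calculation exactly
        calc = StructureFactorCalculator(structure.copy(), None, "electron", hkl)
        calc.calculate()
        site = calc.structure.site("O4")
        site.xyz = site.xyz + [1e-3, -2e-3, 0.0]
        calc.mark_dirty("O4")
        incremental = calc.calculate()
        fresh = structure_factor(calc.structure, hkl, None, "electron")
        np.testing.assert_allclose(incremental, fresh, rtol=1e-12)
        # with multipole models the frames follow only after invalidation
        calc2 = StructureFactorCalculator(structure.copy(), models_databank,
                                          "electron", hkl)
        calc2.calculate()
        site2 = calc2.structure.site("O4")
        site2.xyz = site2.xyz + [1e-3, -2e-3, 0.0]
        calc2.invalidate_frames()
        fresh2 = structure_factor(calc2.structure, hkl, models_databank,
                                  "electron")
        np.testing.assert_allclose(calc2.calculate(), fresh2, rtol=1e-12)


class TestReflectionIO:
    def make_set(self):
        import pandas as pd
        df = pd.DataFrame({
            "h": [1, 2, -1], "k": [0, 1, 1], "l": [0, -1, 2],
            "F_obs": [12.34, 5.6, 0.12], "I_obs": [152.28, 31.36, 0.01],
            "sigma": [1.2, 0.8, 0.05], "phase": [0.0, math.pi, 0.0]})
        return ReflectionSet(df)

    def test_shelx_round_trip(self, tmp_path):
        refl = self.make_set()
        for hklf in (3, 4):
            path = tmp_path / f"test{hklf}.hkl"
            write_shelx_hkl(refl, path, hklf=hklf)
            back = read_shelx_hkl(path, hklf=hklf)
            assert len(back) == 3
            col = "F_obs" if hklf == 3 else "I_obs"
            np.testing.assert_allclose(back.data[col],
                                       np.round(refl.data[col], 2))

    def test_phased_round_trip(self, tmp_path):
        refl = self.make_set()
        path = tmp_path / "phased.hkl"
        write_phased_hkl(refl, path)
        back = read_phased_hkl(path)
        np.testing.assert_allclose(back.data["F_obs"], refl.data["F_obs"],
                                   atol=1e-5)
        np.testing.assert_allclose(back.data["phase"], refl.data["phase"],
                                   atol=1e-5)

    def test_observed_flag_follows_three_sigma(self):
        refl = self.make_set().flag_observed()
        np.testing.assert_array_equal(refl.data["observed"],
                                      [True, True, False])

    def test_negative_sigma_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            ReflectionSet(pd.DataFrame({"h": [1], "k": [0], "l": [0],
                                        "sigma": [-1.0]}))


class TestDeltaFTable:
    def test_identical_sets_give_zero(self, structure, models_databank,
                                      electron_data):
        refl, _ = electron_data
        table = delta_f_table(refl, refl, structure.cell)
        assert np.allclose(table["delta_F"], 0.0)

    def test_single_perturbed_reflection_ranks_first(self, electron_data,
                                                     structure):
        refl, _ = electron_data
        bumped = refl.copy()
        bumped.data.loc[37, "F_obs"] += 5.0
        table = delta_f_table(bumped, refl, structure.cell)
        assert table.loc[0, "delta_F"] == pytest.approx(5.0)
        assert np.abs(table["delta_F"][1:]).max() < 1e-10

    def test_iam_vs_multipole_differences_peak_at_low_resolution(
            self, structure, models_databank, electron_data):
        refl, _ = electron_data
        iam_amp = np.abs(structure_factor(structure, refl.hkl, None, "electron"))
        import pandas as pd
        iam = ReflectionSet(pd.DataFrame({
            "h": refl.data.h, "k": refl.data.k, "l": refl.data.l,
            "F_obs": iam_amp}))
        table = delta_f_table(iam, refl, structure.cell)
        d = table["d"].to_numpy()
        adf = np.abs(table["delta_F"].to_numpy())
        order = np.argsort(-d)
        shells = np.array_split(order, 5)
        means = [np.mean(adf[sh]) for sh in shells]
        assert means[0] == max(means)
        assert all(means[i] >= means[i + 1] for i in range(len(means) - 1))

    def test_mismatched_index_sets_rejected(self, electron_data):
        refl, _ = electron_data
        other = ReflectionSet(refl.data.iloc[:-3].copy())
        with pytest.raises(ValueError, match="match"):
            delta_f_table(refl, other)
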