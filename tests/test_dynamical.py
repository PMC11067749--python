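"""Excitation errors, beam selection, Bloch-wave solver and thickness fits."""

import numpy as np
import pytest

from aspher.dynamical import (BeamSet, BlochSolver, Frame, excitation_error,
                              gamma_from_wavelength, read_frames,
                              refine_thickness_scale,
                              relative_excitation_error, select_beams,
                              two_beam_intensity, write_frames)
from aspher.fixtures import full_reflections, simulate_frames

LAMBDA = 0.0251
ZONE = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="module")
def beam_pool(structure):
    return full_reflections(structure.cell, structure.spacegroup, 1.2)


@pytest.fixture(scope="module")
def zone_beams(structure, beam_pool):
    return select_beams(structure.cell, beam_pool, ZONE, LAMBDA, phi_deg=0.7,
                        d_min=1.2)


@pytest.fixture(scope="module")
def zone_solver(structure, models_databank, zone_beams):
    return BlochSolver(structure, models_databank, zone_beams)


class TestExcitationError:
    def test_bragg_condition_zero(self, structure):
        # orientation tilted so that |k0 + g| = K exactly
        cell = structure.cell
        g = cell.hkl_to_cart(np.array([2, 0, 0]))
        K = 1.0 / LAMBDA
        gn = np.linalg.norm(g)
        # incident beam: component -g/2 plus orthogonal component to reach |k0|=K
        ortho = np.array([0.0, 0.0, 1.0])
        k0 = -g / 2 + ortho * np.sqrt(K**2 - (gn / 2) ** 2)
        s = excitation_error(cell, k0 / np.linalg.norm(k0), LAMBDA,
                             np.array([2, 0, 0]))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_zone_axis_zero_layer_formula(self, structure):
        for hkl in [(1, 1, 0), (2, 0, 0), (3, 1, 0)]:
            g2 = np.sum(structure.cell.hkl_to_cart(np.array(hkl)) ** 2)
            s = excitation_error(structure.cell, ZONE, LAMBDA, np.array(hkl))
            assert s == pytest.approx(-g2 * LAMBDA / 2.0, abs=1e-10)

    def test_tilt_continuity_before_crossing(self, structure):
        """|S_g| shrinks monotonically as the beam tilts the relp towards the
        sphere, until the Bragg condition is crossed."""
        hkl = np.array([2, 2, 0])
        g = structure.cell.hkl_to_cart(hkl)
        ghat = g / np.linalg.norm(g)
        mags = []
        for eps in (0.0, 0.001, 0.002, 0.003):
            tilted = ZONE - eps * ghat
            tilted /= np.linalg.norm(tilted)
            mags.append(abs(excitation_error(structure.cell, tilted, LAMBDA, hkl)))
        assert mags == sorted(mags, reverse=True)


class TestRelativeExcitationError:
    def test_zero_at_central_bragg(self, structure):
        cell = structure.cell
        g = cell.hkl_to_cart(np.array([2, 0, 0]))
        K = 1.0 / LAMBDA
        k0 = -g / 2 + np.array([0, 0, 1.0]) * np.sqrt(K**2 - (g @ g) / 4)
        rs = relative_excitation_error(cell, k0 / np.linalg.norm(k0), LAMBDA,
                                       0.7, np.array([2, 0, 0]))
        assert rs == pytest.approx(0.0, abs=1e-9)

    def test_grid_refinement_stable(self, structure):
        hkl = np.array([[2, 2, 0], [1, 3, 0], [2, 0, 2]])
        rs_360 = relative_excitation_error(structure.cell, ZONE, LAMBDA, 0.7,
                                           hkl, n_azimuth=360)
        rs_720 = relative_excitation_error(structure.cell, ZONE, LAMBDA, 0.7,
                                           hkl, n_azimuth=720)
        np.testing.assert_allclose(rs_360, rs_720, atol=1e-4)

    def test_bounded_by_one_when_crossing(self, structure, beam_pool):
        rs = relative_excitation_error(structure.cell, ZONE, LAMBDA, 0.7,
                                       beam_pool[:200])
        s_central = np.abs(np.atleast_1d(excitation_error(
            structure.cell, ZONE, LAMBDA, beam_pool[:200])))
        # a reflection that crosses the sphere reaches |S| = 0 < central value
        crossing = rs[s_central > 1e-6]
        assert np.all(crossing <= 1.0 + 1e-9)

    def test_zero_precession_angle_rejected(self, structure):
        with pytest.raises(ValueError):
            relative_excitation_error(structure.cell, ZONE, LAMBDA, 0.0,
                                      np.array([1, 1, 0]))


class TestSelectBeams:
    def test_loose_thresholds_keep_everything(self, structure):
        pool = full_reflections(structure.cell, structure.spacegroup, 2.0)
        beams = select_beams(structure.cell, pool, ZONE, LAMBDA,
                             phi_deg=0.0, d_min=2.0, s_max=1e6, rs_max=np.inf)
        assert len(beams.hkl) == len(pool) + 1

    def test_tight_s_cut_keeps_only_bragg(self, structure, beam_pool):
        with pytest.raises(ValueError):
            select_beams(structure.cell, beam_pool, ZONE, LAMBDA,
                         phi_deg=0.0, d_min=1.2, s_max=1e-9)

    def test_matches_brute_force_filter(self, structure, beam_pool, zone_beams):
        cell = structure.cell
        kept = []
        for h in beam_pool:
            d = cell.d_spacing(h)
            s = excitation_error(cell, ZONE, LAMBDA, h)
            rs = relative_excitation_error(cell, ZONE, LAMBDA, 0.7, h)
            if d >= 1.2 and abs(s) <= 0.02 and rs <= 0.75:
                kept.append(tuple(h))
        assert set(map(tuple, zone_beams.hkl[1:])) == set(kept)

    def test_deterministic_ordering(self, structure, zone_beams):
        g = np.linalg.norm(structure.cell.hkl_to_cart(zone_beams.hkl[1:]), axis=1)
        assert np.all(np.diff(g) >= -1e-12)

    def test_000_leads_and_validation(self, zone_beams):
        assert tuple(zone_beams.hkl[0]) == (0, 0, 0)
        with pytest.raises(ValueError):
            BeamSet(np.array([[1, 0, 0], [0, 0, 0]]), np.zeros(2), None,
                    ZONE, LAMBDA)


class TestBlochSolver:
    def test_zero_thickness(self, zone_solver):
        inten = zone_solver.intensities(0.0)
        assert inten[0] == pytest.approx(1.0)
        assert inten[1:].max() < 1e-20

    @pytest.mark.parametrize("t_nm", [40.0, 120.0, 333.0])
    def test_unitarity_without_absorption(self, zone_solver, t_nm):
        assert zone_solver.intensities(t_nm).sum() == pytest.approx(1.0, abs=1e-10)

    def test_two_beam_matches_pendelloesung(self, structure, models_databank):
        """Oracle: the analytic closed form, over an (S_g, t) grid."""
        K = 1.0 / LAMBDA
        hkl = np.array([[0, 0, 0], [2, 2, 0]])
        for s_g in (0.0, 0.002, -0.005):
            beams = BeamSet(hkl, np.array([0.0, s_g]), None, ZONE, LAMBDA)
            solver = BlochSolver(structure, models_databank, beams)
            u_g = abs(solver._u_matrix[0, 1])
            for t_nm in (25.0, 80.0, 210.0):
                numeric = solver.intensities(t_nm)[1]
                analytic = two_beam_intensity(u_g, s_g, K, 10.0 * t_nm)
                assert abs(numeric - analytic) < 1e-8

    def test_thin_crystal_kinematical_limit(self, structure, models_databank,
                                            zone_beams):
        """As t -> 0, I_g approaches (pi U_g t / K)^2 sinc^2(t S_g) for every
        beam that is kinematically allowed; weak beams acquire relative
        intensity only through double scattering, which dies as t^2."""
        solver = BlochSolver(structure, models_databank, zone_beams)
        t_nm = 0.5
        inten = solver.intensities(t_nm)[1:]
        expected = solver.kinematical_intensities(t_nm)[1:]
        strong = expected > expected.max() * 1e-3
        rel = np.abs(inten[strong] - expected[strong]) / expected[strong]
        assert rel.max() < 5e-2
        # and the error contracts quadratically with thickness
        rel2 = np.abs(solver.intensities(2 * t_nm)[1:]
                      - solver.kinematical_intensities(2 * t_nm)[1:])[strong] \
            / solver.kinematical_intensities(2 * t_nm)[1:][strong]
        assert np.median(rel2) > 2.0 * np.median(rel)

    def test_negative_thickness_rejected(self, zone_solver):
        with pytest.raises(ValueError):
            zone_solver.intensities(-1.0)


class TestPrecession:
    def test_zero_angle_degenerates_to_static(self, structure, models_databank,
                                              beam_pool):
        beams = select_beams(structure.cell, beam_pool, ZONE, LAMBDA,
                             phi_deg=0.0, d_min=1.2)
        solver = BlochSolver(structure, models_databank, beams)
        np.testing.assert_array_equal(solver.precession_intensities(90.0),
                                      solver.intensities(90.0))

    def test_azimuth_refinement_stable(self, zone_solver):
        # intensities are on the unit (sum = 1) scale, so stability is
        # assessed absolutely against the strongest beam
        i64 = zone_solver.precession_intensities(100.0, 64)
        i128 = zone_solver.precession_intensities(100.0, 128)
        assert np.abs(i128 - i64).max() / i64.max() < 1e-3

    def test_too_few_azimuths_rejected(self, zone_solver):
        with pytest.raises(ValueError):
            zone_solver.precession_intensities(100.0, 2)


@pytest.fixture(scope="module")
def noisy_frames(structure, models_databank):
    orients = [("1", ZONE)]
    for tilt in ([0.05, 0.02, 1.0], [-0.03, 0.05, 1.0], [0.06, -0.04, 1.0]):
        v = np.array(tilt)
        orients.append(("1", v / np.linalg.norm(v)))
    return simulate_frames(structure, models_databank, orients, 120.0,
                           noise_frac=0.02, seed=3)


class TestThicknessRefinement:
    def test_thickness_recovery_with_noise(self, structure, models_databank,
                                           noisy_frames):
        frames, ledger = noisy_frames
        result = refine_thickness_scale(frames, structure, models_databank)
        assert abs(result.thickness_nm["1"] - ledger["thickness_nm"]) < 5.0

    def test_noise_free_frames_near_perfect(self, structure, models_databank):
        v = np.array([0.05, 0.02, 1.0])
        frames, ledger = simulate_frames(
            structure, models_databank, [("1", v / np.linalg.norm(v))],
            100.0, noise_frac=0.0, seed=5)
        result = refine_thickness_scale(frames, structure, models_databank)
        assert result.r_all < 0.1
        assert abs(result.thickness_nm["1"] - 100.0) < 0.5

    def test_frame_order_invariance(self, structure, models_databank,
                                    noisy_frames):
        frames, _ = noisy_frames
        a = refine_thickness_scale(frames, structure, models_databank)
        b = refine_thickness_scale(frames[::-1], structure, models_databank)
        assert a.thickness_nm["1"] == pytest.approx(b.thickness_nm["1"], abs=0.05)

    def test_zone_axis_frame_most_dynamical(self, structure, models_databank,
                                            noisy_frames):
        """Multiple scattering (Bloch vs single-scattering intensities in the
        same precession geometry) is strongest for the zone-axis frame."""
        frames, _ = noisy_frames
        deviations = []
        for fr in frames:
            solver = BlochSolver(structure, models_databank,
                                 fr.beam_set(structure.cell))
            i_dyn = solver.precession_intensities(120.0, 32)[1:]
            i_kin = solver.precession_intensities(120.0, 32, kinematical=True)[1:]
            deviations.append(float(np.sum(np.abs(i_dyn - i_kin))
                                    / np.sum(i_dyn)))
        assert deviations[0] == max(deviations)

    def test_empty_frame_list_rejected(self, structure):
        with pytest.raises(ValueError):
            refine_thickness_scale([], structure)


class TestFrameIO:
    def test_round_trip(self, structure, models_databank, tmp_path):
        v = np.array([0.03, -0.01, 1.0])
        frames, _ = simulate_frames(structure, models_databank,
                                    [("c2", v / np.linalg.norm(v))],
                                    80.0, noise_frac=0.01, seed=9)
        path = tmp_path / "frames.txt"
        write_frames(frames, path)
        back = read_frames(path)
        assert len(back) == 1
        assert back[0].crystal == "c2"
        np.testing.assert_array_equal(back[0].hkl, frames[0].hkl)
        np.testing.assert_allclose(back[0].i_obs, frames[0].i_obs, rtol=1e-5)


def test_relativistic_gamma_consistency():
    from aspher.constants import electron_wavelength, relativistic_gamma
    lam = electron_wavelength(200.0)
    assert gamma_from_wavelength(lam) == pytest.approx(relativistic_gamma(200.0),
                                                       rel=1e-9)
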