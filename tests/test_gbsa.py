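"""MM-GBSA components: analytic limits, oracles and composition."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from ppstab import gbsa, synthetic as syn
from ppstab.gbsa import (AtomParams, COULOMB_CONSTANT, GB_OFFSET,
                         OBC_ALPHA, OBC_BETA, OBC_GAMMA,
                         binding_energy, coulomb_energy, effective_born_radii,
                         gb_polar_energy, lcpo_sasa, ligand_efficiency,
                         lj_energy, multi_pose_score, nonpolar_energy,
                         pose_indices, toy_params)
from ppstab.io import ComplexDefinition, Selection, Structure, Trajectory

from conftest import translated_copy_complex


def uniform_params(n, charge=0.0, radius=1.7, eps=0.1, rmin=1.9):
    return syn._uniform_params(n, charge, radius, eps=eps, rmin=rmin)


class TestCoulomb:
    def test_closed_form_pair(self):
        coords = np.array([[0.0, 0, 0], [3.320637, 0, 0]])
        p = uniform_params(2, charge=[1.0, -1.0])
        assert coulomb_energy(coords, p, cutoff=None) == pytest.approx(-100.0)

    def test_zero_charges(self):
        coords = np.random.default_rng(0).normal(size=(5, 3)) * 4
        assert coulomb_energy(coords, uniform_params(5)) == 0.0

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(5, 3)) * 5
        q = rng.uniform(-1, 1, 5)
        p = uniform_params(5, charge=q)
        brute = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.linalg.norm(coords[i] - coords[j])
                if r < 18.0:
                    brute += COULOMB_CONSTANT * q[i] * q[j] / r
        assert coulomb_energy(coords, p) == pytest.approx(brute, abs=1e-9)

    def test_coincident_atoms_error(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError):
            coulomb_energy(coords, uniform_params(2, charge=1.0))


class TestLennardJones:
    def test_minimum_at_rmin(self):
        p = uniform_params(2, eps=0.25, rmin=1.9)
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])  # r = rmin_i + rmin_j
        assert lj_energy(coords, p, cutoff=None) == pytest.approx(-0.25)

    def test_zero_at_sigma(self):
        p = uniform_params(2, eps=0.25, rmin=1.9)
        sigma = 3.8 / 2 ** (1 / 6)
        coords = np.array([[0.0, 0, 0], [sigma, 0, 0]])
        assert lj_energy(coords, p, cutoff=None) == pytest.approx(0.0, abs=1e-9)

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(5, 3)) * 4 + np.arange(5)[:, None] * 2.5
        eps = rng.uniform(0.05, 0.3, 5)
        rmin = rng.uniform(1.5, 2.1, 5)
        p = AtomParams(np.zeros(5), eps, rmin, np.full(5, 1.7),
                       np.ones(5), -np.ones(5), np.zeros(5), np.zeros(5),
                       np.full(5, 1.7))
        brute = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.linalg.norm(coords[i] - coords[j])
                if r < 18.0:
                    rm = rmin[i] + rmin[j]
                    e = math.sqrt(eps[i] * eps[j])
                    brute += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert lj_energy(coords, p) == pytest.approx(brute, abs=1e-9)


def _hct_numeric(r, rho_i, s):
    """Quadrature oracle for the pairwise descreening integral."""
    def frac(t):
        if t <= s - r:
            return 1.0
        if t >= s + r or t < r - s:
            return 0.0
        mu = np.clip((t * t + r * r - s * s) / (2 * t * r), -1.0, 1.0)
        return (1.0 - mu) / 2.0
    hi = r + s
    if hi <= rho_i:
        return 0.0
    val, _ = quad(lambda t: frac(t) / t ** 2, rho_i, hi, limit=200)
    return val


class TestBornRadii:
    def test_isolated_atom_limit(self):
        s, p = syn.born_ion(1.0, 2.0)
        assert effective_born_radii(s.coord, p)[0] == pytest.approx(2.0, abs=1e-9)

    def test_distant_pair_reverts_to_isolated(self):
        s, p = syn.ion_pair(1.0, 1.0, 500.0, radius=2.0)
        radii = effective_born_radii(s.coord, p)
        assert np.abs(radii - 2.0).max() < 1e-6

    def test_three_atom_matches_numerical_descreening(self):
        """Effective radii agree with an independent quadrature evaluation
        of the descreening integrals pushed through the OBC rescaling."""
        coords = np.array([[0.0, 0, 0], [3.1, 0, 0], [1.4, 2.6, 0.0]])
        p = uniform_params(3, radius=np.array([1.6, 1.8, 1.5]))
        radii = effective_born_radii(coords, p)
        scale = gbsa.DEFAULT_HCT_SCALE
        rho_t = p.gb_radius - GB_OFFSET
        for i in range(3):
            integral = sum(
                _hct_numeric(np.linalg.norm(coords[i] - coords[j]),
                             rho_t[i], scale * rho_t[j])
                for j in range(3) if j != i
            )
            psi = rho_t[i] * integral
            inv = 1 / rho_t[i] - math.tanh(
                OBC_ALPHA * psi - OBC_BETA * psi ** 2 + OBC_GAMMA * psi ** 3
            ) / p.gb_radius[i]
            assert radii[i] == pytest.approx(1 / inv, abs=1e-6)

    def test_overlapping_centers_error(self):
        p = uniform_params(2, radius=1.7)
        with pytest.raises(ValueError):
            effective_born_radii(np.zeros((2, 3)), p)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        s, p = syn.born_ion(1.0, 2.0)
        e = gb_polar_energy(s.coord, p)
        expected = -0.5 * (1 - 1 / 78.5) * COULOMB_CONSTANT / 2.0
        assert e == pytest.approx(expected, abs=1e-6)

    def test_zero_charges_zero_energy(self):
        s, p = syn.sphere_pair(4.0)
        assert gb_polar_energy(s.coord, p) == 0.0

    def test_distant_ions_reach_screened_coulomb(self):
        s, p = syn.ion_pair(1.0, -1.0, 50.0, radius=2.0)
        radii = effective_born_radii(s.coord, p)
        total = gb_polar_energy(s.coord, p, radii)
        self_terms = sum(
            gb_polar_energy(s.coord[i: i + 1], p.subset(np.array([i])),
                            radii[i: i + 1])
            for i in range(2)
        )
        cross = total - self_terms
        screened = -(1 - 1 / 78.5) * COULOMB_CONSTANT * (1.0 * -1.0) / 50.0
        assert abs(cross - screened) / abs(screened) < 1e-3


def _shrake_rupley(coords, radii, probe=1.4, n_points=960):
    """Numerical SASA oracle: Fibonacci sphere point counting."""
    k = np.arange(n_points)
    phi = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * k + 1) / n_points
    theta = 2 * math.pi * k / phi
    pts = np.stack([np.sqrt(1 - z ** 2) * np.cos(theta),
                    np.sqrt(1 - z ** 2) * np.sin(theta), z], axis=1)
    out = []
    R = radii + probe
    for i in range(len(coords)):
        surface = coords[i] + R[i] * pts
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            buried |= (np.linalg.norm(surface - coords[j], axis=1) < R[j])
        out.append(4 * math.pi * R[i] ** 2 * (1 - buried.mean()))
    return np.array(out)


class TestLCPO:
    def test_isolated_atom_sphere_area(self):
        s, p = syn.sphere_pair(100.0, 1.7, 1.7)
        per, total = lcpo_sasa(s.coord, p)
        assert per[0] == pytest.approx(4 * math.pi * 3.1 ** 2, abs=1e-6)

    @pytest.mark.parametrize("sep", [1.0, 2.0, 3.0, 4.5])
    def test_two_sphere_overlap_matches_numerical_oracle(self, sep):
        s, p = syn.sphere_pair(sep, 1.7, 1.5)
        per, total = lcpo_sasa(s.coord, p)
        oracle = _shrake_rupley(s.coord.astype(float),
                                np.array([1.7, 1.5]))
        assert total == pytest.approx(oracle.sum(), rel=0.10)

    def test_fully_caged_atom_clamps_to_zero(self):
        # octahedral cage of large spheres around a small central atom
        cage = np.array([[3.0, 0, 0], [-3.0, 0, 0], [0, 3.0, 0],
                         [0, -3.0, 0], [0, 0, 3.0], [0, 0, -3.0],
                         [0.0, 0, 0]])
        radii = np.array([2.5] * 6 + [1.2])
        p = AtomParams(np.zeros(7), np.full(7, 0.1), np.full(7, 1.9),
                       radii, np.ones(7), -np.ones(7), np.zeros(7),
                       np.zeros(7), radii)
        per, _ = lcpo_sasa(cage, p)
        assert per[-1] == pytest.approx(0.0, abs=1e-9)


class TestNonpolar:
    def test_linear_form(self):
        assert nonpolar_energy(1000.0) == pytest.approx(5.0)
        assert nonpolar_energy(0.0) == 0.0
        assert nonpolar_energy(1000.0, surface_tension=0.0072) == pytest.approx(7.2)


def _charged_pair_complex(separation=20.0):
    """Two single-residue chains (LYS/GLU Cbeta stubs) at a separation."""
    rec = syn.build_toy_peptide("K", "extended", "A")
    par = syn.build_toy_peptide("E", "extended", "B")
    par.atoms.coord = par.atoms.coord + np.array([separation, 0, 0],
                                                 dtype=np.float32)
    cplx = Structure(rec.atoms + par.atoms)
    cdef = ComplexDefinition(Selection("A"), (Selection("B"),))
    return cplx, cdef


class TestBindingEnergy:
    def test_separated_uncharged_chains_score_zero(self):
        rec = syn.build_toy_peptide("AAA", "extended", "A")
        par = syn.build_toy_peptide("AAA", "extended", "B")
        par.atoms.coord = par.atoms.coord + np.array([200.0, 0, 0],
                                                     dtype=np.float32)
        cplx = Structure(rec.atoms + par.atoms)
        cdef = ComplexDefinition(Selection("A"), (Selection("B"),))
        bd = binding_energy(cplx, cdef, toy_params(cplx))
        assert bd.total == pytest.approx(0.0, abs=1e-6)

    def test_composition_matches_independent_species_scoring(self):
        """Eq.-style composition: directly computed binding enthalpy equals
        the difference of independently scored complex/receptor/partner."""
        cplx, cdef = _charged_pair_complex(8.0)
        params = toy_params(cplx)
        bd = binding_energy(cplx, cdef, params)
        atoms = cplx.atoms
        rec = np.flatnonzero(cdef.receptor_mask(atoms))
        par = np.flatnonzero(cdef.partner_mask(atoms))
        coords = atoms.coord.astype(float)

        def species(idx):
            sp = params.subset(idx)
            c = coords[idx]
            polar = gb_polar_energy(c, sp)
            _, sasa = lcpo_sasa(c, sp)
            return polar + nonpolar_energy(sasa)

        inter = (coulomb_energy(coords, params, rec, par)
                 + lj_energy(coords, params, rec, par))
        both = np.concatenate([rec, par])
        expected = inter + species(both) - species(rec) - species(par)
        assert bd.total == pytest.approx(expected, abs=1e-9)
        assert bd.total == pytest.approx(
            bd.e_elec + bd.e_vdw + bd.g_polar + bd.g_nonpolar, abs=1e-9)

    def test_attractive_complex_is_negative(self):
        cplx, cdef = _charged_pair_complex(6.0)
        bd = binding_energy(cplx, cdef, toy_params(cplx))
        assert bd.total < 0

    def test_rigid_motion_invariance(self):
        cplx, cdef = _charged_pair_complex(7.0)
        params = toy_params(cplx)
        ref = binding_energy(cplx, cdef, params)
        rot = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
        moved = cplx.copy()
        moved.atoms.coord = (
            cplx.atoms.coord.astype(float) @ rot.T + [7.0, -3.0, 11.0]
        ).astype(np.float32)
        alt = binding_energy(moved, cdef, params)
        for name in ("e_elec", "e_vdw", "g_polar", "g_nonpolar"):
            assert getattr(alt, name) == pytest.approx(
                getattr(ref, name), abs=1e-4)


class TestMultiPose:
    def test_even_spacing_rule(self):
        assert pose_indices(100, 5) == [50, 62, 74, 86, 98]

    def test_too_few_frames_error(self):
        with pytest.raises(ValueError):
            pose_indices(8, 5)

    def test_constant_trajectory_zero_sd(self):
        cplx, cdef = _charged_pair_complex(8.0)
        traj = syn.trajectory_bound(cplx, 0.0, 20, seed=1)
        score = multi_pose_score(traj, cdef, toy_params(cplx))
        assert score.sd_kj == pytest.approx(0.0, abs=1e-9)

    def test_mean_recomposes_from_single_pose_calls(self):
        cplx, cdef = _charged_pair_complex(8.0)
        params = toy_params(cplx)
        traj = syn.trajectory_bound(cplx, 0.1, 20, seed=2)
        score = multi_pose_score(traj, cdef, params)
        direct = [binding_energy(traj.frame(i), cdef, params).total_kj
                  for i in score.pose_indices]
        assert score.mean_kj == pytest.approx(np.mean(direct), abs=1e-9)


class TestRelaxation:
    def test_clash_relief_with_restrained_geometry(self):
        """Relaxation pushes a clashed pair apart while the positional
        restraints keep every atom near its input position."""
        cplx, cdef = _charged_pair_complex(2.0)  # inside LJ repulsion
        params = toy_params(cplx)
        relaxed = gbsa.relax_pose(cplx, params)
        before = cplx.atoms.coord.astype(float)
        after = relaxed.atoms.coord.astype(float)
        rec = cdef.receptor_mask(cplx.atoms)
        par = cdef.partner_mask(cplx.atoms)
        dmin_before = np.sqrt(((before[rec][:, None] - before[par][None]) ** 2
                               ).sum(-1)).min()
        dmin_after = np.sqrt(((after[rec][:, None] - after[par][None]) ** 2
                              ).sum(-1)).min()
        assert dmin_after > dmin_before
        assert np.linalg.norm(after - before, axis=1).max() < 2.0

    def test_relaxed_multi_pose_runs(self):
        cplx, cdef = _charged_pair_complex(6.0)
        traj = syn.trajectory_bound(cplx, 0.05, 12, seed=8)
        score = multi_pose_score(traj, cdef, toy_params(cplx), n_poses=2,
                                 relax=True)
        assert np.isfinite(score.mean_kj)


class TestLigandEfficiency:
    @pytest.mark.parametrize("mean_kj, atoms, expected", [
        (-130.94, 300, -0.44),
        (-48.06, 232, -0.21),
        (0.0, 100, 0.00),
    ])
    def test_rounding(self, mean_kj, atoms, expected):
        assert ligand_efficiency(mean_kj, atoms) == expected

    def test_zero_atoms_error(self):
        with pytest.raises(ValueError):
            ligand_efficiency(-10.0, 0)


class TestParamTable:
    def test_round_trip(self, tmp_path, toy_complex):
        cplx, _ = toy_complex
        params = toy_params(cplx)
        path = tmp_path / "params.tbl"
        gbsa.save_params(cplx, params, path)
        back = gbsa.load_params(cplx, path)
        for name in ("charge", "eps", "rmin", "gb_radius", "lcpo_radius"):
            assert np.allclose(getattr(back, name), getattr(params, name))

    def test_missing_atom_errors(self, tmp_path):
        s = syn.build_toy_peptide("AK", "extended", "A")
        params = toy_params(s)
        path = tmp_path / "p.tbl"
        gbsa.save_params(s, params, path)
        bigger = syn.build_toy_peptide("AKL", "extended", "A")
        with pytest.raises(ValueError, match="no parameters"):
            gbsa.load_params(bigger, path)
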