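"""Gaussian shape overlap, Coulomb potential grids and the Tanimoto
similarity scores (ST, ET, ET_combo)."""

import numpy as np
import pytest

from natscreen.chem_core import Conformer
from natscreen.overlay_scoring import (
    GAUSSIAN_AMPLITUDE,
    GridSpec,
    OverlayScore,
    best_query_score,
    coulomb_potential,
    electro_tanimoto,
    electrostatic_tanimoto_pair,
    gaussian_overlap,
    potential_grid,
    score_pair,
    select_candidates,
    shape_tanimoto,
)


def conf(points, elements=None, charges=None):
    points = np.atleast_2d(np.asarray(points, float))
    elements = tuple(elements or ["C"] * len(points))
    c = Conformer(coords=points, elements=elements)
    if charges is not None:
        c.charges = np.asarray(charges, float)
    return c


def alpha_for(radius, p=GAUSSIAN_AMPLITUDE):
    return np.pi * (3.0 * p / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)


class TestGaussianOverlap:
    def test_single_atom_self_overlap_matches_closed_form(self):
        a = conf([[0, 0, 0]])  # carbon, R = 1.70
        alpha = alpha_for(1.70)
        expected = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2 * alpha)) ** 1.5
        assert gaussian_overlap(a, a) == pytest.approx(expected, rel=1e-12)

    def test_far_separated_atoms_overlap_vanishes(self):
        a = conf([[0, 0, 0]])
        b = conf([[50.0, 0, 0]])
        assert gaussian_overlap(a, b) < 1e-9

    def test_pairwise_overlap_at_1A_matches_closed_form(self):
        # two nitrogen atoms (R = 1.55) 1 Å apart
        a = conf([[0, 0, 0]], elements=["N"])
        b = conf([[1.0, 0, 0]], elements=["N"])
        alpha = alpha_for(1.55)
        expected = (
            GAUSSIAN_AMPLITUDE**2
            * (np.pi / (2 * alpha)) ** 1.5
            * np.exp(-(alpha / 2) * 1.0**2)
        )
        assert gaussian_overlap(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self, rng):
        a = conf(rng.normal(scale=2, size=(4, 3)))
        b = conf(rng.normal(scale=2, size=(6, 3)), elements=list("CCNNOO"))
        assert gaussian_overlap(a, b) == pytest.approx(gaussian_overlap(b, a), rel=1e-12)


class TestShapeTanimoto:
    def test_self_similarity_is_exactly_one(self, rng):
        a = conf(rng.normal(scale=2, size=(5, 3)), elements=list("CCNOS"))
        assert shape_tanimoto(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_far_separated_pair_scores_near_zero(self):
        a = conf([[0, 0, 0], [1.5, 0, 0]])
        b = conf([[60.0, 0, 0], [61.5, 0, 0]])
        assert shape_tanimoto(a, b) < 1e-9

    def test_symmetric_and_bounded(self, rng):
        for _ in range(5):
            a = conf(rng.normal(scale=2, size=(4, 3)))
            b = conf(rng.normal(scale=2, size=(5, 3)))
            st_ab = shape_tanimoto(a, b)
            assert st_ab == pytest.approx(shape_tanimoto(b, a), rel=1e-12)
            assert 0.0 <= st_ab <= 1.0

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        a = conf(rng.normal(scale=2, size=(5, 3)))
        b = conf(rng.normal(scale=2, size=(5, 3)))
        st0 = shape_tanimoto(a, b)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=10, size=3)
        am = conf(a.coords @ rot.T + shift)
        bm = conf(b.coords @ rot.T + shift)
        assert shape_tanimoto(am, bm) == pytest.approx(st0, abs=1e-9)


class TestPotentialGrid:
    def test_point_charge_coulomb_value(self):
        # single +1 charge; potential at 1 Å with eps = 1 is 1 internal unit
        phi = coulomb_potential([[0, 0, 0]], [1.0], [[1.0, 0, 0]], dielectric=1.0)
        assert phi[0] == pytest.approx(1.0, rel=1e-12)

    def test_dipole_field_antisymmetry(self):
        atoms = [[0, 0, 0.5], [0, 0, -0.5]]
        charges = [1.0, -1.0]
        probe = [[2.0, 0, 1.0], [2.0, 0, -1.0]]
        phi = coulomb_potential(atoms, charges, probe, dielectric=1.0)
        assert phi[0] == pytest.approx(-phi[1], rel=1e-12)

    def test_doubling_dielectric_halves_the_field(self, rng):
        c = conf(rng.normal(size=(3, 3)), charges=[0.3, -0.1, -0.2])
        f1 = potential_grid(c, GridSpec(spacing=1.0, margin=3.0), dielectric=40.0)
        f2 = potential_grid(c, GridSpec(spacing=1.0, margin=3.0), dielectric=80.0)
        np.testing.assert_allclose(f1.values, 2.0 * f2.values, atol=1e-12)

    def test_unphysical_total_charge_is_an_error(self):
        c = conf([[0, 0, 0]], charges=[5.0])
        with pytest.raises(ValueError, match="charge"):
            potential_grid(c)


class TestElectroTanimoto:
    def test_self_similarity_is_one(self, rng):
        c = conf(rng.normal(scale=1.5, size=(4, 3)), charges=[0.4, -0.2, -0.1, -0.1])
        f = potential_grid(c, GridSpec(spacing=0.8, margin=3.0))
        assert electro_tanimoto(f, f) == pytest.approx(1.0, abs=1e-12)

    def test_charge_negation_gives_negative_similarity(self, rng):
        pts = rng.normal(scale=1.5, size=(4, 3))
        q = np.array([0.4, -0.2, -0.1, -0.1])
        a = conf(pts, charges=q)
        b = conf(pts, charges=-q)
        fa = potential_grid(a, GridSpec(spacing=0.8, margin=3.0), companions=[b])
        fb = potential_grid(b, GridSpec(spacing=0.8, margin=3.0), companions=[a])
        assert electro_tanimoto(fa, fb) < 0

    def test_invariant_under_uniform_charge_scaling(self, rng):
        pts_a = rng.normal(scale=1.5, size=(3, 3))
        pts_b = rng.normal(scale=1.5, size=(3, 3))
        qa = np.array([0.3, -0.2, -0.1])
        qb = np.array([-0.1, 0.25, -0.15])
        grid = GridSpec(spacing=0.8, margin=3.0)
        base = electrostatic_tanimoto_pair(conf(pts_a, charges=qa), conf(pts_b, charges=qb), grid)
        scaled = electrostatic_tanimoto_pair(
            conf(pts_a, charges=0.37 * qa), conf(pts_b, charges=0.37 * qb), grid
        )
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_grid_refinement_converges(self, model):
        from natscreen.synthetic_data import make_query_poses

        queries, _ = make_query_poses(model, n_queries=2, seed=3)
        a, b = queries[0], queries[1]
        ets = [
            electrostatic_tanimoto_pair(a, b, GridSpec(spacing=s, margin=4.0))
            for s in (0.75, 0.5, 0.35)
        ]
        assert abs(ets[1] - ets[0]) < 0.02
        assert abs(ets[2] - ets[1]) < 0.02

    def test_mismatched_grids_are_rejected(self, rng):
        a = conf(rng.normal(size=(3, 3)), charges=[0.1, 0.1, -0.2])
        f1 = potential_grid(a, GridSpec(spacing=1.0, margin=3.0))
        f2 = potential_grid(a, GridSpec(spacing=0.9, margin=3.0))
        with pytest.raises(ValueError):
            electro_tanimoto(f1, f2)


class TestSelection:
    def make_scores(self, values):
        return [
            OverlayScore(shape_tanimoto=0.5, electro_tanimoto=v - 0.5, et_combo=v, query_id=f"q{i}")
            for i, v in enumerate(values)
        ]

    def test_threshold_is_inclusive(self):
        kept = select_candidates(self.make_scores([0.86, 0.84, 0.850]))
        assert [s.et_combo for s in kept] == [0.86, 0.850]

    def test_identical_candidate_scores_two(self, model, query_poses):
        queries, qids = query_poses
        score = best_query_score(queries[0], queries, qids)
        assert score.et_combo == pytest.approx(2.0, abs=1e-9)

    def test_adding_a_query_never_lowers_the_best(self, model, query_poses):
        queries, qids = query_poses
        few = best_query_score(queries[0], queries[:1], qids[:1])
        more = best_query_score(queries[0], queries, qids)
        assert more.et_combo >= few.et_combo - 1e-12

    def test_empty_query_set_is_an_error(self, query_poses):
        queries, _ = query_poses
        with pytest.raises(ValueError):
            best_query_score(queries[0], [])
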