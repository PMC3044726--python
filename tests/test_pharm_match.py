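"""Kabsch superposition and pharmacophore matching (flexible / in place)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from natscreen.chem_core import Conformer, FeaturePoint
from natscreen.pharmacophore_model import (
    ExcludedVolume,
    PharmacophoreModel,
    PharmacophoreSite,
)
from natscreen.pharm_match import (
    DegenerateGeometryError,
    flexible_match,
    generate_poses,
    kabsch_superpose,
    score_in_place,
)
from natscreen.synthetic_data import make_planted_active


def feature(kind, pos):
    return FeaturePoint(kind=kind, position=np.asarray(pos, float), member_atoms=(0,))


def conformer_at(points, elements=None):
    points = np.asarray(points, float)
    elements = tuple(elements or ["C"] * len(points))
    return Conformer(coords=points, elements=elements)


class TestKabsch:
    def test_identical_sets_give_identity_and_zero_rmsd(self, rng):
        pts = rng.normal(size=(5, 3))
        rot, trans, rmsd = kabsch_superpose([(p, p) for p in pts])
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_is_recovered(self, rng):
        pts = rng.normal(size=(6, 3))
        r_true = Rotation.random(rng=rng).as_matrix()
        moved = pts @ r_true.T
        rot, trans, rmsd = kabsch_superpose(list(zip(pts, moved)))
        # transform maps features (moved) back onto sites: rot == r_true^T
        np.testing.assert_allclose(rot, r_true.T, atol=1e-8)
        assert rmsd < 1e-9

    def test_mirror_image_returns_proper_rotation_with_residual(self, rng):
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(list(zip(pts, mirrored)))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.05

    def test_too_few_or_collinear_pairs_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose([(np.zeros(3), np.zeros(3))] * 2)
        line = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose([(p, p) for p in line])


def simple_model(tolerance=1.0, min_match=3, evs=()):
    sites = [
        PharmacophoreSite("donor", [0.0, 0.0, 0.0], tolerance),
        PharmacophoreSite("acceptor", [3.0, 0.0, 0.0], tolerance),
        PharmacophoreSite("hydrophobic", [0.0, 3.0, 0.0], tolerance),
        PharmacophoreSite("donor", [0.0, 0.0, 3.0], tolerance),
    ]
    return PharmacophoreModel(
        sites=sites, excluded_volumes=list(evs), min_match_sites=min_match
    )


def features_at_sites(model, indices, kinds=None):
    feats = []
    for i in indices:
        site = model.sites[i]
        kind = site.kind if kinds is None else kinds[i]
        if kind == "hydrophobic":
            kind = "aromatic_hydrophobic"
        feats.append(feature(kind, site.center))
    return feats


class TestFlexibleMatch:
    def test_planted_four_feature_conformer_hits_after_rigid_motion(self, rng):
        model = simple_model()
        feats = features_at_sites(model, range(4))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=10.0, size=3)
        moved = [
            FeaturePoint(kind=f.kind, position=rot @ f.position + shift, member_atoms=f.member_atoms)
            for f in feats
        ]
        conf = conformer_at([f.position for f in moved])
        res = flexible_match(moved, conf, model)
        assert res is not None and res.is_hit
        assert res.site_rmsd == pytest.approx(0.0, abs=1e-8)

    def test_two_matching_features_is_no_hit(self):
        model = simple_model()
        feats = features_at_sites(model, [0, 1])
        res = flexible_match(feats, conformer_at([f.position for f in feats]), model)
        assert res is None

    def test_excluded_volume_clash_rejects_the_pose(self):
        model_clear = simple_model()
        feats = features_at_sites(model_clear, [0, 1, 2])
        # extra heavy atom that lands inside an EV sphere after the
        # (identity) superposition
        coords = [f.position for f in feats] + [[1.0, 1.0, 0.0]]
        conf = conformer_at(coords)
        assert flexible_match(feats, conf, model_clear) is not None
        model_blocked = simple_model(evs=[ExcludedVolume([1.0, 1.0, 0.0], 0.8)])
        assert flexible_match(feats, conf, model_blocked) is None

    def test_rigid_motion_invariance_of_decision_and_rmsd(self, rng):
        model = simple_model(tolerance=1.2)
        base = [
            feature("donor", [0.1, 0.2, 0.0]),
            feature("acceptor", [3.2, -0.1, 0.1]),
            feature("aromatic_hydrophobic", [-0.2, 2.8, 0.0]),
        ]
        conf = conformer_at([f.position for f in base])
        res0 = flexible_match(base, conf, model)
        assert res0 is not None
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=20.0, size=3)
            moved = [
                FeaturePoint(kind=f.kind, position=rot @ f.position + shift, member_atoms=f.member_atoms)
                for f in base
            ]
            mconf = conformer_at([f.position for f in moved])
            res = flexible_match(moved, mconf, model)
            assert res is not None
            assert res.site_rmsd == pytest.approx(res0.site_rmsd, abs=1e-6)

    def test_rotation_is_always_proper(self, rng):
        model = simple_model(tolerance=1.5)
        for _ in range(10):
            feats = [
                feature("donor", rng.normal(scale=2, size=3)),
                feature("acceptor", rng.normal(scale=2, size=3) + [3, 0, 0]),
                feature("aromatic_hydrophobic", rng.normal(scale=2, size=3) + [0, 3, 0]),
            ]
            conf = conformer_at([f.position for f in feats])
            res = flexible_match(feats, conf, model)
            if res is not None:
                assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


class TestScoreInPlace:
    def test_receptor_frame_pose_inside_tolerances_hits(self):
        model = simple_model(tolerance=1.0)
        feats = [
            feature("donor", [0.3, 0.0, 0.0]),
            feature("acceptor", [3.0, 0.3, 0.0]),
            feature("aromatic_hydrophobic", [0.0, 2.8, 0.2]),
        ]
        res = score_in_place(feats, conformer_at([f.position for f in feats]), model)
        assert res is not None
        np.testing.assert_allclose(res.rotation, np.eye(3))

    def test_translated_pose_misses(self):
        model = simple_model(tolerance=1.0)
        feats = features_at_sites(model, [0, 1, 2])
        shifted = [
            FeaturePoint(kind=f.kind, position=f.position + [5.0, 0, 0], member_atoms=f.member_atoms)
            for f in feats
        ]
        conf = conformer_at([f.position for f in shifted])
        assert score_in_place(shifted, conf, model) is None

    def test_in_place_hit_implies_flexible_hit(self, rng):
        model = simple_model(tolerance=1.2)
        for _ in range(20):
            feats = [
                feature("donor", rng.normal(scale=1.0, size=3)),
                feature("acceptor", [3, 0, 0] + rng.normal(scale=1.0, size=3)),
                feature("aromatic_hydrophobic", [0, 3, 0] + rng.normal(scale=1.0, size=3)),
            ]
            conf = conformer_at([f.position for f in feats])
            if score_in_place(feats, conf, model) is not None:
                assert flexible_match(feats, conf, model) is not None


class TestGeneratePoses:
    def test_pose_cap_and_rmsd_ordering(self, model):
        mol = make_planted_active(model, k_sites=4, seed=21, conformers=40)
        poses = generate_poses(mol, model, max_poses=32)
        assert 1 <= len(poses) <= 32
        rmsds = [p.match.site_rmsd for p in poses]
        assert rmsds == sorted(rmsds)

    def test_small_cap_truncates(self, model):
        mol = make_planted_active(model, k_sites=4, seed=22, conformers=40)
        all_poses = generate_poses(mol, model, max_poses=32)
        capped = generate_poses(mol, model, max_poses=2)
        assert len(capped) == min(2, len(all_poses))

    def test_non_matching_molecule_has_no_poses(self, model):
        mol = make_planted_active(model, k_sites=2, seed=23)
        assert generate_poses(mol, model) == []
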