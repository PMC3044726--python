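"""Pharmacophore persistence, excluded-volume construction, interaction
detection and the hinge/pocket coherence criterion."""

import numpy as np
import pytest

from natscreen.chem_core import Conformer, perceive_features
from natscreen.pharmacophore_model import (
    ExcludedVolume,
    PharmacophoreModel,
    PharmacophoreSchemaError,
    PharmacophoreSite,
    build_excluded_volumes,
    detect_interactions,
    is_knowledge_based_coherent,
    load_pharmacophore,
    models_equal,
    save_pharmacophore,
)
from natscreen.synthetic_data import make_toy_receptor


def single_atom_conformer(pos, element="C"):
    return Conformer(coords=np.array([pos], dtype=float), elements=(element,))


class TestPersistence:
    def test_shipped_fixture_has_expected_sites(self):
        from importlib import resources

        path = resources.files("natscreen.data").joinpath("hinge_pharmacophore_synthetic.json")
        model = load_pharmacophore(str(path))
        kinds = [s.kind for s in model.sites]
        assert kinds == ["donor", "donor", "acceptor", "hydrophobic"]
        assert [s.tolerance for s in model.sites] == [1.5, 1.5, 1.5, 3.0]
        assert model.min_match_sites == 3
        assert not model.mandatory_sites
        assert not model.prefer_more_sites
        assert len(model.excluded_volumes) > 0

    def test_roundtrip_equality(self, tmp_path, rng):
        sites = [
            PharmacophoreSite("donor", rng.normal(size=3), 1.2),
            PharmacophoreSite("acceptor", rng.normal(size=3), 1.5),
            PharmacophoreSite("hydrophobic", rng.normal(size=3), 2.5),
        ]
        evs = [ExcludedVolume(rng.normal(size=3) * 5, 1.7, source_atom="C")]
        model = PharmacophoreModel(sites=sites, excluded_volumes=evs, min_match_sites=2)
        p = tmp_path / "m.json"
        save_pharmacophore(model, p)
        assert models_equal(model, load_pharmacophore(p))

    def test_schema_violation_reports_json_path(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"version": 1, "sites": [{"kind": "donor", "center": [0,0,0]}]}')
        with pytest.raises(PharmacophoreSchemaError, match=r"\$\.sites\[0\]\.tolerance"):
            load_pharmacophore(p)


class TestExcludedVolumes:
    def make_receptor_atoms(self, surface_distances):
        # ligand: single carbon at origin (vdW 1.7); receptor carbons on x
        # axis with prescribed surface-to-surface distance d = x - 3.4
        return [("C", 1.7, np.array([3.4 + d, 0.0, 0.0])) for d in surface_distances]

    def test_two_sphere_filters_select_the_shell(self):
        ligand = [single_atom_conformer([0.0, 0.0, 0.0])]
        atoms = self.make_receptor_atoms([0.1, 1.0, 5.0, 9.0, 12.0])
        evs = build_excluded_volumes(atoms, ligand, surface_margin=0.25, shell_thickness=10.0)
        assert len(evs) == 3  # d=0.1 hugs the ligand; d=12 is outside the shell

    def test_margin_excludes_contact_atoms(self):
        ligand = [single_atom_conformer([0, 0, 0])]
        evs = build_excluded_volumes(
            self.make_receptor_atoms([0.1]), ligand, surface_margin=0.25
        )
        assert evs == []

    def test_shell_thickness_excludes_remote_atoms(self):
        ligand = [single_atom_conformer([0, 0, 0])]
        evs = build_excluded_volumes(
            self.make_receptor_atoms([15.0]), ligand, shell_thickness=10.0
        )
        assert evs == []

    def test_output_independent_of_receptor_atom_ordering(self, rng):
        ligand = [single_atom_conformer([0, 0, 0])]
        atoms = self.make_receptor_atoms(rng.uniform(-0.5, 12.0, size=20))
        fwd = build_excluded_volumes(atoms, ligand)
        rev = build_excluded_volumes(atoms[::-1], ligand)
        centers_fwd = sorted(tuple(np.round(e.center, 9)) for e in fwd)
        centers_rev = sorted(tuple(np.round(e.center, 9)) for e in rev)
        assert centers_fwd == centers_rev

    def test_widening_the_window_never_removes_spheres(self, rng):
        ligand = [single_atom_conformer([0, 0, 0])]
        atoms = self.make_receptor_atoms(rng.uniform(-0.5, 14.0, size=30))
        narrow = build_excluded_volumes(atoms, ligand, surface_margin=1.0, shell_thickness=6.0)
        wide = build_excluded_volumes(atoms, ligand, surface_margin=0.25, shell_thickness=10.0)
        narrow_centers = {tuple(np.round(e.center, 9)) for e in narrow}
        wide_centers = {tuple(np.round(e.center, 9)) for e in wide}
        assert narrow_centers <= wide_centers

    def test_empty_receptor_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            build_excluded_volumes([], [single_atom_conformer([0, 0, 0])])


class TestInteractions:
    def test_reference_pose_makes_hinge_hbond_and_pocket_contact(self, template, receptor):
        conf = template.conformer(0)
        feats = perceive_features(template, 0)
        interactions = detect_interactions(conf, feats, receptor, ligand_bonds=template.bonds())
        hbonds = [i for i in interactions if i.kind == "hydrogen_bond"]
        contacts = [i for i in interactions if i.kind == "hydrophobic_contact"]
        assert any(i.receptor_residue[1] == 99 and i.receptor_is_backbone for i in hbonds)
        assert any(i.receptor_residue[1] == 29 for i in contacts)

    def test_far_away_ligand_has_no_interactions(self, template, receptor):
        conf = template.conformer(0)
        shifted = Conformer(coords=conf.coords + 20.0, elements=conf.elements)
        feats = perceive_features(template, 0)
        shifted_feats = [
            type(f)(kind=f.kind, position=f.position + 20.0, member_atoms=f.member_atoms)
            for f in feats
        ]
        assert detect_interactions(shifted, shifted_feats, receptor) == []


class TestCoherence:
    def hb(self, resid, backbone=True):
        from natscreen.pharmacophore_model import Interaction

        return Interaction(
            kind="hydrogen_bond",
            ligand_atoms=(0,),
            receptor_residue=("A", resid, "CYS"),
            distance=2.9,
            receptor_is_backbone=backbone,
        )

    def contact(self, resid):
        from natscreen.pharmacophore_model import Interaction

        return Interaction(
            kind="hydrophobic_contact",
            ligand_atoms=(1,),
            receptor_residue=("A", resid, "VAL"),
            distance=4.0,
        )

    def test_hinge_bond_plus_pocket_contact_is_coherent(self):
        assert is_knowledge_based_coherent([self.hb(99), self.contact(29)])

    def test_hinge_bond_alone_is_not(self):
        assert not is_knowledge_based_coherent([self.hb(99)])

    def test_pocket_contact_alone_is_not(self):
        assert not is_knowledge_based_coherent([self.contact(152)])

    def test_sidechain_hbond_does_not_satisfy_hinge(self):
        assert not is_knowledge_based_coherent(
            [self.hb(99, backbone=False), self.contact(29)]
        )

    def test_toy_receptor_pose_coherent_until_translated(self, template, receptor, model):
        rec, ref = make_toy_receptor(model)
        conf = ref.conformer(0)
        feats = perceive_features(ref, 0)
        ints = detect_interactions(conf, feats, rec, ligand_bonds=ref.bonds())
        assert is_knowledge_based_coherent(ints)
        moved = Conformer(coords=conf.coords + np.array([10.0, 0, 0]), elements=conf.elements)
        moved_feats = [
            type(f)(kind=f.kind, position=f.position + np.array([10.0, 0, 0]), member_atoms=f.member_atoms)
            for f in feats
        ]
        ints2 = detect_interactions(moved, moved_feats, rec, ligand_bonds=ref.bonds())
        assert not is_knowledge_based_coherent(ints2)
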