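"""Pharmacophore representation and persistence, receptor-based excluded
volumes, protein-ligand interaction detection and the knowledge-based
pose-coherence test.

A pharmacophore is a set of typed feature sites (donor / acceptor /
hydrophobic) with tolerance radii, optionally surrounded by a shell of
excluded-volume spheres marking receptor-occupied space.  The shell is
built from receptor atoms whose van der Waals surface lies between a
margin (default 0.25 Å) and a shell thickness (default 10 Å) away from
the reference-ligand surface.

For an ATP-competitive kinase inhibitor, a pose is *knowledge-based
coherent* when it hydrogen-bonds to the main chain of a hinge-region
residue and makes at least one hydrophobic contact with the hydrophobic
pocket.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chem_core import Conformer, FeaturePoint, vdw_radius

SITE_KINDS = ("donor", "acceptor", "hydrophobic")

#: Default residue numbering of the shipped synthetic kinase fixture.
#: Hinge segment 96-99; hydrophobic pocket {29, 44, 152, 165}.
DEFAULT_HINGE_RESIDUES = frozenset(range(96, 100))
DEFAULT_POCKET_RESIDUES = frozenset({29, 44, 152, 165})

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PharmacophoreSchemaError(ValueError):
    """Raised when a pharmacophore JSON file violates the schema; the
    message carries the JSON path of the offending field."""


@dataclass
class PharmacophoreSite:
    kind: str
    center: np.ndarray
    tolerance: float

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("site center must be a 3-vector")
        if not self.tolerance > 0:
            raise ValueError("site tolerance must be positive")

    def accepts(self, feature_kind: str) -> bool:
        """Type compatibility: a hydrophobic site accepts both aliphatic
        and aromatic hydrophobic features."""
        if self.kind == "hydrophobic":
            return feature_kind in ("hydrophobic", "aromatic_hydrophobic")
        return feature_kind == self.kind


@dataclass
class ExcludedVolume:
    center: np.ndarray
    radius: float
    source_atom: str | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.radius > 0:
            raise ValueError("excluded-volume radius must be positive")


@dataclass
class PharmacophoreModel:
    sites: list[PharmacophoreSite]
    excluded_volumes: list[ExcludedVolume] = field(default_factory=list)
    min_match_sites: int = 3
    mandatory_sites: frozenset[int] = frozenset()
    prefer_more_sites: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.min_match_sites <= len(self.sites):
            raise ValueError("min_match_sites must be in 1..len(sites)")
        self.mandatory_sites = frozenset(self.mandatory_sites)
        if any(i not in range(len(self.sites)) for i in self.mandatory_sites):
            raise ValueError("mandatory_sites must index into sites")

    def site_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.sites])


# ---------------------------------------------------------------------------
# JSON persistence (schema v1)
# ---------------------------------------------------------------------------


def save_pharmacophore(model: PharmacophoreModel, path: str | Path) -> None:
    doc = {
        "version": 1,
        "sites": [
            {"kind": s.kind, "center": list(map(float, s.center)), "tolerance": float(s.tolerance)}
            for s in model.sites
        ],
        "excluded_volumes": [
            {
                "center": list(map(float, ev.center)),
                "radius": float(ev.radius),
                **({"source_atom": ev.source_atom} if ev.source_atom else {}),
            }
            for ev in model.excluded_volumes
        ],
        "min_match_sites": model.min_match_sites,
        "mandatory_sites": sorted(model.mandatory_sites),
        "prefer_more_sites": model.prefer_more_sites,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _require(doc: dict, key: str, types, path: str):
    if key not in doc:
        raise PharmacophoreSchemaError(f"{path}.{key}: missing required field")
    value = doc[key]
    if not isinstance(value, types):
        raise PharmacophoreSchemaError(f"{path}.{key}: expected {types}, got {type(value).__name__}")
    return value


def load_pharmacophore(path: str | Path) -> PharmacophoreModel:
    """Load a schema-v1 pharmacophore JSON file.

    Round trip contract: ``load(save(m))`` equals ``m``.
    """
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise PharmacophoreSchemaError("$: document must be an object")
    version = _require(doc, "version", int, "$")
    if version != 1:
        raise PharmacophoreSchemaError(f"$.version: unsupported schema version {version}")
    sites = []
    for i, raw in enumerate(_require(doc, "sites", list, "$")):
        p = f"$.sites[{i}]"
        kind = _require(raw, "kind", str, p)
        if kind not in SITE_KINDS:
            raise PharmacophoreSchemaError(f"{p}.kind: not one of {SITE_KINDS}")
        center = _require(raw, "center", list, p)
        if len(center) != 3:
            raise PharmacophoreSchemaError(f"{p}.center: must have 3 components")
        tolerance = _require(raw, "tolerance", (int, float), p)
        if tolerance <= 0:
            raise PharmacophoreSchemaError(f"{p}.tolerance: must be positive")
        sites.append(PharmacophoreSite(kind=kind, center=center, tolerance=float(tolerance)))
    evs = []
    for i, raw in enumerate(doc.get("excluded_volumes", [])):
        p = f"$.excluded_volumes[{i}]"
        center = _require(raw, "center", list, p)
        radius = _require(raw, "radius", (int, float), p)
        if radius <= 0:
            raise PharmacophoreSchemaError(f"{p}.radius: must be positive")
        evs.append(
            ExcludedVolume(center=center, radius=float(radius), source_atom=raw.get("source_atom"))
        )
    try:
        return PharmacophoreModel(
            sites=sites,
            excluded_volumes=evs,
            min_match_sites=doc.get("min_match_sites", 3),
            mandatory_sites=frozenset(doc.get("mandatory_sites", [])),
            prefer_more_sites=bool(doc.get("prefer_more_sites", False)),
        )
    except ValueError as exc:
        raise PharmacophoreSchemaError(f"$: {exc}") from exc


def models_equal(a: PharmacophoreModel, b: PharmacophoreModel, tol: float = 1e-9) -> bool:
    if len(a.sites) != len(b.sites) or len(a.excluded_volumes) != len(b.excluded_volumes):
        return False
    for sa, sb in zip(a.sites, b.sites):
        if sa.kind != sb.kind or abs(sa.tolerance - sb.tolerance) > tol:
            return False
        if np.max(np.abs(sa.center - sb.center)) > tol:
            return False
    for ea, eb in zip(a.excluded_volumes, b.excluded_volumes):
        if abs(ea.radius - eb.radius) > tol or np.max(np.abs(ea.center - eb.center)) > tol:
            return False
    return (
        a.min_match_sites == b.min_match_sites
        and a.mandatory_sites == b.mandatory_sites
        and a.prefer_more_sites == b.prefer_more_sites
    )


# ---------------------------------------------------------------------------
# Receptor structure
# ---------------------------------------------------------------------------


@dataclass
class Receptor:
    """A protein structure with residue numbering, backed by parsed PDB
    ATOM/HETATM records.  Residue numbers are taken verbatim from the
    input file (no renumbering)."""

    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Receptor":
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
        return cls.from_atom_array(atoms)

    @classmethod
    def from_atom_array(cls, atoms: struc.AtomArray) -> "Receptor":
        if atoms.array_length() == 0:
            raise ValueError("receptor structure is empty")
        if np.all(atoms.res_id == 0):
            raise ValueError("receptor is missing residue numbering")
        return cls(
            coords=np.asarray(atoms.coord, dtype=float),
            elements=np.array([e.capitalize() for e in atoms.element]),
            atom_names=np.asarray(atoms.atom_name),
            res_ids=np.asarray(atoms.res_id, dtype=int),
            res_names=np.asarray(atoms.res_name),
            chain_ids=np.asarray(atoms.chain_id),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.elements])

    def is_backbone(self) -> np.ndarray:
        return np.isin(self.atom_names, sorted(_BACKBONE_ATOMS))

    def atom_tuples(self) -> list[tuple[str, float, np.ndarray]]:
        """(element, vdW radius, position) triplets for the EV builder."""
        radii = self.vdw_radii()
        return [
            (self.elements[i], float(radii[i]), self.coords[i]) for i in range(self.n_atoms)
        ]


# ---------------------------------------------------------------------------
# Excluded-volume construction
# ---------------------------------------------------------------------------


def build_excluded_volumes(
    receptor_atoms: list[tuple[str, float, np.ndarray]] | Receptor,
    reference_ligands: list[Conformer],
    surface_margin: float = 0.25,
    shell_thickness: float = 10.0,
) -> list[ExcludedVolume]:
    """Build the excluded-volume shell from receptor atoms.

    A receptor atom yields a sphere (center at the atom, radius its vdW
    radius) iff its surface-to-ligand-surface distance d satisfies
    ``surface_margin <= d <= shell_thickness`` where

        d = min over reference-ligand heavy atoms of
            (center distance - vdW_receptor - vdW_ligand).

    Atoms closer than the margin to any ligand are ignored (they would
    clash with the ligands that define the model); atoms beyond the shell
    thickness are irrelevant to sterics.
    """
    if isinstance(receptor_atoms, Receptor):
        atoms = receptor_atoms.atom_tuples()
    else:
        atoms = list(receptor_atoms)
    if not atoms:
        raise ValueError("receptor is empty")
    if not reference_ligands:
        raise ValueError("at least one reference ligand pose is required")

    lig_coords = np.vstack([c.heavy_coords for c in reference_ligands])
    lig_radii = np.concatenate([c.heavy_radii() for c in reference_ligands])

    spheres: list[ExcludedVolume] = []
    eps = 1e-9  # keep the inclusive bounds robust to float round-off
    for element, radius, pos in atoms:
        pos = np.asarray(pos, dtype=float)
        d = np.min(np.linalg.norm(lig_coords - pos, axis=1) - radius - lig_radii)
        if surface_margin - eps <= d <= shell_thickness + eps:
            spheres.append(ExcludedVolume(center=pos, radius=radius, source_atom=element))
    return spheres


# ---------------------------------------------------------------------------
# Interaction detection and the coherence test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionGeometry:
    """Geometric cutoffs for interaction detection (standard practice
    values; all configurable)."""

    hbond_distance: float = 3.5  # donor..acceptor heavy-atom distance, Å
    hbond_angle: float = 120.0  # D-H...A angle, degrees
    hydrophobic_distance: float = 4.5  # apolar C..apolar C, Å


@dataclass
class Interaction:
    kind: str  # hydrogen_bond | hydrophobic_contact
    ligand_atoms: tuple[int, ...]
    receptor_residue: tuple[str, int, str]  # (chain, resSeq, resName)
    distance: float
    angle: float | None = None
    receptor_atom: str = ""
    receptor_is_backbone: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("hydrogen_bond", "hydrophobic_contact"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not self.distance > 0:
            raise ValueError("interaction distance must be positive")


def _ligand_hydrogens_on(conf: Conformer, heavy_idx: int, bonds: list[tuple[int, int]]) -> list[int]:
    out = []
    for i, j in bonds:
        if i == heavy_idx and conf.elements[j] == "H":
            out.append(j)
        elif j == heavy_idx and conf.elements[i] == "H":
            out.append(i)
    return out


def detect_interactions(
    conf: Conformer,
    features: list[FeaturePoint],
    receptor: Receptor,
    geometry: InteractionGeometry = InteractionGeometry(),
    ligand_bonds: list[tuple[int, int]] | None = None,
) -> list[Interaction]:
    """Detect hydrogen bonds and hydrophobic contacts of a ligand pose.

    A hydrogen bond is emitted when a ligand donor (acceptor) heavy atom
    lies within the distance cutoff of a receptor N/O acceptor (donor N)
    atom; when the ligand's explicit H positions are available the
    D-H...A angle must also exceed the angular cutoff, otherwise the
    check is distance-only.  A hydrophobic contact pairs a ligand apolar
    carbon with a receptor side-chain carbon within the distance cutoff.
    """
    interactions: list[Interaction] = []
    rec_is_no = np.isin(receptor.elements, ["N", "O"])
    rec_polar_idx = np.where(rec_is_no)[0]
    backbone = receptor.is_backbone()

    def residue_of(i: int) -> tuple[str, int, str]:
        return (str(receptor.chain_ids[i]), int(receptor.res_ids[i]), str(receptor.res_names[i]))

    # Hydrogen bonds via perceived donor/acceptor features.
    for feat in features:
        if feat.kind not in ("donor", "acceptor"):
            continue
        heavy_idx = feat.member_atoms[0]
        d_pos = conf.coords[heavy_idx]
        for ri in rec_polar_idx:
            # ligand donor -> receptor N/O acceptor; ligand acceptor -> receptor
            # donor nitrogen (backbone N or side-chain N carries an H)
            if feat.kind == "acceptor" and receptor.elements[ri] != "N":
                continue
            dist = float(np.linalg.norm(receptor.coords[ri] - d_pos))
            if dist > geometry.hbond_distance or dist < 1.0:
                continue
            angle = None
            if feat.kind == "donor" and ligand_bonds is not None:
                h_atoms = _ligand_hydrogens_on(conf, heavy_idx, ligand_bonds)
                if h_atoms:
                    best = -1.0
                    for h in h_atoms:
                        v1 = d_pos - conf.coords[h]
                        v2 = receptor.coords[ri] - conf.coords[h]
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
                    angle = best
                    if angle < geometry.hbond_angle:
                        continue
            interactions.append(
                Interaction(
                    kind="hydrogen_bond",
                    ligand_atoms=(heavy_idx,),
                    receptor_residue=residue_of(ri),
                    distance=dist,
                    angle=angle,
                    receptor_atom=str(receptor.atom_names[ri]),
                    receptor_is_backbone=bool(backbone[ri]),
                )
            )

    # Hydrophobic contacts: ligand apolar carbons vs receptor side-chain carbons.
    apolar_ligand = []
    for idx in conf.heavy_indices:
        if conf.elements[idx] != "C":
            continue
        if ligand_bonds is not None:
            nbr_elements = {
                conf.elements[j if i == idx else i]
                for i, j in ligand_bonds
                if idx in (i, j)
            }
            if nbr_elements & {"N", "O", "S", "P"}:
                continue
        apolar_ligand.append(idx)
    rec_apolar = np.where((receptor.elements == "C") & ~backbone)[0]
    for li in apolar_ligand:
        for ri in rec_apolar:
            dist = float(np.linalg.norm(receptor.coords[ri] - conf.coords[li]))
            if dist <= geometry.hydrophobic_distance:
                interactions.append(
                    Interaction(
                        kind="hydrophobic_contact",
                        ligand_atoms=(li,),
                        receptor_residue=residue_of(ri),
                        distance=dist,
                        receptor_atom=str(receptor.atom_names[ri]),
                    )
                )
    return interactions


def is_knowledge_based_coherent(
    interactions: list[Interaction],
    hinge_residues: frozenset[int] | set[int] = DEFAULT_HINGE_RESIDUES,
    pocket_residues: frozenset[int] | set[int] = DEFAULT_POCKET_RESIDUES,
) -> bool:
    """A pose is coherent iff it makes >= 1 hydrogen bond to a main-chain
    atom of a hinge-region residue and >= 1 hydrophobic contact with a
    hydrophobic-pocket residue."""
    if not hinge_residues or not pocket_residues:
        raise ValueError("residue sets must be nonempty")
    has_hinge_hb = any(
        i.kind == "hydrogen_bond"
        and i.receptor_is_backbone
        and i.receptor_residue[1] in hinge_residues
        for i in interactions
    )
    has_pocket_contact = any(
        i.kind == "hydrophobic_contact" and i.receptor_residue[1] in pocket_residues
        for i in interactions
    )
    return has_hinge_hb and has_pocket_contact
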