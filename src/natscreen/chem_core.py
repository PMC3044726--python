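"""Molecule/conformer data model, I/O, conformer enumeration and descriptors.

The unit every screening stage consumes is a :class:`Molecule`: an RDKit
chemical graph plus zero or more 3D conformers, an identifier and a
natural-product label.  Pharmacophoric feature perception (hydrogen-bond
donors/acceptors, hydrophobic groups including aromatic-ring centroids)
and classic rule-of-five descriptors live here as well.

RDKit does the heavy lifting for SMILES/SDF parsing, distance-geometry
conformer embedding (ETKDG) and the Crippen additive-atomic-contribution
logP; this module defines the stable surface the rest of the package uses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

FEATURE_KINDS = ("donor", "acceptor", "hydrophobic", "aromatic_hydrophobic")

_VDW_TABLE: dict[str, float] | None = None
_VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Å (table shipped as package data)."""
    global _VDW_TABLE, _VDW_DEFAULT
    if _VDW_TABLE is None:
        raw = json.loads(
            resources.files("natscreen.data").joinpath("vdw_radii.json").read_text()
        )
        _VDW_TABLE = dict(raw["radii"])
        _VDW_DEFAULT = float(raw["default"])
    return _VDW_TABLE.get(element, _VDW_DEFAULT)


@dataclass
class Conformer:
    """One 3D coordinate set of a molecule (all atoms, explicit H included).

    ``coords`` is (n_atoms, 3) in Å with the parent molecule's atom
    ordering.  ``charges`` holds per-atom partial charges (e) when they
    have been assigned.
    """

    coords: np.ndarray
    elements: tuple[str, ...]
    energy_rank: int = 0
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements/coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices]

    @property
    def heavy_elements(self) -> tuple[str, ...]:
        return tuple(self.elements[i] for i in self.heavy_indices)

    def heavy_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.heavy_elements])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a copy with coordinates mapped through x -> R x + t."""
        return Conformer(
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            elements=self.elements,
            energy_rank=self.energy_rank,
            charges=None if self.charges is None else np.array(self.charges),
        )


@dataclass
class Molecule:
    """A chemical graph with optional conformers and screening metadata."""

    identifier: str
    rdmol: Chem.Mol
    is_natural_product: bool = False
    source_smiles: str | None = None
    embed_failed: bool = False

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.GetSymbol() for a in self.rdmol.GetAtoms())

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    def conformer(self, index: int = 0) -> Conformer:
        conf = self.rdmol.GetConformer(self.rdmol.GetConformers()[index].GetId())
        charges = None
        if self.rdmol.GetAtomWithIdx(0).HasProp("_GasteigerCharge"):
            charges = np.array(
                [a.GetDoubleProp("_GasteigerCharge") for a in self.rdmol.GetAtoms()]
            )
        return Conformer(
            coords=np.array(conf.GetPositions(), dtype=float),
            elements=self.elements,
            energy_rank=index,
            charges=charges,
        )

    def conformers(self) -> Iterator[Conformer]:
        for i in range(self.n_conformers):
            yield self.conformer(i)

    def bonds(self) -> list[tuple[int, int]]:
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in self.rdmol.GetBonds()]

    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.rdmol))


@dataclass
class FeaturePoint:
    """A perceived pharmacophoric feature of one conformer."""

    kind: str
    position: np.ndarray
    member_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float)
        self.member_atoms = tuple(sorted(self.member_atoms))


@dataclass(frozen=True)
class LipinskiDescriptors:
    molecular_weight: float
    logp: float
    hbd_count: int
    hba_count: int

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError("descriptor counts must be nonnegative")


class Library(Sequence):
    """A read library: molecules plus the count of unparseable records."""

    def __init__(self, molecules: list[Molecule], skipped: int = 0) -> None:
        self.molecules = molecules
        self.skipped = skipped

    def __len__(self) -> int:
        return len(self.molecules)

    def __getitem__(self, i):
        return self.molecules[i]

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)


def _molecule_from_rdmol(
    rdmol: Chem.Mol, identifier: str, source_smiles: str | None = None
) -> Molecule:
    flag = False
    if rdmol.HasProp("is_natural_product"):
        flag = rdmol.GetProp("is_natural_product").strip().lower() in ("1", "true", "yes")
    return Molecule(
        identifier=identifier,
        rdmol=rdmol,
        is_natural_product=flag,
        source_smiles=source_smiles,
    )


def read_library(path: str | Path, fmt: str | None = None) -> Library:
    """Read a SMILES (one record per line, optional id) or SDF V2000 file.

    Records that fail chemistry perception are skipped and counted in
    ``Library.skipped``.  SDF 3D coordinates become conformer 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "smiles"

    molecules: list[Molecule] = []
    skipped = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else f"{path.stem}_{lineno + 1}"
            rdmol = Chem.MolFromSmiles(smiles)
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparseable SMILES record at line %d", lineno + 1)
                continue
            molecules.append(_molecule_from_rdmol(rdmol, ident, source_smiles=smiles))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparseable SDF record %d", i)
                continue
            ident = rdmol.GetProp("_Name") if rdmol.GetProp("_Name") else f"{path.stem}_{i + 1}"
            molecules.append(_molecule_from_rdmol(rdmol, ident))
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    return Library(molecules, skipped)


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules (conformer 0 when present) to an SDF V2000 file."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in molecules:
            rdmol = Chem.Mol(mol.rdmol)
            rdmol.SetProp("_Name", mol.identifier)
            rdmol.SetProp("is_natural_product", "1" if mol.is_natural_product else "0")
            if rdmol.GetNumConformers() == 0:
                rdmol = Chem.AddHs(rdmol)
                AllChem.Compute2DCoords(rdmol)
            writer.write(rdmol)
    finally:
        writer.close()


def standardize_protonation(mol: Molecule) -> Molecule:
    """Single rule-based protonation pass at pH 7.

    Protonates aliphatic amines and deprotonates carboxylic acids; no
    tautomer or multi-state enumeration.
    """
    rw = Chem.RWMol(mol.rdmol)
    amine = Chem.MolFromSmarts("[NX3;H2,H1,H0;!$(N[CX3]=[OX1]);!$(N=*);!a;+0]")
    acid = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
    for (idx,) in rw.GetSubstructMatches(amine):
        atom = rw.GetAtomWithIdx(idx)
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    for match in rw.GetSubstructMatches(acid):
        o_idx = match[2]
        atom = rw.GetAtomWithIdx(o_idx)
        atom.SetFormalCharge(-1)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Molecule(
        identifier=mol.identifier,
        rdmol=out,
        is_natural_product=mol.is_natural_product,
        source_smiles=mol.source_smiles,
    )


def enumerate_conformers(
    mol: Molecule, max_conformers: int = 200, seed: int = 0
) -> Molecule:
    """Embed up to ``max_conformers`` 3D conformers with ETKDG.

    Deterministic for a fixed seed.  On embedding failure the returned
    molecule carries zero conformers and ``embed_failed=True``.
    """
    rdmol = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = 0.25
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=int(max_conformers), params=params)
    out = Molecule(
        identifier=mol.identifier,
        rdmol=rdmol,
        is_natural_product=mol.is_natural_product,
        source_smiles=mol.source_smiles,
    )
    if len(ids) == 0:
        logger.warning("conformer embedding failed for %s", mol.identifier)
        out.embed_failed = True
    return out


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------


@dataclass
class FeatureRules:
    """SMARTS rules for donors/acceptors plus structural hydrophobic rules."""

    donor_smarts: list[str] = field(default_factory=list)
    acceptor_smarts: list[str] = field(default_factory=list)
    min_aliphatic_chain: int = 3

    @classmethod
    def default(cls) -> "FeatureRules":
        text = resources.files("natscreen.data").joinpath("feature_rules.smarts").read_text()
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "FeatureRules":
        rules = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, smarts = line.split(None, 1)
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid feature SMARTS: {smarts}")
            if kind == "donor":
                rules.donor_smarts.append(smarts)
            elif kind == "acceptor":
                rules.acceptor_smarts.append(smarts)
            else:
                raise ValueError(f"unknown feature rule kind {kind!r}")
        return rules


_DEFAULT_RULES: FeatureRules | None = None


def _default_rules() -> FeatureRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = FeatureRules.default()
    return _DEFAULT_RULES


def _aliphatic_clusters(rdmol: Chem.Mol, min_size: int) -> list[tuple[int, ...]]:
    # Contiguous non-aromatic carbons with no attached heteroatom collapse
    # into one hydrophobic cluster per connected component.
    eligible = set()
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIsAromatic():
            continue
        if any(n.GetSymbol() not in ("C", "H") for n in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    clusters: list[tuple[int, ...]] = []
    seen: set[int] = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        comp = []
        stack = [start]
        while stack:
            idx = stack.pop()
            if idx in seen:
                continue
            seen.add(idx)
            comp.append(idx)
            for n in rdmol.GetAtomWithIdx(idx).GetNeighbors():
                if n.GetIdx() in eligible and n.GetIdx() not in seen:
                    stack.append(n.GetIdx())
        if len(comp) >= min_size:
            clusters.append(tuple(sorted(comp)))
    return clusters


def perceive_features(
    mol: Molecule, conf_index: int = 0, rules: FeatureRules | None = None
) -> list[FeaturePoint]:
    """Perceive donor/acceptor/hydrophobic feature points of one conformer.

    Donors and acceptors are placed on the matched heavy atom; each
    aromatic ring yields one ``aromatic_hydrophobic`` feature at its
    centroid; contiguous aliphatic-carbon clusters (>= 3 C, no attached
    heteroatom) yield one ``hydrophobic`` feature at their centroid.
    Output order is deterministic: by kind, then lowest member atom index.
    """
    rules = rules or _default_rules()
    rdmol = mol.rdmol
    conf = mol.conformer(conf_index)
    coords = conf.coords

    feats: list[FeaturePoint] = []
    for kind, smarts_list in (("donor", rules.donor_smarts), ("acceptor", rules.acceptor_smarts)):
        atoms: set[int] = set()
        for smarts in smarts_list:
            patt = Chem.MolFromSmarts(smarts)
            for match in rdmol.GetSubstructMatches(patt):
                atoms.add(match[0])
        for idx in sorted(atoms):
            feats.append(FeaturePoint(kind=kind, position=coords[idx], member_atoms=(idx,)))

    ring_info = rdmol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = coords[list(ring)].mean(axis=0)
            feats.append(
                FeaturePoint(kind="aromatic_hydrophobic", position=centroid, member_atoms=ring)
            )
    for cluster in _aliphatic_clusters(rdmol, rules.min_aliphatic_chain):
        centroid = coords[list(cluster)].mean(axis=0)
        feats.append(FeaturePoint(kind="hydrophobic", position=centroid, member_atoms=cluster))

    feats.sort(key=lambda f: (FEATURE_KINDS.index(f.kind), f.member_atoms))
    return feats


def assign_gasteiger_charges(mol: Molecule) -> Molecule:
    """Assign Gasteiger partial charges (electronegativity-equalization
    scheme) in place on the molecule's atoms; conformers extracted
    afterwards carry them."""
    AllChem.ComputeGasteigerCharges(mol.rdmol)
    for atom in mol.rdmol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            atom.SetDoubleProp("_GasteigerCharge", 0.0)
    return mol


def compute_descriptors(mol: Molecule) -> LipinskiDescriptors:
    """Rule-of-five descriptors: MW, Crippen logP, HBD, HBA (N+O count)."""
    rdmol = Chem.RemoveHs(Chem.Mol(mol.rdmol))
    return LipinskiDescriptors(
        molecular_weight=Descriptors.MolWt(rdmol),
        logp=Crippen.MolLogP(rdmol),
        hbd_count=int(Lipinski.NumHDonors(rdmol)),
        hba_count=int(Lipinski.NOCount(rdmol)),
    )
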