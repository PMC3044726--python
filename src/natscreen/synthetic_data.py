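"""Synthetic fixtures for every pipeline stage: a toy kinase-hinge
receptor, a matching pharmacophore, planted active molecules, certified
non-matching decoys and simulated dose-response curves.

The reference complex is built around a rigid para-hydroxybenzamide
template ligand: the pharmacophore's two donor sites sit on the amide
nitrogen and phenol oxygen, the acceptor site on the carbonyl oxygen and
the hydrophobic site (3.0 Å tolerance) on the aromatic-ring centroid —
the 2-donor/1-acceptor/1-hydrophobic site pattern of an ATP-competitive
kinase-inhibitor pharmacophore.  A minimal polypeptide fragment (hinge
residues numbered 96-99, hydrophobic-pocket residues 29/44/152/165) is
placed around the template pose so that the pose hydrogen-bonds to the
hinge main chain and contacts the pocket, and the excluded-volume shell
is derived from those receptor atoms.

Receptor coordinates are synthetic mock geometry, not derived from any
experimental or homology-model structure.

Every generator is a pure function of (spec, seed), and every generated
molecule is verified by the consuming module's own checker (the flexible
matcher, the interaction detector) before being returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from rdkit import Chem

from .chem_core import (
    Conformer,
    Molecule,
    assign_gasteiger_charges,
    compute_descriptors,
    enumerate_conformers,
    perceive_features,
)
from .dose_response import DoseResponsePoint, four_pl
from .pharmacophore_model import (
    ExcludedVolume,
    PharmacophoreModel,
    PharmacophoreSite,
    Receptor,
    build_excluded_volumes,
)
from .pharm_match import flexible_match, generate_poses

TEMPLATE_SMILES = "NC(=O)c1ccc(O)cc1"
_EMBED_SEED = 20110224  # fixed template embedding seed (fixture identity)

#: Rigid variants presenting all four / three / two pharmacophore features.
ACTIVE_TEMPLATES = {
    4: [
        "NC(=O)c1ccc(O)cc1",
        "NC(=O)c1ccc(O)c(C)c1",
        "NC(=O)c1ccc(O)c(F)c1",
        "NC(=O)c1ccc(O)c(Cl)c1",
        "CNC(=O)c1ccc(O)cc1",
        "NC(=O)c1ccc(O)c(OC)c1",
    ],
    3: [
        "NC(=O)c1ccccc1",
        "NC(=O)c1ccc(C)cc1",
        "NC(=O)c1ccc(F)cc1",
        "CNC(=O)c1ccccc1",
    ],
    2: [
        "CC(=O)c1ccccc1",
        "COC(=O)c1ccccc1",
        "CC(=O)c1ccc(C)cc1",
    ],
}

_DECOY_TEMPLATES = [
    "{a}c1ccc({b})cc1",
    "{a}c1cccc({b})c1",
    "{a}c1ccccc1{b}",
    "{a}c1ccc({b})cn1",
    "{a}c1cc({b})ccn1",
    "{a}c1ccc({b})o1",
    "{a}c1ccc({b})s1",
    "{a}c1cc({b})co1",
    "{a}c1cc({b})cs1",
    "{a}c1ccc2cc({b})ccc2c1",
    "{a}C1CCC({b})CC1",
    "{a}C1CCC({b})C1",
    "{a}c1ncc({b})cn1",
    "{a}c1ccc(C{b})cc1",
    "{a}c1cccc(C{b})c1",
    "{a}c1ccc(CC{b})cc1",
    "{a}c1ccc({b})c(C)c1",
    "{a}c1cc({b})ccc1C",
    "{a}c1ccc({b})c(F)c1",
    "{a}c1cc({b})cc(C)c1",
]
_DECOY_PREFIX = [
    "C", "CC", "CCC", "CC(C)", "CC(=O)", "CCC(=O)", "COC(=O)", "N#C",
    "CO", "CCO", "COC", "CN(C)", "O", "N", "CC(=O)N", "OCC",
    "CCOC(=O)", "CC(C)C", "CS", "CCN(C)",
]
_DECOY_PAREN = [
    "C", "CC", "CCC", "C(C)C", "F", "Cl", "OC", "OCC", "C(=O)C", "C(=O)OC",
    "C(=O)N(C)C", "C#N", "N(C)C", "O", "N", "CO", "CN", "NC(=O)C", "C(F)(F)F", "SC",
    "C(C)(C)C", "CSC", "CC#N", "C(=O)CC", "N(CC)CC", "OC(C)C", "COC",
]


@dataclass
class SyntheticLibrarySpec:
    n_actives: int = 20
    n_decoys: int = 1000
    seed: int = 0
    planted_match_sites: int = 4
    jitter: float = 0.0  # positional noise sigma, Å
    conformers_per_molecule: int = 12
    property_window: "PropertyWindow | None" = None


@dataclass(frozen=True)
class PropertyWindow:
    """Descriptor ranges decoys must fall in (coarse property matching).

    For per-active matching in the DUD style, pass descriptor targets to
    :func:`make_decoy_set` instead; the per-target tolerances are MW
    ±30 Da, logP ±0.75, HBD ±2 and HBA ±1.
    """

    molecular_weight: tuple[float, float] = (110.0, 230.0)
    logp: tuple[float, float] = (-1.0, 3.0)
    hbd: tuple[int, int] = (0, 3)
    hba: tuple[int, int] = (1, 4)

    def contains(self, desc) -> bool:
        return (
            self.molecular_weight[0] <= desc.molecular_weight <= self.molecular_weight[1]
            and self.logp[0] <= desc.logp <= self.logp[1]
            and self.hbd[0] <= desc.hbd_count <= self.hbd[1]
            and self.hba[0] <= desc.hba_count <= self.hba[1]
        )


#: Per-target matching tolerances.  MW and logP are matched tightly;
#: hydrogen-bond counts use coarse bins, as in DUD-style decoy
#: selection, because the geometric non-matching certification
#: systematically rejects donor-rich candidates: with donor and acceptor
#: sites only ~2.3 Å apart, almost any donor-bearing aromatic candidate
#: can satisfy three sites, so certified decoys are donor-poor by
#: necessity.
MATCH_TOL_MW = 30.0
MATCH_TOL_LOGP = 0.75
MATCH_TOL_HBD = 2
MATCH_TOL_HBA = 1


def _matches_target(desc, target) -> bool:
    return (
        abs(desc.molecular_weight - target.molecular_weight) <= MATCH_TOL_MW
        and abs(desc.logp - target.logp) <= MATCH_TOL_LOGP
        and abs(desc.hbd_count - target.hbd_count) <= MATCH_TOL_HBD
        and abs(desc.hba_count - target.hba_count) <= MATCH_TOL_HBA
    )


# ---------------------------------------------------------------------------
# Reference complex: template pose, receptor fragment, pharmacophore
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _template_molecule() -> Molecule:
    mol = Molecule(identifier="template", rdmol=Chem.MolFromSmiles(TEMPLATE_SMILES))
    mol = enumerate_conformers(mol, max_conformers=1, seed=_EMBED_SEED)
    if mol.n_conformers == 0:
        raise RuntimeError("template embedding failed")
    mol.is_natural_product = False
    return mol


def _template_geometry(mol: Molecule):
    rdmol = mol.rdmol
    conf = mol.conformer(0)
    amide = rdmol.GetSubstructMatch(Chem.MolFromSmarts("[NX3][CX3]=[OX1]"))
    phenol = rdmol.GetSubstructMatch(Chem.MolFromSmarts("[OX2H1]"))
    n_idx, _, carbonyl_o = amide
    phenol_o = phenol[0]
    ring = next(
        r
        for r in rdmol.GetRingInfo().AtomRings()
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    )
    ring_coords = conf.coords[list(ring)]
    centroid = ring_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_coords - centroid)
    normal = vt[2]
    h_idx = next(
        n.GetIdx()
        for n in rdmol.GetAtomWithIdx(n_idx).GetNeighbors()
        if n.GetSymbol() == "H"
    )
    return {
        "conf": conf,
        "amide_n": conf.coords[n_idx],
        "amide_h_dir": _unit(conf.coords[h_idx] - conf.coords[n_idx]),
        "carbonyl_o": conf.coords[carbonyl_o],
        "phenol_o": conf.coords[phenol_o],
        "ring_centroid": centroid,
        "ring_normal": normal,
    }


def _toy_receptor_atoms(geom) -> struc.AtomArray:
    """Hand-placed backbone/side-chain atoms around the template pose.

    The Cys99 backbone carbonyl oxygen is put on the amide N-H axis at
    hydrogen-bond distance; the remaining hinge residues extend as a
    strand perpendicular to that axis; Val29's side chain sits along the
    ring normal within hydrophobic-contact range; the other pocket
    residues surround the site at excluded-volume range.
    """
    n_pos = geom["amide_n"]
    u = geom["amide_h_dir"]
    rc = geom["ring_centroid"]
    nv = geom["ring_normal"]
    o99 = n_pos + 2.9 * u
    w = _unit(o99 - rc)
    s = np.cross(w, nv)
    if np.linalg.norm(s) < 1e-6:
        s = np.cross(w, np.array([1.0, 0.0, 0.0]))
    s = _unit(s)

    atoms: list[tuple[str, int, str, str, np.ndarray]] = []  # (resname, resid, atomname, element, xyz)

    def backbone(resname, resid, base):
        atoms.append((resname, resid, "O", "O", base))
        c = base + 1.23 * w
        atoms.append((resname, resid, "C", "C", c))
        ca = c + 1.52 * _unit(0.5 * s + 0.87 * w)
        atoms.append((resname, resid, "CA", "C", ca))
        atoms.append((resname, resid, "N", "N", ca + 1.46 * _unit(0.8 * s - 0.6 * nv)))
        return ca

    hinge_names = {96: "MET", 97: "GLU", 98: "TYR", 99: "CYS", 100: "GLN"}
    for resid, offset in ((96, -3), (97, -2), (98, -1), (99, 0), (100, 1)):
        backbone(hinge_names[resid], resid, o99 + 3.5 * offset * s)

    # Val29: CB within hydrophobic-contact range of the ring face.
    cb = rc + 4.0 * nv
    atoms.append(("VAL", 29, "CB", "C", cb))
    atoms.append(("VAL", 29, "CG1", "C", cb + 1.54 * _unit(nv + 0.8 * s)))
    atoms.append(("VAL", 29, "CG2", "C", cb + 1.54 * _unit(nv - 0.8 * s)))
    ca29 = cb + 1.54 * nv
    atoms.append(("VAL", 29, "CA", "C", ca29))
    atoms.append(("VAL", 29, "N", "N", ca29 + 1.46 * s))
    atoms.append(("VAL", 29, "C", "C", ca29 + 1.52 * _unit(nv + s)))
    atoms.append(("VAL", 29, "O", "O", ca29 + 1.52 * _unit(nv + s) + 1.23 * nv))

    def pocket(resname, resid, direction, dist):
        base = rc + dist * _unit(direction)
        atoms.append((resname, resid, "CB", "C", base))
        atoms.append((resname, resid, "CG", "C", base + 1.54 * _unit(direction)))
        ca = base + 1.54 * _unit(direction) + 1.54 * _unit(direction + 0.3 * s)
        atoms.append((resname, resid, "CA", "C", ca))
        atoms.append((resname, resid, "N", "N", ca + 1.46 * s))
        atoms.append((resname, resid, "C", "C", ca + 1.52 * _unit(direction)))
        atoms.append((resname, resid, "O", "O", ca + 1.52 * _unit(direction) + 1.23 * nv))

    pocket("LYS", 44, -nv, 4.8)
    pocket("VAL", 152, nv + s, 5.5)
    pocket("ILE", 165, nv - s, 5.5)

    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a[4] for a in atoms], dtype=np.float32)
    arr.chain_id = np.array(["A"] * len(atoms))
    arr.res_id = np.array([a[1] for a in atoms], dtype=int)
    arr.res_name = np.array([a[0] for a in atoms])
    arr.atom_name = np.array([a[2] for a in atoms])
    arr.element = np.array([a[3] for a in atoms])
    arr.hetero = np.array([False] * len(atoms))
    return arr


@dataclass
class ReferenceComplex:
    model: PharmacophoreModel
    receptor: Receptor
    atom_array: struc.AtomArray = field(repr=False, default=None)
    template: Molecule = None

    def reference_pose(self) -> Conformer:
        return self.template.conformer(0)


@lru_cache(maxsize=4)
def reference_complex(seed: int = 0) -> ReferenceComplex:
    """Build the synthetic hinge complex: template pose, toy receptor,
    and the four-site pharmacophore with its excluded-volume shell.

    The site pattern and tolerances (donor/donor/acceptor 1.5 Å,
    hydrophobic 3.0 Å) are fixed; ``seed`` only perturbs nothing today
    and is kept for interface stability.
    """
    del seed  # the fixture is a constant; see docstring
    template = _template_molecule()
    geom = _template_geometry(template)
    arr = _toy_receptor_atoms(geom)
    receptor = Receptor.from_atom_array(arr)
    sites = [
        PharmacophoreSite(kind="donor", center=geom["amide_n"], tolerance=1.5),
        PharmacophoreSite(kind="donor", center=geom["phenol_o"], tolerance=1.5),
        PharmacophoreSite(kind="acceptor", center=geom["carbonyl_o"], tolerance=1.5),
        PharmacophoreSite(kind="hydrophobic", center=geom["ring_centroid"], tolerance=3.0),
    ]
    evs = build_excluded_volumes(receptor, [template.conformer(0)])
    model = PharmacophoreModel(sites=sites, excluded_volumes=evs, min_match_sites=3)
    return ReferenceComplex(model=model, receptor=receptor, atom_array=arr, template=template)


def make_toy_receptor(
    model: PharmacophoreModel | None = None, seed: int = 0
) -> tuple[Receptor, Molecule]:
    """Toy hinge receptor plus the reference ligand pose it was built
    around.  The shipped pose forms one hinge main-chain hydrogen bond
    and one pocket hydrophobic contact (verified by the interaction
    detector in the test suite)."""
    del model
    complex_ = reference_complex(seed)
    return complex_.receptor, complex_.template


def write_receptor_pdb(receptor_atoms: struc.AtomArray, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(receptor_atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Planted actives and decoys
# ---------------------------------------------------------------------------


def _max_matched_count(mol: Molecule, model: PharmacophoreModel) -> int:
    """Largest accepted match size over all conformers (uses the matcher
    itself with prefer_more_sites, so verification shares the screen's
    acceptance rules)."""
    greedy = PharmacophoreModel(
        sites=model.sites,
        excluded_volumes=model.excluded_volumes,
        min_match_sites=model.min_match_sites,
        mandatory_sites=model.mandatory_sites,
        prefer_more_sites=True,
    )
    best = 0
    for ci in range(mol.n_conformers):
        res = flexible_match(perceive_features(mol, ci), mol.conformer(ci), greedy)
        if res is not None:
            best = max(best, res.matched_count)
    return best


def _jittered(mol: Molecule, sigma: float, rng: np.random.Generator) -> Molecule:
    if sigma <= 0:
        return mol
    rdmol = Chem.Mol(mol.rdmol)
    for conf in rdmol.GetConformers():
        pos = conf.GetPositions() + rng.normal(0.0, sigma, size=(rdmol.GetNumAtoms(), 3))
        for i, xyz in enumerate(pos):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
    return Molecule(
        identifier=mol.identifier,
        rdmol=rdmol,
        is_natural_product=mol.is_natural_product,
        source_smiles=mol.source_smiles,
    )


def make_planted_active(
    model: PharmacophoreModel,
    k_sites: int = 4,
    jitter: float = 0.0,
    seed: int = 0,
    conformers: int = 12,
    identifier: str | None = None,
) -> Molecule:
    """A molecule with at least one conformer whose features match exactly
    ``k_sites`` pharmacophore sites (after reorientation, within
    tolerance, no excluded-volume clash), verified by the matcher itself.

    Built from rigid hydroxy/benzamide templates whose feature geometry
    reproduces the site layout; raises when no template/seed realizes the
    requested match count.
    """
    if k_sites > len(model.sites):
        raise ValueError("k_sites exceeds the number of model sites")
    templates = ACTIVE_TEMPLATES.get(k_sites)
    if templates is None:
        raise ValueError(f"no planted-active template family for k={k_sites}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(templates)))
    for attempt in range(3 * len(templates)):
        smiles = templates[order[attempt % len(templates)]]
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol = Molecule(
            identifier=identifier or f"active_k{k_sites}_{seed}",
            rdmol=Chem.MolFromSmiles(smiles),
            is_natural_product=True,
            source_smiles=smiles,
        )
        mol = enumerate_conformers(mol, max_conformers=conformers, seed=embed_seed)
        if mol.n_conformers == 0:
            continue
        mol.is_natural_product = True
        mol = _jittered(mol, jitter, rng)
        achieved = _max_matched_count(mol, model)
        if k_sites >= model.min_match_sites:
            if achieved == k_sites:
                return mol
        elif achieved == 0:
            # below-threshold plant: verified NOT a hit at screen settings
            return mol
    raise RuntimeError(f"could not realize a planted active with k={k_sites} (seed {seed})")


def _decoy_pool() -> list[str]:
    """The unique combinatorial decoy candidate pool (canonical SMILES),
    in deterministic order."""
    global _DECOY_POOL_CACHE
    if _DECOY_POOL_CACHE is None:
        seen: set[str] = set()
        pool: list[str] = []
        for template in _DECOY_TEMPLATES:
            for a in _DECOY_PREFIX:
                for b in _DECOY_PAREN:
                    rdmol = Chem.MolFromSmiles(template.format(a=a, b=b))
                    if rdmol is None:
                        continue
                    canonical = Chem.MolToSmiles(rdmol)
                    if canonical not in seen:
                        seen.add(canonical)
                        pool.append(canonical)
        _DECOY_POOL_CACHE = pool
    return _DECOY_POOL_CACHE


_DECOY_POOL_CACHE: list[str] | None = None
_DECOY_DESC_CACHE: dict[str, object] = {}


def _decoy_descriptors(canonical: str):
    desc = _DECOY_DESC_CACHE.get(canonical)
    if desc is None:
        desc = compute_descriptors(Molecule(identifier="x", rdmol=Chem.MolFromSmiles(canonical)))
        _DECOY_DESC_CACHE[canonical] = desc
    return desc


def make_decoy_set(
    n: int,
    property_window: PropertyWindow | None = None,
    seed: int = 0,
    model: PharmacophoreModel | None = None,
    conformers: int = 8,
    targets: list | None = None,
) -> list[Molecule]:
    """Property-matched decoys certified non-matching by the flexible
    matcher at screen settings.

    Candidates come from a fixed combinatorial pool of one- and two-ring
    scaffolds with common substituents, visited in a seed-shuffled order.
    With ``targets`` (a list of active descriptor records), each
    candidate must match a randomly drawn active within the per-property
    tolerances (MW/logP tight, H-bond counts coarse-binned); otherwise
    the coarse ``property_window`` is applied.  Every returned decoy is
    verified to have no flexible pharmacophore match over its own
    conformers.  Raises with the achieved count if the pool cannot
    supply ``n`` certified decoys.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    window = property_window or PropertyWindow()
    if model is None:
        model = reference_complex().model
    rng = np.random.default_rng(seed)
    pool = list(_decoy_pool())
    rng.shuffle(pool)
    decoys: list[Molecule] = []
    for canonical in pool:
        if len(decoys) >= n:
            break
        desc = _decoy_descriptors(canonical)
        if targets:
            if not any(_matches_target(desc, target) for target in targets):
                continue
        elif not window.contains(desc):
            continue
        mol = Molecule(
            identifier=f"decoy_{len(decoys):05d}",
            rdmol=Chem.MolFromSmiles(canonical),
            is_natural_product=True,
            source_smiles=canonical,
        )
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol = enumerate_conformers(mol, max_conformers=conformers, seed=embed_seed)
        if mol.n_conformers == 0:
            continue
        mol.is_natural_product = True
        matches = any(
            flexible_match(perceive_features(mol, ci), mol.conformer(ci), model) is not None
            for ci in range(mol.n_conformers)
        )
        if matches:
            continue
        decoys.append(mol)
    if len(decoys) < n:
        raise RuntimeError(
            f"could only generate {len(decoys)} of {n} certified decoys "
            f"from a pool of {len(pool)} candidates"
        )
    return decoys


def make_validation_library(spec: SyntheticLibrarySpec, model: PharmacophoreModel | None = None):
    """Planted actives + certified decoys with labels, ready for
    ``vs_pipeline.validate``.  Returns (actives, decoys)."""
    if model is None:
        model = reference_complex().model
    rng = np.random.default_rng(spec.seed)
    actives = []
    for i in range(spec.n_actives):
        actives.append(
            make_planted_active(
                model,
                k_sites=spec.planted_match_sites,
                jitter=spec.jitter,
                seed=int(rng.integers(1, 2**31 - 1)),
                conformers=spec.conformers_per_molecule,
                identifier=f"active_{i:04d}",
            )
        )
    decoys = make_decoy_set(
        spec.n_decoys,
        property_window=spec.property_window,
        seed=int(rng.integers(1, 2**31 - 1)),
        model=model,
        conformers=max(4, spec.conformers_per_molecule // 2),
        targets=[compute_descriptors(m) for m in actives],
    )
    return actives, decoys


def make_query_poses(
    model: PharmacophoreModel | None = None, n_queries: int = 3, seed: int = 7
) -> tuple[list[Conformer], list[str]]:
    """Query poses for the overlay stage: matched-transform poses of
    planted actives, with partial charges assigned (the stand-in for the
    docked poses of known inhibitors used as similarity queries)."""
    if model is None:
        model = reference_complex().model
    rng = np.random.default_rng(seed)
    queries: list[Conformer] = []
    ids: list[str] = []
    while len(queries) < n_queries:
        mol = make_planted_active(
            model, k_sites=4, seed=int(rng.integers(1, 2**31 - 1)), identifier=f"query_{len(queries)}"
        )
        assign_gasteiger_charges(mol)
        poses = generate_poses(mol, model, max_poses=1)
        if not poses:
            continue
        pose = poses[0]
        conf = mol.conformer(pose.match.conformer_index)
        posed = conf.transformed(pose.match.rotation, pose.match.translation)
        queries.append(posed)
        ids.append(mol.identifier)
    return queries, ids


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------


def simulate_dose_response(
    top: float,
    bottom: float,
    hill: float,
    log_ic50: float,
    doses: list[float],
    sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> list[DoseResponsePoint]:
    """Noisy 4PL readouts: y = 4PL(log10 dose) + N(0, sigma) per
    replicate; deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    points = []
    for dose in doses:
        x = math.log10(dose)
        mean = four_pl(x, top, bottom, hill, log_ic50)
        for rep in range(replicates):
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            points.append(
                DoseResponsePoint(concentration=dose, response=float(mean + noise), replicate=rep)
            )
    return points
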