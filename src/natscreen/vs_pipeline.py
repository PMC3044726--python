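"""Virtual-screening workflow orchestration and enrichment-factor
accounting.

Stage order: ADME/Tox -> pharmacophore search with reorientation ->
pose generation -> pharmacophore rescoring in place -> shape/
electrostatic similarity selection.  A molecule survives a stage when
any of its conformers/poses passes (per-molecule semantics), so survivor
sets are nested across stages.

For labeled validation runs, each stage's enrichment factor is

    EF = (actives_out / total_out) / (actives_in / total_in)

and the global EF (first stage in, last stage out) equals the product of
the per-stage EFs exactly — the factors telescope as rationals, so the
identity is computed with exact arithmetic and only converted to float
for presentation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction

from .admet_filter import LipinskiThresholds, ToxRule, admet_pass, load_tox_rules
from .chem_core import Conformer, Molecule, assign_gasteiger_charges, enumerate_conformers, perceive_features
from .overlay_scoring import GridSpec, OverlayScore, best_query_score
from .pharmacophore_model import PharmacophoreModel
from .pharm_match import Pose, generate_poses, score_in_place

STAGE_NAMES = (
    "admet",
    "pharmacophore_flexible",
    "pose_generation",
    "pharmacophore_in_place",
    "shape_electrostatics",
)


class PipelineError(ValueError):
    pass


@dataclass
class StageCounts:
    name: str
    total_in: int
    total_out: int
    actives_in: int | None = None
    actives_out: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.total_out <= self.total_in:
            raise ValueError(f"stage {self.name}: totals must satisfy 0 <= out <= in")
        if self.actives_in is not None and self.actives_out is not None:
            if self.actives_out > self.actives_in:
                raise ValueError(f"stage {self.name}: actives_out > actives_in")


def enrichment_factor(
    actives_in: int, total_in: int, actives_out: int, total_out: int, stage: str = ""
) -> float:
    """EF = (actives_out/total_out) / (actives_in/total_in)."""
    return float(
        enrichment_factor_exact(actives_in, total_in, actives_out, total_out, stage)
    )


def enrichment_factor_exact(
    actives_in: int, total_in: int, actives_out: int, total_out: int, stage: str = ""
) -> Fraction:
    if total_in <= 0 or total_out <= 0 or actives_in <= 0:
        raise PipelineError(
            f"enrichment factor undefined at stage {stage or '<unnamed>'}: "
            f"actives_in={actives_in}, total_in={total_in}, total_out={total_out}"
        )
    return Fraction(actives_out, total_out) / Fraction(actives_in, total_in)


@dataclass
class ScreenConfig:
    model: PharmacophoreModel
    queries: list[Conformer] = field(default_factory=list)
    query_ids: list[str] | None = None
    seed: int = 0
    max_conformers: int = 20
    max_poses: int = 32
    max_violations: int = 1
    tox_rules: list[ToxRule] | None = None
    lipinski_thresholds: LipinskiThresholds = field(default_factory=LipinskiThresholds)
    et_threshold: float = 0.850
    grid: GridSpec = field(default_factory=GridSpec)
    dielectric: float = 80.0
    clash_use_vdw: bool = False
    regenerate_conformers: bool = False

    def fingerprint(self) -> str:
        """Stable configuration hash for report provenance."""
        doc = {
            "sites": [
                [s.kind, [round(float(v), 6) for v in s.center], s.tolerance]
                for s in self.model.sites
            ],
            "n_ev": len(self.model.excluded_volumes),
            "min_match_sites": self.model.min_match_sites,
            "seed": self.seed,
            "max_conformers": self.max_conformers,
            "max_poses": self.max_poses,
            "max_violations": self.max_violations,
            "et_threshold": self.et_threshold,
            "grid": [self.grid.spacing, self.grid.margin],
            "dielectric": self.dielectric,
            "clash_use_vdw": self.clash_use_vdw,
            "n_queries": len(self.queries),
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    stages: list[StageCounts]
    hits: list[str]
    per_stage_ef: dict[str, float] = field(default_factory=dict)
    global_ef: float | None = None
    overlay_scores: dict[str, OverlayScore] = field(default_factory=dict)
    exit_stage: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "stages": [
                {
                    "name": s.name,
                    "total_in": s.total_in,
                    "total_out": s.total_out,
                    "actives_in": s.actives_in,
                    "actives_out": s.actives_out,
                }
                for s in self.stages
            ],
            "per_stage_ef": self.per_stage_ef,
            "global_ef": self.global_ef,
            "hits": self.hits,
            "exit_stage": self.exit_stage,
            "overlay_scores": {
                k: {
                    "shape_tanimoto": v.shape_tanimoto,
                    "electro_tanimoto": v.electro_tanimoto,
                    "et_combo": v.et_combo,
                    "query_id": v.query_id,
                }
                for k, v in sorted(self.overlay_scores.items())
            },
            "provenance": self.provenance,
        }
        return json.dumps(doc, sort_keys=True, indent=1)


def run_screen(
    library: list[Molecule],
    config: ScreenConfig,
    labels: dict[str, bool] | None = None,
) -> ScreenReport:
    """Run the five-stage screen; with ``labels`` (id -> is-active),
    per-stage and global enrichment factors are reported."""
    if config.model is None:
        raise PipelineError("config.model is required")
    if not config.queries:
        raise PipelineError("config.queries is required (overlay stage)")
    ids = [m.identifier for m in library]
    if len(set(ids)) != len(ids):
        raise PipelineError("duplicate molecule identifiers in library")

    def n_actives(mols: list[Molecule]) -> int | None:
        if labels is None:
            return None
        return sum(1 for m in mols if labels.get(m.identifier, False))

    stages: list[StageCounts] = []
    exit_stage: dict[str, str] = {}
    survivors = list(library)

    # Stage 1: ADME/Tox
    tox = config.tox_rules if config.tox_rules is not None else load_tox_rules()
    passed = []
    for mol in survivors:
        decision = admet_pass(
            mol, config.max_violations, tox, thresholds=config.lipinski_thresholds
        )
        if decision.passed:
            passed.append(mol)
        else:
            exit_stage[mol.identifier] = "admet"
    stages.append(
        StageCounts(
            "admet", len(survivors), len(passed), n_actives(survivors), n_actives(passed)
        )
    )
    survivors = passed

    # Conformers are generated once after the ADME stage and reused by
    # both pharmacophore stages.
    prepared = []
    for i, mol in enumerate(survivors):
        if mol.n_conformers == 0 or config.regenerate_conformers:
            mol = enumerate_conformers(
                mol, config.max_conformers, seed=(config.seed * 100003 + i) % (2**31 - 1)
            )
        prepared.append(mol)
    survivors = prepared

    # Stage 2+3: flexible pharmacophore search and pose generation
    # (poses come from the matched transforms, computed once).
    poses_by_mol: dict[str, list[Pose]] = {}
    flex_pass = []
    for mol in survivors:
        poses = generate_poses(
            mol, config.model, config.max_poses, clash_use_vdw=config.clash_use_vdw
        )
        if poses:
            poses_by_mol[mol.identifier] = poses
            flex_pass.append(mol)
        else:
            exit_stage[mol.identifier] = "pharmacophore_flexible"
    stages.append(
        StageCounts(
            "pharmacophore_flexible",
            len(survivors),
            len(flex_pass),
            n_actives(survivors),
            n_actives(flex_pass),
        )
    )
    survivors = flex_pass

    posed = [m for m in survivors if poses_by_mol.get(m.identifier)]
    for m in survivors:
        if m.identifier not in poses_by_mol:
            exit_stage[m.identifier] = "pose_generation"
    stages.append(
        StageCounts(
            "pose_generation", len(survivors), len(posed), n_actives(survivors), n_actives(posed)
        )
    )
    survivors = posed

    # Stage 4: score in place on the generated poses.
    in_place_pass = []
    best_pose: dict[str, Pose] = {}
    for mol in survivors:
        kept = None
        for pose in poses_by_mol[mol.identifier]:
            features = perceive_features(mol, pose.match.conformer_index)
            posed_features = [
                type(f)(
                    kind=f.kind,
                    position=pose.match.rotation @ f.position + pose.match.translation,
                    member_atoms=f.member_atoms,
                )
                for f in features
            ]
            res = score_in_place(
                posed_features, pose.conformer, config.model, clash_use_vdw=config.clash_use_vdw
            )
            if res is not None:
                kept = pose
                break
        if kept is not None:
            best_pose[mol.identifier] = kept
            in_place_pass.append(mol)
        else:
            exit_stage[mol.identifier] = "pharmacophore_in_place"
    stages.append(
        StageCounts(
            "pharmacophore_in_place",
            len(survivors),
            len(in_place_pass),
            n_actives(survivors),
            n_actives(in_place_pass),
        )
    )
    survivors = in_place_pass

    # Stage 5: shape + electrostatic similarity against the query poses.
    overlay_scores: dict[str, OverlayScore] = {}
    final = []
    for mol in survivors:
        assign_gasteiger_charges(mol)
        pose = best_pose[mol.identifier]
        conf = mol.conformer(pose.match.conformer_index)
        posed_conf = conf.transformed(pose.match.rotation, pose.match.translation)
        score = best_query_score(
            posed_conf, config.queries, config.query_ids, config.grid, config.dielectric
        )
        overlay_scores[mol.identifier] = score
        if score.et_combo >= config.et_threshold:
            final.append(mol)
        else:
            exit_stage[mol.identifier] = "shape_electrostatics"
    stages.append(
        StageCounts(
            "shape_electrostatics",
            len(survivors),
            len(final),
            n_actives(survivors),
            n_actives(final),
        )
    )

    report = ScreenReport(
        stages=stages,
        hits=[m.identifier for m in final],
        overlay_scores=overlay_scores,
        exit_stage=exit_stage,
        provenance={"config": config.fingerprint(), "seed": config.seed, "n_input": len(library)},
    )
    if labels is not None:
        per_stage: dict[str, Fraction] = {}
        for s in stages:
            per_stage[s.name] = enrichment_factor_exact(
                s.actives_in, s.total_in, s.actives_out, s.total_out, s.name
            )
        product = Fraction(1)
        for v in per_stage.values():
            product *= v
        report.per_stage_ef = {k: float(v) for k, v in per_stage.items()}
        report.global_ef = float(product)
    return report


def validate(
    actives: list[Molecule], decoys: list[Molecule], config: ScreenConfig
) -> ScreenReport:
    """Labeled validation run: actives and decoys must be disjoint by id."""
    active_ids = {m.identifier for m in actives}
    decoy_ids = {m.identifier for m in decoys}
    overlap = active_ids & decoy_ids
    if overlap:
        raise PipelineError(f"ids present in both actives and decoys: {sorted(overlap)[:5]}")
    labels = {i: True for i in active_ids}
    labels.update({i: False for i in decoy_ids})
    return run_screen(list(actives) + list(decoys), config, labels=labels)
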