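"""Pharmacophore matching: flexible search with reorientation, in-place
rescoring and pose generation, all with excluded-volume steric rejection.

A conformer matches when at least ``min_match_sites`` type-compatible
sites can be superposed onto distinct perceived features by a proper
rigid transform that leaves every matched pair within its site tolerance
and places no ligand heavy atom inside an excluded-volume sphere.  Among
accepted assignments the one with the lowest site RMSD wins (matched
count does not rank unless ``prefer_more_sites`` is set); ties break on
the lexicographically smallest assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .chem_core import Conformer, FeaturePoint, Molecule, perceive_features
from .pharmacophore_model import PharmacophoreModel


class DegenerateGeometryError(ValueError):
    """Fewer than three pairs, or collinear points: no unique superposition."""


@dataclass
class MatchResult:
    assignment: dict[int, int]  # site index -> feature index
    rotation: np.ndarray  # proper rotation (det +1), applied to the ligand
    translation: np.ndarray
    site_rmsd: float
    matched_count: int
    ev_clash: bool
    is_hit: bool
    conformer_index: int = 0

    def assignment_key(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.assignment.items()))


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(1.0, s[0])


def kabsch_superpose(
    pairs: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rigid superposition of feature points onto
    site centers (Kabsch, SVD form).

    Each pair is (site center, feature position).  Returns (R, t, rmsd)
    such that ``R @ feature + t`` approximates the site center and R has
    determinant +1 (reflections are excluded).
    """
    if len(pairs) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    sites = np.array([np.asarray(s, float) for s, _ in pairs])
    feats = np.array([np.asarray(f, float) for _, f in pairs])
    if _collinear(sites) or _collinear(feats):
        raise DegenerateGeometryError("collinear point set")
    sc = sites.mean(axis=0)
    fc = feats.mean(axis=0)
    h = (feats - fc).T @ (sites - sc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = sc - rotation @ fc
    moved = feats @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - sites) ** 2, axis=1))))
    return rotation, translation, rmsd


def _ev_clash(
    heavy_coords: np.ndarray, model: PharmacophoreModel, atom_radii: np.ndarray | None = None
) -> bool:
    """Clash = a ligand heavy-atom center inside an excluded-volume sphere
    (center rule; pass atom radii to add the vdW radius instead)."""
    if not model.excluded_volumes:
        return False
    centers = np.array([ev.center for ev in model.excluded_volumes])
    radii = np.array([ev.radius for ev in model.excluded_volumes])
    dists = np.linalg.norm(heavy_coords[:, None, :] - centers[None, :, :], axis=2)
    if atom_radii is not None:
        dists = dists - atom_radii[:, None]
    return bool(np.any(dists < radii[None, :]))


def _candidate_assignments(
    features: list[FeaturePoint], model: PharmacophoreModel
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (site subset, feature tuple) injective type-compatible
    assignments of at least ``min_match_sites`` sites, honoring mandatory
    sites, in deterministic lexicographic order."""
    n_sites = len(model.sites)
    compatible = [
        [fi for fi, f in enumerate(features) if model.sites[si].accepts(f.kind)]
        for si in range(n_sites)
    ]
    out = []
    for k in range(model.min_match_sites, n_sites + 1):
        for subset in itertools.combinations(range(n_sites), k):
            if not model.mandatory_sites <= set(subset):
                continue
            pools = [compatible[si] for si in subset]
            for choice in itertools.product(*pools):
                if len(set(choice)) != len(choice):
                    continue
                out.append((subset, choice))
    return out


def _evaluate_assignment(
    subset: tuple[int, ...],
    choice: tuple[int, ...],
    features: list[FeaturePoint],
    conf: Conformer,
    model: PharmacophoreModel,
    in_place: bool,
    clash_use_vdw: bool,
) -> MatchResult | None:
    pairs = [(model.sites[si].center, features[fi].position) for si, fi in zip(subset, choice)]
    if in_place:
        rotation = np.eye(3)
        translation = np.zeros(3)
    else:
        try:
            rotation, translation, _ = kabsch_superpose(pairs)
        except DegenerateGeometryError:
            return None
    deltas = [
        np.linalg.norm(rotation @ f + translation - s) for s, f in pairs
    ]
    # inclusive tolerance boundary
    if any(
        d > model.sites[si].tolerance + 1e-12 for d, si in zip(deltas, subset)
    ):
        return None
    moved_heavy = conf.heavy_coords @ rotation.T + translation
    clash = _ev_clash(
        moved_heavy, model, atom_radii=conf.heavy_radii() if clash_use_vdw else None
    )
    if clash:
        return None
    rmsd = float(np.sqrt(np.mean(np.square(deltas))))
    return MatchResult(
        assignment=dict(zip(subset, choice)),
        rotation=rotation,
        translation=translation,
        site_rmsd=rmsd,
        matched_count=len(subset),
        ev_clash=False,
        is_hit=True,
    )


def _best_match(
    features: list[FeaturePoint],
    conf: Conformer,
    model: PharmacophoreModel,
    in_place: bool,
    clash_use_vdw: bool,
) -> MatchResult | None:
    best: MatchResult | None = None
    for subset, choice in _candidate_assignments(features, model):
        res = _evaluate_assignment(
            subset, choice, features, conf, model, in_place, clash_use_vdw
        )
        if res is None:
            continue
        if best is None:
            best = res
            continue
        if model.prefer_more_sites and res.matched_count != best.matched_count:
            if res.matched_count > best.matched_count:
                best = res
            continue
        if res.site_rmsd < best.site_rmsd - 1e-12:
            best = res
        elif abs(res.site_rmsd - best.site_rmsd) <= 1e-12 and res.assignment_key() < best.assignment_key():
            best = res
    return best


def flexible_match(
    features: list[FeaturePoint],
    conf: Conformer,
    model: PharmacophoreModel,
    clash_use_vdw: bool = False,
) -> MatchResult | None:
    """Match with reorientation: enumerate type-compatible assignments,
    superpose each, accept iff all matched pairs are within tolerance and
    no heavy atom is transformed into an excluded volume.  Returns the
    accepted assignment with the lowest site RMSD, or None."""
    return _best_match(features, conf, model, in_place=False, clash_use_vdw=clash_use_vdw)


def score_in_place(
    features: list[FeaturePoint],
    conf: Conformer,
    model: PharmacophoreModel,
    clash_use_vdw: bool = False,
) -> MatchResult | None:
    """Match without reorientation (identity transform): the pose must
    already satisfy the tolerances and excluded volumes in the frame it
    is given in."""
    return _best_match(features, conf, model, in_place=True, clash_use_vdw=clash_use_vdw)


@dataclass
class Pose:
    """A conformer placed in the pharmacophore/receptor frame by its
    matched transform."""

    conformer: Conformer
    match: MatchResult
    molecule_id: str = ""


def generate_poses(
    mol: Molecule,
    model: PharmacophoreModel,
    max_poses: int = 32,
    clash_use_vdw: bool = False,
) -> list[Pose]:
    """For each conformer with a flexible match, emit the matched-transform
    pose; rank by site RMSD and return at most ``max_poses``."""
    scored: list[Pose] = []
    for ci in range(mol.n_conformers):
        conf = mol.conformer(ci)
        features = perceive_features(mol, ci)
        res = flexible_match(features, conf, model, clash_use_vdw=clash_use_vdw)
        if res is None:
            continue
        res.conformer_index = ci
        posed = conf.transformed(res.rotation, res.translation)
        scored.append(Pose(conformer=posed, match=res, molecule_id=mol.identifier))
    scored.sort(key=lambda p: (p.match.site_rmsd, p.match.conformer_index))
    return scored[: int(max_poses)]
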