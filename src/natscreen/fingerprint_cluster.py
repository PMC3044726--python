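"""Scaffold-hopping triage: atom-environment (MOLPRINT 2D style)
fingerprints, set Tanimoto similarity, sphere-exclusion (Butina)
clustering and identification of natural-product-only clusters.

Each heavy atom contributes one canonical environment string encoding
its own type (element + aromaticity flag) and the multisets of neighbor
types at bond distances 1 and 2.  The fingerprint is the *set* of these
strings, which makes it invariant under atom renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_core import Molecule


@dataclass(frozen=True)
class Fingerprint:
    environments: frozenset[str]

    def __post_init__(self) -> None:
        if not self.environments:
            raise ValueError("fingerprint must be nonempty")


def _atom_type(atom: Chem.Atom) -> str:
    return f"{atom.GetSymbol()}{'ar' if atom.GetIsAromatic() else ''}"


def molprint_fingerprint(mol: Molecule) -> Fingerprint:
    """One environment string per heavy atom, canonicalized by sorting
    neighbor-type counts; duplicates collapse (set semantics)."""
    rdmol = Chem.RemoveHs(Chem.Mol(mol.rdmol))
    if rdmol.GetNumAtoms() == 0:
        raise ValueError("molecule has no heavy atoms")
    dmat = Chem.GetDistanceMatrix(rdmol)
    envs: set[str] = set()
    for atom in rdmol.GetAtoms():
        i = atom.GetIdx()
        shells = []
        for depth in (1, 2):
            types = sorted(
                _atom_type(rdmol.GetAtomWithIdx(j))
                for j in range(rdmol.GetNumAtoms())
                if dmat[i, j] == depth
            )
            counts: dict[str, int] = {}
            for t in types:
                counts[t] = counts.get(t, 0) + 1
            shells.append(",".join(f"{t}:{n}" for t, n in sorted(counts.items())))
        envs.add(f"{_atom_type(atom)}|{shells[0]}|{shells[1]}")
    return Fingerprint(environments=frozenset(envs))


def tanimoto_sets(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B|; symmetric, in [0, 1], 1 iff the sets are equal."""
    inter = len(a.environments & b.environments)
    union = len(a.environments | b.environments)
    if union == 0:
        raise ValueError("both fingerprints are empty")
    return inter / union


@dataclass
class ClusterReport:
    clusters: list[list[str]]
    labels: dict[str, str] = field(default_factory=dict)
    np_only_cluster_ids: list[int] = field(default_factory=list)
    candidate_count: int = 0

    def all_ids(self) -> list[str]:
        return [i for cluster in self.clusters for i in cluster]


def _butina(ids: list[str], sim: np.ndarray, threshold: float) -> list[list[str]]:
    """Sphere-exclusion clustering: repeatedly pick the unassigned item
    with the most unassigned neighbors (similarity >= threshold) as a
    centroid and absorb its neighbors.  Deterministic given input order
    (ties break on input position)."""
    n = len(ids)
    neighbor = [set(np.flatnonzero(sim[i] >= threshold)) - {i} for i in range(n)]
    unassigned = set(range(n))
    clusters: list[list[int]] = []
    while unassigned:
        best = max(
            sorted(unassigned),
            key=lambda i: (len(neighbor[i] & unassigned), -i),
        )
        members = [best] + sorted(neighbor[best] & unassigned - {best})
        clusters.append(members)
        unassigned -= set(members)
    return [[ids[i] for i in members] for members in clusters]


def _complete_linkage(ids: list[str], sim: np.ndarray, n_clusters: int) -> list[list[str]]:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    assign = fcluster(z, t=n_clusters, criterion="maxclust")
    out: dict[int, list[str]] = {}
    for ident, c in zip(ids, assign):
        out.setdefault(int(c), []).append(ident)
    return [out[k] for k in sorted(out)]


def cluster_molecules(
    fps: dict[str, Fingerprint],
    method: str = "butina",
    similarity_threshold: float = 0.4,
    n_clusters: int | None = None,
) -> ClusterReport:
    """Cluster molecules by fingerprint Tanimoto.

    ``butina`` (default) is sphere exclusion at a similarity threshold;
    ``complete`` is complete-linkage cut to a target cluster count (for
    parity experiments against tools that report a fixed cluster count).
    """
    ids = list(fps)
    if not ids:
        raise ValueError("no fingerprints to cluster")
    n = len(ids)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto_sets(fps[ids[i]], fps[ids[j]])
            sim[i, j] = sim[j, i] = s
    if method == "butina":
        clusters = _butina(ids, sim, similarity_threshold)
    elif method == "complete":
        if n_clusters is None:
            raise ValueError("complete-linkage mode requires n_clusters")
        clusters = _complete_linkage(ids, sim, n_clusters)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterReport(clusters=clusters)


def scaffold_hopping_candidates(report: ClusterReport) -> ClusterReport:
    """Identify clusters containing only natural products; their members
    are the scaffold-hopping candidates.

    ``report.labels`` must map every clustered id to ``natural_product``
    or ``known_inhibitor``.
    """
    np_only: list[int] = []
    count = 0
    for ci, members in enumerate(report.clusters):
        classes = set()
        for ident in members:
            if ident not in report.labels:
                raise ValueError(f"unlabeled molecule id {ident!r}")
            classes.add(report.labels[ident])
        if classes == {"natural_product"}:
            np_only.append(ci)
            count += len(members)
    report.np_only_cluster_ids = np_only
    report.candidate_count = count
    return report
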