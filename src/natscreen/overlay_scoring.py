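"""Shape and electrostatic similarity of poses: Gaussian volume overlap,
Coulomb potential grids, the two Tanimoto scores and their sum (ET_combo).

Shape: each heavy atom is an isotropic Gaussian whose amplitude/width
follow the Grant-Pickup convention (amplitude p = 2*sqrt(2); the width is
set so the Gaussian integrates to the atom's vdW sphere volume).  The
pairwise product integrals have a closed form, and the shape Tanimoto is

    ST = O_AB / (O_AA + O_BB - O_AB)            in [0, 1].

Electrostatics: a uniform-dielectric Coulomb potential evaluated on a
rectilinear grid over the union bounding box of the pair, with points
inside any atom's vdW radius masked out.  The electrostatic Tanimoto

    ET = <a,b> / (<a,a> + <b,b> - <a,b>)

is 1 for identical fields and negative when positive and negative
potentials overlap.  Because ET is a ratio of bilinear forms it is
invariant to uniform potential scaling, which is what justifies the
uniform-dielectric approximation in place of a Poisson-Boltzmann solver.
ET_combo = ST + ET (maximum 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_core import Conformer

#: Grant-Pickup Gaussian amplitude.
GAUSSIAN_AMPLITUDE = 2.0 * np.sqrt(2.0)


def _gaussian_alphas(radii: np.ndarray, amplitude: float = GAUSSIAN_AMPLITUDE) -> np.ndarray:
    # alpha chosen so each Gaussian integrates to its vdW sphere volume:
    # p * (pi/alpha)^(3/2) = (4/3) pi R^3
    return np.pi * (3.0 * amplitude / (4.0 * np.pi * radii**3)) ** (2.0 / 3.0)


def gaussian_overlap(
    a: Conformer, b: Conformer, amplitude: float = GAUSSIAN_AMPLITUDE
) -> float:
    """First-order Gaussian overlap volume O_AB in Å^3 (symmetric)."""
    ca, cb = a.heavy_coords, b.heavy_coords
    aa = _gaussian_alphas(a.heavy_radii(), amplitude)
    ab = _gaussian_alphas(b.heavy_radii(), amplitude)
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=2)
    s = aa[:, None] + ab[None, :]
    prefac = amplitude * amplitude * (np.pi / s) ** 1.5
    return float(np.sum(prefac * np.exp(-(aa[:, None] * ab[None, :] / s) * d2)))


def shape_tanimoto(a: Conformer, b: Conformer) -> float:
    """Gaussian shape Tanimoto; 1 for a perfect overlap (same shape)."""
    o_ab = gaussian_overlap(a, b)
    o_aa = gaussian_overlap(a, a)
    o_bb = gaussian_overlap(b, b)
    denom = o_aa + o_bb - o_ab
    if denom <= 0 or o_aa <= 0 or o_bb <= 0:
        raise ValueError("zero-volume conformer in shape comparison")
    return o_ab / denom


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear grid parameters, Å.

    ``mask_inflation`` is added to each heavy atom's vdW radius when
    masking interior grid points.  It stands in for the hydrogen
    envelope (the mask is built from heavy atoms only) and keeps the
    near-surface 1/r divergence out of the Tanimoto integral, which
    makes the score converge quickly under grid refinement.
    """

    spacing: float = 0.5
    margin: float = 4.0
    mask_inflation: float = 0.5


@dataclass
class PotentialField:
    """A scalar potential sampled on a grid, with a validity mask (False
    where the point lies inside an atom's vdW sphere)."""

    values: np.ndarray
    mask: np.ndarray
    origin: np.ndarray
    spacing: float


def _grid_points(confs: list[Conformer], grid: GridSpec) -> tuple[np.ndarray, np.ndarray, tuple]:
    all_coords = np.vstack([c.heavy_coords for c in confs])
    lo = all_coords.min(axis=0) - grid.margin
    hi = all_coords.max(axis=0) + grid.margin
    axes = [np.arange(lo[k], hi[k] + grid.spacing, grid.spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return mesh, lo, shape


def _interior_mask(points: np.ndarray, conf: Conformer, inflation: float = 0.0) -> np.ndarray:
    """True where the point is inside some atom's (inflated) vdW sphere."""
    coords = conf.heavy_coords
    radii = conf.heavy_radii() + inflation
    inside = np.zeros(len(points), dtype=bool)
    for pos, rad in zip(coords, radii):
        inside |= np.einsum("ij,ij->i", points - pos, points - pos) < rad * rad
    return inside


def coulomb_potential(
    atom_positions: np.ndarray,
    charges: np.ndarray,
    points: np.ndarray,
    dielectric: float = 1.0,
) -> np.ndarray:
    """phi at each point: sum_i q_i / (eps * |x - r_i|), internal units."""
    atom_positions = np.atleast_2d(np.asarray(atom_positions, float))
    points = np.atleast_2d(np.asarray(points, float))
    charges = np.atleast_1d(np.asarray(charges, float))
    out = np.zeros(len(points))
    for pos, q in zip(atom_positions, charges):
        r = np.maximum(np.linalg.norm(points - pos, axis=1), 1e-9)
        out += q / (dielectric * r)
    return out


def potential_grid(
    conf: Conformer,
    grid: GridSpec = GridSpec(),
    dielectric: float = 80.0,
    companions: list[Conformer] | None = None,
) -> PotentialField:
    """Coulomb potential phi(x) = sum_i q_i / (eps * |x - r_i|) on a grid
    covering the conformer (and any companions) plus margin.

    Heavy-atom partial charges must be assigned.  Grid points inside any
    atom's vdW radius (of the conformer or a companion) are masked out so
    the Tanimoto integral runs over exterior space only.
    """
    if conf.charges is None:
        raise ValueError("conformer has no partial charges")
    charges = np.asarray(conf.charges, dtype=float)
    if np.abs(charges.sum()) > conf.n_atoms:
        raise ValueError("unphysical total charge")
    group = [conf] + list(companions or [])
    points, origin, shape = _grid_points(group, grid)
    inside = np.zeros(len(points), dtype=bool)
    for c in group:
        inside |= _interior_mask(points, c, grid.mask_inflation)
    values = np.zeros(len(points))
    outside = ~inside
    # all atoms (H included) carry charge; use full coordinates
    values[outside] = coulomb_potential(conf.coords, charges, points[outside], dielectric)
    return PotentialField(values=values, mask=outside, origin=origin, spacing=grid.spacing)


def electro_tanimoto(a: PotentialField, b: PotentialField) -> float:
    """Electrostatic Tanimoto of two fields on the identical grid/mask."""
    if a.values.shape != b.values.shape:
        raise ValueError("fields are not on the same grid")
    if not np.array_equal(a.mask, b.mask):
        raise ValueError("fields do not share a mask")
    va = a.values[a.mask]
    vb = b.values[b.mask]
    ab = float(np.dot(va, vb))
    aa = float(np.dot(va, va))
    bb = float(np.dot(vb, vb))
    if aa == 0.0 and bb == 0.0:
        raise ValueError("both fields are identically zero")
    return ab / (aa + bb - ab)


def electrostatic_tanimoto_pair(
    a: Conformer, b: Conformer, grid: GridSpec = GridSpec(), dielectric: float = 80.0
) -> float:
    """Convenience: build the shared union grid for a pair and return ET."""
    fa = potential_grid(a, grid, dielectric, companions=[b])
    fb = potential_grid(b, grid, dielectric, companions=[a])
    return electro_tanimoto(fa, fb)


@dataclass
class OverlayScore:
    shape_tanimoto: float
    electro_tanimoto: float
    et_combo: float
    query_id: str

    def __post_init__(self) -> None:
        if not -1e-9 <= self.shape_tanimoto <= 1 + 1e-9:
            raise ValueError("shape Tanimoto out of [0, 1]")
        if self.electro_tanimoto > 1 + 1e-9:
            raise ValueError("electrostatic Tanimoto above 1")


def score_pair(
    candidate: Conformer,
    query: Conformer,
    query_id: str = "",
    grid: GridSpec = GridSpec(),
    dielectric: float = 80.0,
) -> OverlayScore:
    st = shape_tanimoto(candidate, query)
    et = electrostatic_tanimoto_pair(candidate, query, grid, dielectric)
    return OverlayScore(shape_tanimoto=st, electro_tanimoto=et, et_combo=st + et, query_id=query_id)


def best_query_score(
    candidate: Conformer,
    queries: list[Conformer],
    query_ids: list[str] | None = None,
    grid: GridSpec = GridSpec(),
    dielectric: float = 80.0,
) -> OverlayScore:
    """Maximum ET_combo over all query poses (ties go to the earlier
    query; the comparison is done in the shared receptor frame)."""
    if not queries:
        raise ValueError("empty query set")
    if query_ids is None:
        query_ids = [f"query_{i}" for i in range(len(queries))]
    best: OverlayScore | None = None
    for qid, query in zip(query_ids, queries):
        score = score_pair(candidate, query, qid, grid, dielectric)
        if best is None or score.et_combo > best.et_combo:
            best = score
    return best


def select_candidates(
    scores: list[OverlayScore], threshold: float = 0.850
) -> list[OverlayScore]:
    """Keep scores with ET_combo >= threshold (inclusive)."""
    return [s for s in scores if s.et_combo >= threshold]
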