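# Methods

This note documents the models, numerical choices and limitations of
the `natscreen` screening stack.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Molecules, conformers and features

Molecules are RDKit graphs with explicit-hydrogen 3D conformers embedded
by ETKDGv3 (fixed seed per call; RMSD pruning at 0.25 Å; at most
`max_conformers`, default 200).  No force-field refinement is applied —
distance-geometry conformers are accurate enough for feature-point
matching at 1.5–3.0 Å tolerances, and refinement is out of scope.

Pharmacophoric features are perceived from a shipped SMARTS rule file
(`data/feature_rules.smarts`), a documented stand-in for the proprietary
feature definitions of commercial tools:

* **donor** — any N/O bearing a hydrogen; the feature point is the heavy
  atom (point features, not projected points).
* **acceptor** — carbonyl/ether/hydroxyl oxygens, aromatic and sp²/sp³
  nitrogens with an available lone pair; amide and anilinic nitrogens
  excluded.
* **aromatic_hydrophobic** — one feature at each aromatic-ring centroid.
* **hydrophobic** — contiguous clusters of ≥ 3 non-aromatic carbons with
  no attached heteroatom, collapsed to their centroid.  This granularity
  (one feature per cluster) is a deliberate choice; per-atom hydrophobic
  features would make the 3.0 Å hydrophobic site trivially satisfiable.

Rule-of-five descriptors use the classic conventions: HBD = count of
N–H/O–H groups, HBA = count of N+O atoms, logP from the Crippen additive
atomic-contribution scheme as implemented in RDKit (published parameter
set, reproducible), MW from average atomic masses.  A single rule-based
protonation pass (protonate aliphatic amines, deprotonate carboxylic
acids) approximates pH 7; ionization-state and tautomer enumeration are
out of scope because no downstream stage depends on them.

## ADME/Tox stage

A molecule passes when it breaches at most `max_violations` (default 1)
of MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10 — bounds inclusive, the common
rule-of-five reading — and matches none of the toxicophore SMARTS rules.
The shipped list (`data/tox_rules.smarts`, 31 rules) covers the usual
electrophile/chelator/frequent-hitter classes and is user-replaceable;
it makes no claim to reproduce any specific commercial rule set.

## Pharmacophore model and matching

A model is a list of typed sites (donor/acceptor/hydrophobic) with
tolerance radii, a shell of excluded-volume spheres, `min_match_sites`
(default 3), optional mandatory sites and a `prefer_more_sites` flag
(default off).  JSON persistence is versioned (schema v1) with
round-trip equality.

**Matching semantics.** All injective, type-compatible assignments of
`k ≥ min_match_sites` sites to distinct features are enumerated.  For
each assignment the optimal proper rigid transform (Kabsch, SVD form;
reflections excluded by the determinant correction) superposes the
feature points onto the site centers; the assignment is accepted iff
every matched pair lies within its site tolerance (inclusive) after the
transform and no ligand heavy-atom center falls inside an excluded
volume (a config flag adds the atom vdW radius instead).  Among accepted
assignments the lowest site RMSD wins; matched count does not rank
(unless `prefer_more_sites`), and exact ties break on the
lexicographically smallest assignment.  Collinear three-point
assignments are rejected as degenerate rather than guessed.  A
hydrophobic site accepts both aliphatic and aromatic hydrophobic
features.  Score-in-place applies the same acceptance rules at the
identity transform.

Acceptance is *defined* through the least-squares transform: an
assignment whose best-fit superposition violates a tolerance is a
non-match even if some other (non-optimal) transform would satisfy all
tolerances.  The test suite checks decision equivalence against a brute
force that enumerates every assignment with an independent alignment
solver.

**Excluded volumes.** A receptor atom yields a sphere (center at the
atom, radius = Bondi vdW radius) iff its surface-to-ligand-surface
distance `d = min over reference-ligand heavy atoms (center distance −
vdW_rec − vdW_lig)` satisfies `margin ≤ d ≤ shell` (defaults 0.25 and
10 Å, bounds inclusive with a 1e-9 guard against float round-off).
Surface semantics via vdW radii is a documented choice; the shipped
Bondi table is in `data/vdw_radii.json`.

**Interactions and coherence.** Hydrogen bonds: donor–acceptor
heavy-atom distance ≤ 3.5 Å, D–H…A angle ≥ 120° when ligand hydrogens
are available (distance-only otherwise).  Hydrophobic contacts: ligand
apolar carbon to receptor side-chain carbon ≤ 4.5 Å.  These are standard
practice values, configurable.  A pose is *knowledge-based coherent*
iff it makes ≥ 1 hydrogen bond to a main-chain atom of a hinge residue
AND ≥ 1 hydrophobic contact to a pocket residue.  Residue numbers are
taken verbatim from the input structure; the fixture uses hinge 96–99
and pocket {29, 44, 152, 165}.

## Overlay scoring

Shape uses first-order Gaussian overlaps (heavy atoms only): amplitude
p = 2√2, width α = π(3p/(4πR³))^{2/3} so each atom Gaussian integrates
to its vdW sphere volume; pair integrals are closed-form.  Higher-order
intersection corrections are omitted — the Tanimoto normalization makes
the score insensitive to the common overestimate at this order.

Electrostatics replaces a Poisson–Boltzmann solver with a
uniform-dielectric Coulomb grid (ε = 80 outside the molecules).  This is
an approximation of the screened potential, justified for a *Tanimoto*
score because the ratio is invariant under any uniform scaling of the
potentials; what it does not capture is the shape-dependent dielectric
boundary.  Grid defaults: 0.5 Å spacing, 4.0 Å margin around the pair's
union bounding box, interior masking at vdW + 0.5 Å.  The 0.5 Å mask
inflation stands in for the hydrogen envelope (the mask uses heavy atoms
only) and keeps the 1/r near-surface divergence out of the integral;
with it, refining the spacing 0.75 → 0.5 → 0.35 Å moves ET by well under
0.02 on the fixture pair (asserted in the tests).  Partial charges come
from RDKit's Gasteiger implementation (iterative electronegativity
equalization); an SDF charge column, when present, can be used instead.
Candidate and query poses are compared in the receptor frame their
matches define — there is no overlay re-optimization.

`ET_combo = ST + ET`; the selection threshold 0.850 is inclusive.
Numerical agreement with any commercial shape/electrostatics code is
explicitly not claimed.

## Fingerprints and clustering

The atom-environment fingerprint is the set of per-heavy-atom strings
`type | sorted counts of neighbor types at bond distance 1 | at
distance 2`, with atom type = element + aromaticity flag.  Set semantics
(duplicates collapse) makes it renumbering-invariant.  Similarity is set
Tanimoto.  Clustering is Butina sphere exclusion at a similarity
threshold (default 0.4), deterministic for a fixed input order; a
complete-linkage mode with a target cluster count exists for parity
experiments with tools that report a fixed number of clusters.  Clusters
whose members are all natural products are the scaffold-hopping
candidates.

## Pipeline accounting

Conformers are generated once, after the ADME stage, and reused by both
pharmacophore stages; molecules that already carry conformers (e.g.
synthetic fixtures certified at generation time) are not re-embedded
unless requested.  A molecule survives a stage if any of its
conformers/poses passes.  Enrichment factors are computed from realized
counts with `fractions.Fraction`, so the global EF equals the product of
per-stage EFs exactly; floats appear only in the report.  Reports carry
a configuration hash and seed and serialize to sorted-key JSON, making
reproducibility checkable by string equality.

## Dose-response

The 4PL uses the log10-based parameterization standard in dose-response
software.  Initialization: top/bottom from the data extremes, hill = 1,
log IC50 at the dose whose mean response is nearest half-range; the Hill
slope is bounded to [0.1, 10] during the trust-region least squares.
Replicates are fitted pooled.  Data are canonically sorted before
fitting, so the result is invariant under point shuffling.
Non-convergence is reported (`converged=False` with a message), never
raised.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the inputs a real screen would take — a
natural-product library, a curated decoy set, a receptor model and a
panel of reference inhibitor poses:

* **Reference complex.** A para-hydroxybenzamide template is embedded
  once (fixed seed); its amide N, phenol O, carbonyl O and ring centroid
  define the two donor sites, the acceptor site and the hydrophobic
  site.  Backbone fragments for hinge residues 96–100 are placed so the
  Cys99 carbonyl oxygen sits on the template's amide N–H axis at 2.9 Å
  (a canonical hinge hydrogen bond); Val29's side chain sits 4.0 Å off
  the ring face (a hydrophobic contact); Lys44/Val152/Ile165 surround
  the site at excluded-volume range.  All receptor coordinates are
  synthetic mock geometry.  The shipped pharmacophore fixture
  (`data/hinge_pharmacophore_synthetic.json`) is generated from this
  construction.
* **Planted actives** are substituted hydroxy-/benzamides embedded at a
  seed-derived conformer seed and *verified by the matcher itself* to
  achieve exactly the requested number of matched sites (a
  `prefer_more_sites` clone of the model reports the maximum accepted
  match size); sub-threshold plants are verified to be non-hits.
* **Decoys** come from a fixed combinatorial pool (~9,200 unique one-
  and two-ring scaffolds with common substituents), visited in a
  seed-shuffled order.  Each decoy must match an active's descriptors
  within MW ±30 Da and logP ±0.75, with HBD/HBA matched in coarse bins
  (±2/±1), and must have no flexible pharmacophore match over its own
  conformers.  The coarse H-bond bins are forced by the geometry: the
  donor and acceptor sites lie ~2.3 Å apart, so almost any donor-bearing
  aromatic candidate can satisfy three sites and is removed by the
  certification — certified decoy sets are therefore donor-poor relative
  to the actives, as real kinase decoy sets also tend to be.
* **Dose-response curves** are 4PL evaluations plus i.i.d. Gaussian
  noise, three replicates per dose by default.

What passing tests on these fixtures show: the stage logic, geometry,
scores and accounting behave as specified under controlled conditions
with known ground truth.  What they do not show: performance on real
chemical matter — real natural products are larger, more flexible and
more stereochemically complex than the planted templates; real decoys
are not certified non-binders; and a real receptor is not five residues
of idealized backbone.

## Problem sizes

Default study conditions: validation screens use 20 planted actives and
1,000 certified decoys (12 and 6 conformers per molecule respectively —
the planted chemotypes are rigid, so small conformer counts already
saturate the match decisions); matcher–oracle equivalence runs 200
random instances with ≤ 6 features; the stochastic dose-response study
fits 200 simulated curves (8 doses × 3 replicates, σ = 5 % of range).
The full pytest suite, including the 1,020-molecule screen, completes in
a few minutes on one CPU.

## Known limitations

* Pose generation is pharmacophore-alignment-based; there is no
  physics-based docking engine, receptor flexibility or pose energy.
* Feature perception and toxicophore lists are representative, not
  reproductions of any commercial tool's internals.
* Electrostatics is uniform-dielectric; solvation-boundary effects are
  absent by design.
* The 4PL fit reports no confidence intervals (profile likelihood is out
  of scope).
* Hinge/pocket coherence typing covers hydrogen bonds and hydrophobic
  contacts only — no π-stacking, ionic or water-mediated interactions.
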