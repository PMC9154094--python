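# Methods

## Model

`bridgewater` treats interface-water prediction as a void-detection problem:
a bridging water lives in a pocket of unoccupied space that is simultaneously
within hydrogen-bond range of a polar atom on the ligand and one on the
protein. The pipeline is purely geometric and deterministic — identical input
and parameters give bitwise-identical output — and operates on heavy atoms
only. PDB inputs usually lack hydrogens, so "hydrogen-bond donor or acceptor"
is approximated by element membership (N and O by default, S optionally):
with no explicit protons there is no donor/acceptor distinction to draw, and
at the 1 Å grid resolution of the method a finer chemical typing would be
false precision.

### Stages and their assumptions

1. **Grid** — cubic lattice centered on the ligand heavy-atom centroid, edge
   `max(2·r_max, min_edge)`. The cube is the simplest region guaranteed to
   cover every point within `r_max` of the centroid; `min_edge` (6 Å) keeps a
   usable box for near-point-like ligands. Points are generated in
   lexicographic (x, y, z) order, which fixes the output ordering end-to-end.
2. **Occupancy pruning** — a point survives iff its distance to every
   protein/ligand heavy atom is ≥ `clash_dist`. A single cutoff is used for
   all elements; per-element van-der-Waals radii would add parameters the
   coarse grid cannot exploit. Crystallographic waters do **not** occupy
   space by default: they are evaluation ground truth, and including them
   would leak the answer into the input (both toggles exist in
   `PlacementParams` for completeness). Cofactor atoms are likewise excluded
   by default, matching a curation policy that removes cofactor-adjacent
   complexes anyway.
3. **Void clustering** — single-linkage connected components at
   `cluster_dist`: two candidates are linked iff within that distance, and a
   void is a connected component. Implemented with a KD-tree proximity graph
   (`scipy.spatial.cKDTree` + `scipy.sparse.csgraph.connected_components`);
   an O(n²) union-find oracle cross-checks it in the tests. Merging is
   iterated to a fixed point — while any two void centroids lie within
   `merge_dist`, merge the closest pair (ties: lowest current indices) and
   recompute the centroid as the mean over *all* member points — because a
   single merge pass is order-dependent. Final centroids are therefore
   pairwise separated by more than `merge_dist`, and output is sorted
   lexicographically by centroid.
4. **Clash re-check** — a void wrapped around a protrusion can average to a
   centroid *inside* an atom, so centroids closer than `clash_dist` to any
   heavy atom are discarded before the shell check. This preserves the
   invariant that no water is ever emitted inside the clash radius.
5. **Hydrogen-bond shell** — accept a centroid iff at least one ligand polar
   atom *and* one protein polar atom lie in `[hbond_min, hbond_max]`; the
   nearest qualifying atom on each side is recorded as the water's contact.
   Only existence matters for acceptance; the contacts are bookkeeping.

### Parameters

| parameter | default | role |
|---|---|---|
| `grid_spacing` | 1.0 Å | lattice constant; ~water-radius resolution |
| `clash_dist` | 2.0 Å | minimum candidate-to-heavy-atom distance |
| `cluster_dist` | 2.0 Å | single-linkage threshold for voids |
| `merge_dist` | 2.0 Å | centroid merge threshold |
| `hbond_min`, `hbond_max` | 0, 3.5 Å | polar-contact shell on both sides |
| `polar_elements` | {N, O} | hydrogen-bond-capable elements |
| `min_edge` | 6.0 Å | floor on the grid edge |

2.0 Å is the one clustering value with published provenance; the remaining
defaults are round numbers in the chemically sensible range (3.5 Å is a
standard heavy-atom hydrogen-bond cutoff) and are exactly the quantities the
`param_opt` module is designed to re-fit per dataset.

### Evaluation

A crystallographic water is **bridging** if its oxygen is within 3 Å of both
a ligand and a protein heavy atom, **local** if within 5 Å of the ligand; all
distances are oxygen-to-heavy-atom, never to hydrogens, and the 3 Å census is
taken over *all* heavy atoms, not only polar ones, so the counts are a purely
geometric property of the deposited structure. Recapture matching is
per-native nearest placed water (≤ 1.4 Å succeeds), explicitly many-to-one:
the method is tuned to over- rather than under-predict, and over-prediction
is reported as its own statistic (`n_placed − n_native_bridging` per
complex). A Hungarian one-to-one matcher (`match_one_to_one`) is provided as
a clearly-labeled secondary metric for false-positive-aware analyses; it is
never used in the headline numbers.

Dataset curation (`filter_dataset`) applies, in order: no DNA/RNA residues
(name in the standard nucleotide set), no non-water cofactor within 6 Å of
the ligand, at most 6 bridging waters, resolution ≤ 1.7 Å (missing resolution
rejects). The first failing rule is the recorded rejection reason.

### Parameter optimization

The objective is the mean over training complexes of the mean per-native
nearest-placed-water distance, after stripping all waters from the input.
When placement produces nothing the distance is undefined; a finite penalty
(10 Å, configurable) substitutes, keeping the search landscape bounded.
Random search is the guaranteed backend: uniform per continuous dimension,
discrete choice for `grid_spacing`, fully reproducible from one integer seed.
TPE (via `hyperopt`) is an optional extra, not a dependency — any minimizer
satisfies the module's contract, and the objective itself is the scientific
content. Ties in the argmin go to the earliest trial. No canonical
training/benchmark split is prescribed; the module accepts any user split.

## Synthetic fixtures

The generator's purpose is *provable* ground truth, not realism. A sparse
shell of pseudo-residues cannot pin down where voids form — the open space
between shell and ligand is one large connected void whose centroid lands
nowhere useful — so the pseudo-protein is instead a **space-filling matrix**:
carbon markers on a unit lattice aligned with the search grid, occupying
everything in and around the box. Each planted bridging site is a spherical
cavity (radius 3.2 Å) carved at a lattice point 2.05–2.60 Å from its ligand
anchor (made an oxygen), with a serine-like hydroxyl placed 2.45 Å from the
site inside the cavity. On the integer lattice the surviving void points
around a site lie within √2 Å of it, so keeping sites ≥ 4.85 Å apart
guarantees (with margin over √2+√2+2.0 = 4.83) that two cavities can never
single-link, and each cavity yields exactly one centroid, within the 1.4 Å
criterion of its site. Decoy waters are sampled in the 3.25–4.75 Å band from
the ligand: local by construction, never bridging. Every fixture is
self-validated after a PDB round trip (native-water census exact, each site
uniquely recaptured, clash radii respected) with a bounded jitter-and-retry
loop; an unsatisfiable spec raises `FixtureInfeasibleError` naming the
violated constraint.

The **calibration family** (`generate_calibration_complex`) re-lines one
cavity so the placement objective has a constructed optimum: a carbon exactly
2.1 Å from the site caps the site's survival at `clash_dist` ≤ 2.1, and liner
carbons 1.7–1.9 Å from the site's open lattice neighbors make those neighbors
join the void (dragging the centroid off the site) once `clash_dist` ≤ 1.9.
The objective is hence 0 only for `clash_dist` ∈ (1.9, 2.1], the penalty
above, and strictly positive below — a unique planted optimum at 2.0 ± 0.1
that a brute-force scan verifies independently of the search. Family members
differ by a lattice-preserving rigid motion (signed axis permutation +
integer translation), which leaves every distance, and hence the objective,
invariant.

**What passing on fixtures does and does not show.** Fixtures prove the
pipeline's mechanics: partitioning, pruning, clustering, merging, shell
logic, scoring, and the optimizer's ability to recover a known optimum. They
do not probe real binding-site chemistry — solvent-exposed pockets with bulk
water, partially occluded sites, borderline polar geometry, alternate
conformations — so 100% recapture on fixtures is a correctness statement, not
a predictive-performance claim. On real curated complexes this class of
coarse-grained method recaptures roughly a third of bridging waters while
over-predicting; regression tests against the Hsp90 case (PDB 3K97, ligand
4CD) and a full curated benchmark are included but accession-gated, since
the structures cannot be redistributed here.

## Numerical choices

* Boundary semantics: pruning removes strictly-closer points (survival is
  `d ≥ clash_dist`); linkage and the shell are inclusive (`≤`); bridging/
  local/success cutoffs are inclusive.
* Grid axis count is `floor(edge/spacing + 1e-9) + 1`, the epsilon guarding
  against `edge/spacing` landing an ulp under an integer.
* Merge ties (equal centroid distances within 1e-12) resolve to the lowest
  index pair in the current cluster list.
* Coordinates are used exactly as deposited (Å, no re-centering); PDB output
  is normalized fixed-width at 3 decimals and round-trips losslessly at that
  precision. Altloc resolution keeps the highest occupancy, ties to 'A';
  insertion codes are preserved in residue identity.
* Empty inputs are legal where geometry allows: no candidates → no voids → no
  waters; a complex with no polar ligand atoms can never place a water.

## Problem sizes

The shipped test suite and acceptance script run on generated complexes of
~1.8k–16k atoms with grids of 343–4096 points (seconds per complex on one
core); benchmark statistics use 25 complexes, planted-site recovery 50
pockets, and parameter recovery 200 random trials over 3 calibration pockets.
These sizes were chosen as the smallest that exercise every code path,
including 6-site pockets at the curation limit.

## Known limitations

* No water orientations (oxygen positions only), no energetic scoring, no
  water–water networks: a water stabilized only by other waters is invisible
  to the dual protein/ligand shell criterion.
* Element-based polarity ignores protonation states and treats carbonyl and
  amide nitrogen alike; halogen-bond acceptors are excluded by default.
* A single clash radius for all elements slightly over-prunes near hydrogens'
  heavy-atom parents and under-prunes near large atoms.
* The grid is ligand-centered: bridging sites farther from the ligand
  centroid than the most distal ligand atom fall outside the search box.
* Centroid summarization is coarse; a large void's centroid can sit > 1.4 Å
  from the true hydration site even when the void itself covers it.
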