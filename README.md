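# bridgewater

Coarse-grained, structure-based prediction of **bridging water molecules** at
protein–small-molecule interfaces, with saturation-test evaluation against
crystallographic waters and a seedable parameter optimizer.

## The problem

Water molecules that sit between a bound ligand and its protein — close enough
to hydrogen-bond with both sides — mediate binding interactions that implicit
solvent models miss, and docking protocols that ignore them mispredict poses
and affinities. `bridgewater` predicts where such *bridging* waters belong
using nothing but geometry: no energy function, no prior knowledge of how many
waters to place or where crystallography found them.

## The algorithm

Given a protein–ligand complex, placement runs four deterministic steps:

1. **Grid.** A cubic lattice (default spacing 1.0 Å) is superimposed on the
   ligand. The box edge is `2·r_max`, twice the distance from the ligand
   heavy-atom centroid to its most distal heavy atom (floored at 6 Å).
2. **Occupancy pruning.** Lattice points closer than `clash_dist` (2.0 Å) to
   any protein or ligand heavy atom are removed, leaving candidate coordinates
   in unoccupied space.
3. **Void clustering.** Candidates are grouped into *voids* by single-linkage
   clustering at `cluster_dist` (2.0 Å); voids whose centroids fall within
   `merge_dist` (2.0 Å) are merged, closest pair first, until all centroids
   are separated. Each void is summarized by its centroid (the mean over all
   member points).
4. **Hydrogen-bond shell.** A centroid is accepted only if a polar heavy atom
   (N or O by default) exists on *both* the ligand and the protein within
   `[hbond_min, hbond_max]` (default 0–3.5 Å). A water oxygen is placed at
   each accepted centroid.

Evaluation uses the **saturation test**: run placement on the unperturbed
native pose, and for every native bridging water (oxygen within 3 Å of both
ligand and protein) measure the distance to the nearest placed water. A native
is *recaptured* when that distance is ≤ 1.4 Å. Over-prediction is reported
separately and never penalized. *Local* waters (within 5 Å of the ligand) are
tallied for context.

All cutoffs live in `PlacementParams` and can be re-fit with the `param_opt`
module, which minimizes the mean per-native nearest-water distance by seeded
random search (or TPE via the optional `hyperopt` extra).

## Worked example

Real curated structures cannot ship with the package, so the example uses a
generated pocket with one planted bridging site and one decoy water
(`bridgewater.synthetic`):

```python
from bridgewater import *
from bridgewater.synthetic import generate_complex, FixtureSpec

fx = generate_complex(FixtureSpec(seed=11, n_planted_sites=1, n_decoy_waters=1))
cx = load_complex(fx.pdb_text, "LIG", source_id="pocket")

placed = place_waters(cx, PlacementParams())
for p in placed:
    print(p.coord, p.ligand_contact, p.protein_contact, p.cluster_size)

bridging, local = find_native_waters(cx)
report = score_saturation(bridging, placed, n_native_local=len(local))
print(report.n_native_bridging, report.n_recaptured, report.per_native_nearest)
```

prints (one water placed, from a 12-point void):

```
[ 0.917 -1.     2.083] (1789, 2.38) (1785, 2.42) 12
1 1 [('HOH 1 S', 0.1179)]
```

i.e. the single predicted water oxygen sits 2.38 Å from a ligand oxygen and
2.42 Å from a protein hydroxyl — a genuine bridge — and lands 0.12 Å from the
pocket's native bridging water, well inside the 1.4 Å recapture criterion.
The decoy water (local, not bridging) is correctly left unmatched.

The same workflows are available from the shell:

```sh
bridgewater place    --pdb complex.pdb --ligand 4CD --params p.yaml --out waters.pdb
bridgewater natives  --pdb complex.pdb --ligand 4CD
bridgewater fixtures --n 20 --seed 1 --out bench/
bridgewater saturate --dataset bench/ --report report.tsv --summary summary.json
bridgewater optimize --dataset bench/ --trials 200 --seed 1 --out best.yaml --log trials.tsv
```

`place` writes a water-augmented PDB plus a TSV sidecar (coordinates and the
polar contacts justifying each water); `saturate` writes per-complex and
aggregate recapture statistics.

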