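# synthscreen

Hierarchical synthon-based virtual screening of reaction-defined
(make-on-demand) chemical spaces, with automatic, geometry-based selection of
docked fragment poses that are worth growing.

## The problem

Make-on-demand libraries are defined by reactions, not by explicit molecules:
each reaction contributes a Markush scaffold with 2–3 attachment points and a
synthon (reactant) list per point, so the number of products is the *product*
of the list sizes and quickly reaches billions. Docking every product is
infeasible; docking a representation that grows with the *sum* of the list
sizes is not. This package implements that hierarchy for people building or
studying reaction-space screening methods:

1. **Minimal enumeration library (MEL).** For every (reaction, attachment
   point, synthon) one fragment is built with that synthon attached and every
   other point capped by a minimal R-group — methyl for aliphatic chemistry,
   phenyl for aromatic — whose attachment carbon carries an isotope label
   (13/14) so it can be found again in a docked pose. Bridge-type 3-component
   reactions (terminal–bridge–terminal) contribute only their terminal
   synthons, methyl-capped at the future bridge junction.
2. **Dock the MEL** with any lower-is-better docking backend (a deterministic
   exhaustive rigid toy docker is built in, so everything runs on synthetic
   fixtures).
3. **Classify pose productivity by sphere growth.** From each labelled cap
   atom a chain of spheres is grown greedily inside the pocket: initial
   radius r₀ = 3.0 Å (methyl) or 3.5 Å (phenyl), then 2.0 Å spheres placed
   tangent to the previous one, directions drawn from a 5° spherical mesh
   (72 × 36 angles) restricted to a 60° half-angle cone around the growth
   axis, each centre keeping ≥ 2 Å clearance from pocket and non-cap ligand
   atoms, the feasible direction maximising the distance to the nearest
   pocket atom being taken. Growth ends on a steric dead end (*clash*) or
   after > 10 Å of travel outside the pocket envelope (*exit*). The
   **CapScore** counts in-pocket spheres; a pose is *productive* when some
   cap grows ≥ 2 of them. Ranking uses the merged score

       MergedScore = −DockScore + w·ln(1 + CapScore),   w = 1 by default.

4. **Enumerate and re-dock.** Ranked productive fragments are enumerated
   (once for 2-component chemistry, twice for 3-component, with the bridge
   synthon inserted in the first round) up to a product budget, and the
   products are re-docked; post-processing offers physicochemical windows,
   PAINS patterns and Tanimoto leader clustering.

Built-in evaluations reproduce the method's internal controls: in-place
heavy-atom RMSD between a fragment pose and its moiety in the enumerated
product (cap atoms excluded, no superposition; flips surface as RMSD > 3 Å),
and enrichment factors EF_T against a property-matched random sample of the
full space.

## Worked example

```python
from synthscreen import (LibrarySpec, PocketSpec, ScreenConfig, build_mel,
                         count_full_space, make_pocket, make_toy_library,
                         run_screen)

lib = make_toy_library(LibrarySpec(two_component=((6, 6),),
                                   three_component=(), seed=23))
pocket, _ = make_pocket(PocketSpec(kind="deadend", radius=4.5,
                                   length=14.0, spacing=1.5))
print("full space:", count_full_space(lib), "products")
print("MEL size:  ", len(build_mel(lib)), "fragments")

cfg = ScreenConfig(library=lib, pocket=pocket, target_enum_count=12,
                   top_final=10, grid_step=2.0, seed=4)
res = run_screen(cfg)
print("docked:    ", res.stats["n_docked_total"],
      f"(reduction {res.stats['reduction_factor']:.1f}x)")
print(res.final_table[["id", "dock_score", "rank"]].head(3).to_string(index=False))
```

prints

```
full space: 36 products
MEL size:   12 fragments
docked:     24 (reduction 1.5x)
                      id  dock_score  rank
R0:1:R0.p1.s1+2=R0.p2.s7      -400.0     1
R0:1:R0.p1.s1+2=R0.p2.s6      -385.0     2
R0:1:R0.p1.s0+2=R0.p2.s7      -366.0     3
```

The screen docked 12 MEL fragments plus 12 budgeted products instead of all
36 — at this miniature scale the saving is small, but the docked count grows
with Σ|synthon lists| + budget while the space grows with Π|synthon lists|
(the packaged default conditions represent 1 872 products with 120 docked
molecules, a 15.6× reduction; production-scale spaces reach >10⁴×). Final
ids read `reaction:point:synthon + point=synthon`, recording full provenance.

A CLI mirrors the library: `synthscreen run --config screen.yaml`,
`synthscreen mel`, `synthscreen capselect --receptor pocket.pdb --poses
poses.sdf --out caps.csv`, `synthscreen enumerate`, `synthscreen evaluate
--run DIR`, `synthscreen fixtures --kind cap_into_tunnel --out dir/`.

## Layout

```
src/synthscreen/
  chem_space.py   reaction space, MEL construction, provenance enumeration
  capselect.py    sphere-growth pose productivity (pocket/pose types, PDB IO)
  scoring.py      docking backend contract, toy rigid docker, MergedScore
  pipeline.py     screen orchestration, selection budgeting, postprocessing
  evaluation.py   RMSD reproducibility, enrichment factors, baseline sampling
  fixtures.py     synthetic pockets, toy libraries, scripted poses
  poseio.py       pose SDF round trip
  cli.py          command-line interface
docs/methods.md   model, parameters, numerical choices, limitations
```
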