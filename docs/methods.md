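# Methods

## The hierarchical screening model

A reaction-defined chemical space is a set of scaffolds, each with `n`
attachment points and a synthon list per point; the product space is the
union over scaffolds of the Cartesian products of the lists. The package's
working assumption — the assumption of all synthon-hierarchical screening —
is that the binding pose and score of a *capped fragment* predict the pose
and score of the molecules enumerated from it: a fragment that docks well
and has room to grow at its capped points is likely to spawn well-scoring
full molecules in a similar pose. Both halves of that assumption are
measurable inside the package (enrichment factors for the scoring half,
in-place RMSD reproducibility for the pose half), which is why the
evaluation module is part of the core rather than an afterthought.

### MEL construction

One fragment per (reaction, point, synthon): the synthon attached at its
point, every other point capped. Cap groups are fixed by the reaction
chemistry declared per point: methyl for aliphatic, phenyl for aromatic.
The cap attachment carbon carries isotope 13 (methyl) or 14 (phenyl ipso)
*and* structural bookkeeping (atom properties naming the point label, cap
type and replaced marker), so isotope handling in any downstream toolkit is
not load-bearing. Fragments are deduplicated per reaction by canonical
isotope-labelled SMILES; symmetric scaffolds therefore contribute fewer
fragments, and conservation is preserved because a dropped symmetric
fragment's products are reachable from the retained ones. The MEL covers
*every* attachment point of every scaffold — which point anchors the
hierarchy is left to the data, since ranking decides which fragments grow.

Bridge-type 3-component reactions (two terminal synthons joined through a
two-marker bridge synthon, no shared core) contribute only terminal
synthons, methyl-capped at the bridge junction: bridge synthons lack
pharmacophores and dock unreliably on their own. The bridge is inserted in
the first enumeration round, its far side methyl-capped; the second round
replaces that cap with the remaining terminal synthons.

Every heavy atom carries a provenance tag (`core:i`, `syn:<point>:<id>:i`,
`cap:<label>:i`). Tags survive enumeration, so an atom of a MEL fragment is
found in any descendant by tag equality — this is what the RMSD machinery
and the conservation tests key on.

### Sphere-growth productivity (CapSelect-style scoring)

Distances in Å; defaults frozen in `CapSelectParams`:

| parameter | default | meaning |
|---|---|---|
| `init_radius_methyl` / `init_radius_phenyl` | 3.0 / 3.5 | initial sphere radius at the labelled cap carbon, sized to the cap group |
| `sphere_radius` | 2.0 | grown-sphere radius, matching a C(sp³)–C(sp³) step plus surroundings |
| `clearance` | 2.0 | minimum centre-to-atom distance to pocket and non-cap ligand atoms |
| `cone_half_angle_deg` | 60 | growth cone (120° full angle) around the current axis |
| mesh | 72 × 36 at 5° | spherical direction grid (2 521 unique directions over the full sphere) |
| `d_solvent` | 8.0 | envelope: a point is "in the pocket" if its nearest pocket atom is within this distance |
| `exit_path_length` | 10.0 | outside-envelope travel before growth stops as a solvent exit |
| `n_min` | 2 | in-pocket spheres needed for a productive chain |
| `max_spheres` | 60 | hard iteration cap (safety net; archetype pockets terminate naturally) |

Growth is greedy and deterministic: steps are tangent (step length = sum of
adjacent radii), the first axis is the anchor→cap bond vector and thereafter
the vector between the two previous centres, and among feasible mesh
directions the one maximising the distance to the nearest pocket atom wins,
ties broken by lowest (θ, φ) grid index. The initial cap sphere sits on real
atoms and is exempt from the clearance rule. "Non-cap ligand atoms" excludes
*all* cap groups of the pose, not only the one being grown — caps are
placeholders that will vanish on enumeration.

The exit rule accumulates path length while the chain is outside the
envelope and resets on re-entry, so long in-pocket channels are allowed
while solvent excursions are stopped. **CapScore counts only in-pocket
spheres**: spheres accepted during an excursion stay in the chain (the
geometry is kept for inspection) but do not count as growth capacity. This
is what makes a cap pointing out of the pocket mouth unproductive — it can
always place spheres in solvent, but none of them are in the pocket.
Consequently `len(centers) − 1 ≥ n_grown`, with equality for chains that
never leave the envelope. A pose with several caps takes the best chain's
score and is productive if any chain is.

The direction grid needs an azimuthal reference frame; the convention is
deterministic (e₁ = normalize(ref × axis) with ref = ẑ, or x̂ when
|axis·ẑ| > 0.9) and is part of the algorithm definition: the test oracle
re-implements the same convention independently and the greedy choice is
checked against an exhaustive scan on seeded random pockets.

### Ranking, selection, iteration

MergedScore = −dock + w·ln(1 + CapScore) with w = 1 (higher is better; the
sign flip confines the lower-is-better docking convention to one place).
The exact published weighting of the two terms is not public; this is the
minimal weighted-logarithmic form consistent with descending-MergedScore
ranking, and w is configurable. `capselect` ranking drops unproductive
fragments; `greedy` ranking (docking score only) is retained as the
comparison baseline. Selection walks the ranked list accumulating each
fragment's eventual spawn (product of remaining list sizes) and stops at
the first fragment reaching the budget, so the cumulative total can
overshoot by at most one fragment's spawn.

The selection/enumeration cycle repeats while partially enumerated
intermediates remain (once for 2-component, twice for 3-component
chemistry), with growth-aware ranking applied at every round by default;
`capselect_first_round=False` reproduces the benchmark variant in which the
first selection is greedy. One pose (best docking score) per fragment feeds
the growth analysis.

### Evaluations

*Pose RMSD* is computed in place — both poses share the receptor frame and
the question is placement, not shape, so no superposition is performed —
over heavy atoms matched by provenance tag, excluding the earlier
fragment's cap groups. Quartiles use linear interpolation; the reproducible
fraction uses strict `RMSD < 3 Å`. A flipped product shows up as a value
far above 3 Å.

*Enrichment factor* EF_T: cutoff at the T-th best test score, hit fractions
compared against a property-matched random sample of the full space of the
same size. Property matching is stratified on heavy-atom count (bin width
2) — the matched property is not published, and heavy-atom count is the
property the toy generator actually varies; molecular-weight binning would
be an easy substitution. A baseline with zero hits yields a finite lower
bound flagged `censored` rather than an infinite EF. EF is exactly
invariant under strictly monotone transforms of all scores.

## The toy docker

An exhaustive rigid-body search: translations on a lattice anchored to the
pocket bounding box (padding 2 Å), orientations the 24 octahedral proper
rotations about the ligand centroid, score = 10·(pairs < 2.5 Å) − (pairs in
[2.5, 4.5] Å), ties broken by (score, grid index, orientation index). It is
deterministic and backend-shaped like a production engine (poses with
scores, lower is better) but models no electrostatics, hydrogen bonding,
conformational flexibility or desolvation. Because the grid is anchored to
the pocket bounding box, scores are exactly invariant under joint
translations and axis-permutation rotations (which move the lattice rigidly
with the system) but only approximately under arbitrary rotations; the
invariance test uses the lattice-compatible transforms.

## Synthetic study conditions, and what the tests do not show

The fixtures module generates everything from specs and seeds: pseudo-atom
pockets (open tunnel, dead-end tunnel, shallow slab, shell, half-space —
the binding-site archetypes that exercise the growth rules), toy reaction
libraries (amide/ester/urea/sulfonamide cores, a vocabulary of small
substituents, two-marker bridge synthons), and scripted poses with recorded
expected growth outcomes. Wall atoms are all carbon — the growth rules are
element-blind — and walls are slabs a few lattice layers thick so a 4–5 Å
growth step cannot jump between lattice points of a single plane, standing
in for protein bulk.

The packaged default screen conditions: one 2-component reaction (12 × 12)
plus one 3-component reaction (12 × 12 × 12), a 1 872-product space
represented by 60 MEL fragments after deduplication; a dead-end tunnel
pocket (radius 4.5 Å, length 14 Å, wall spacing 1.5 Å); toy-docker grid
step 2.0 Å with all 24 orientations; enumeration budget 40 products per
round; final set 25. These sizes are the desk-scale analogue of
production-scale budgets (10⁶ enumerations, 10⁴ finals) and keep a full
run at about a minute on one CPU.

Passing tests on these conditions show that the *machinery* is correct —
conservation of the combinatorial space, exact oracle agreement of the
greedy growth, deterministic end-to-end accounting, correct classification
of unambiguous pocket geometries. They do not show that the toy docker's
scores or poses resemble a physics-based engine's: in particular, pose
reproducibility (RMSD between fragment and product poses) under the toy
docker is weak and seed-dependent, because a contact-count score over a
coarse lattice anchors small fragments poorly. The acceptance script
reports whatever the run produces; the RMSD summary characterises the toy
backend, not the method's ceiling.

## Numerical choices and degenerate inputs

- Clash test is centre-to-atom distance < 2.0 Å, read literally; a
  surface-clearance alternative (radius + van der Waals) is deliberately
  not used, for reproducibility.
- Steps are tangent (step = r_i + r_{i+1}); "non-overlapping" could also be
  read as merely disjoint with free step length, but no free step value is
  published and tangency is the parameter-free reading.
- Greedy tie-break: first maximum in θ-major, φ-minor grid order.
- Determinism everywhere: seeded conformer embedding (per-molecule seed =
  CRC32 of the id XOR the run seed, masked to 31 bits), sorted iteration
  orders, stable sorts with id tie-breaks.
- Degenerate inputs fail loudly: empty synthon lists (degenerate reaction)
  on counting, zero growth axis, empty pockets, non-finite coordinates,
  empty RMSD lists, T < 1. Chemically invalid enumeration products are
  skipped with a logged warning and counted, not fatal.
- Multi-conformer (4D-style) pockets are unioned atom sets — conservative
  for both clash and envelope tests.
- Quartiles: linear interpolation, to make printed summaries reproducible
  across implementations.

## Known limitations

- The toy docker is rigid-body with a single embedded conformer; no
  conformational sampling, no physics. It exists to exercise the pipeline
  contract deterministically.
- Four-component reactions and bridge reactions with a shared Markush core
  are not supported.
- One pose per fragment feeds the growth analysis; multi-pose productivity
  is out of scope.
- The sphere-growth iteration cap (`max_spheres`, 60) reports `exit` if
  ever reached; the packaged pocket archetypes terminate naturally well
  below it, but an unbounded synthetic channel would be truncated.
- PAINS filtering applies a user-supplied SMARTS list; no curated pattern
  set ships with the package.
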