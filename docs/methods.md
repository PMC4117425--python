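# Methods

This note documents the models and numerical conventions behind
`flexsite`, the choices made where the design was genuinely open, and what
the synthetic-fixture validation does and does not demonstrate.

## Structure preparation

Input is PDB format (first MODEL, author chain ids). Waters are removed;
het entities with molecular weight ≤ 1000 Da are removed and logged (the
registry feeds the ligand-pocket overlap test), except a fixed keep-list of
tight-binding cofactors (HEM, MHM, HEV, VER, SRM, HEO, HEB, HEC, HDM, HDD,
DDH, ZN, MG); heavier het entities are retained and flagged as oversized.
Molecular weights come from the chemical component dictionary (implicit
hydrogens included) with a sum-of-present-atoms fallback for unknown codes.

Hydrogens are placed geometrically by local-frame transfer from ideal
residue templates (the template hydrogen is carried through a least-squares
superposition of its bonded heavy atom's covalent neighbourhood onto the
actual coordinates), with fixed default protonation states: Asp/Glu
deprotonated, Lys/Arg protonated, His neutral. Missing side-chain atoms are
rebuilt from the backbone-superposed template and set to the residue's
most common rotamer. This replaces pKa-based protonation/flip optimization;
restrained-minimization-style refinements are known to have little effect
on druggability scores, and the flexibility stage re-samples rotamers
anyway. Chains in which more than half of the residues carry only a CA atom
are rejected (no side chains to work with).

In monomer mode a het entity belongs to the chain owning its nearest
protein heavy atom, ties broken by chain-id order — a convention; deposited
files do not record this assignment.

## Site-point grid

A regular grid (default spacing 0.35 Å, 8 Å margin) carries four per-point
fields:

* **Occupancy** — inside the receptor van der Waals envelope (standard
  radii; C 1.70, N 1.55, O 1.52 Å, …).
* **Probe vdW energy** — a 6-12 Lennard-Jones sum over heavy atoms within
  8 Å for a neutral aliphatic-carbon-like united-atom probe. The pair
  parameters are deliberately uniform across organic elements
  (r_min = 5.0 Å, well depth 0.08 kcal/mol with carbon): the probe field is
  meant to measure pocket *shape*; chemical character enters through the
  separate polarity fields. With these parameters the summed attraction
  above an extended flat wall peaks near −0.9 kcal/mol — just below the
  `maxvdw` = 1.0 threshold — while points ringed by cavity walls
  accumulate several-fold stronger attraction, so the energy test is
  selective for concave geometry. A deeper or shorter-range probe either
  admits flat-surface sheets (whose enclosure sits exactly at the 0.4
  threshold) or excludes sub-100 Å³ cavities entirely; the chosen
  parameters are the calibrated middle. Fluorine keeps a shorter, shallower
  pair (4.15 Å / 0.066 kcal/mol; small atom).
* **Enclosure** — the fraction of 110 deterministic spherical-Fibonacci
  rays whose first entry into the envelope lies within `maxdist` = 10 Å,
  found by marching the occupancy grid at 0.25 Å steps (a ray leaving the
  grid cannot hit). An exact analytic ray–sphere version
  (`enclosure_at_points`) exists for arbitrary points; on fixture mouth
  centres the two agree with a 10⁶-random-ray analytic oracle to < 0.01.
* **Phobic/philic potentials** — kernel sums Σ (1 − r/6)² over apolar
  atoms (carbons with no covalent N/O neighbour in the component template,
  plus halogens) and polar atoms (N, O; charged side-chain atoms doubly
  weighted; S only outside Cys/Met) within 6 Å. `modphobic = 0` means the
  raw phobic sum with no openness attenuation. Both fields are normalized
  so that the site-point mean over a packaged 300 Å³ hemispherical
  reference pocket equals 1.0 — apolar-lined for the phobic scale,
  polar-lined for the philic scale (a single hydrophobic reference cannot
  calibrate the philic field, whose value there is zero).

A **site point** is outside the envelope with enclosure ≥ 0.4 and probe
energy ≤ −1.0 kcal/mol. Enclosure is evaluated only where the energy test
passes (the only points that can qualify), which keeps the fine grid
tractable.

## Sites, volume, ranking

Site points need `nthresh` = 7 neighbours within 1.76 Å (applied once, not
iterated), are clustered by single linkage at `dthresh` = 5 Å — "join two
groups when their closest points are nearer than dthresh" is exactly
single-linkage/connected components — and clusters under `mingroup` = 7
points are dropped. The top five sites by point count are ranked (ties:
larger volume, then lexicographic centroid).

**Volume.** Site points occupy only the attractive core of a pocket,
offset from the walls by roughly the probe contact distance, so counting
member cells alone underestimates cavity volume several-fold. Site volume
is therefore the *enclosed void*: grid cells outside the envelope, within
`volume_reach` = 2.75 Å of a member point (the probe zero-crossing minus
the carbon radius — the thickness of the wall-adjacent dead shell), and
themselves ≥ 0.4 enclosed (evaluated on demand). The enclosure requirement
stops the measure from spilling past the mouth or onto rough outer
surface. On closed spherical test cavities of 2.85–6 Å radius the measure
lands within 6–11% of the analytic volume; pockets that open into wide
bowls read systematically larger than their half-ball volume because the
detector legitimately includes the partially-enclosed region above the
mouth. Degenerate calls without grid context count member cells literally.
Sites above 800 Å³ are flagged oversized; they are reported but the
decision layer does not advance them.

## Dscore and Dscore+

```
Dscore  = w_size·√n + w_enclosure·e − w_philic·min(p, cap)
Dscore+ = Dscore + 0.3·h
```

with defaults w_size = 0.094, w_enclosure = 0.60, w_philic = 0.324,
cap = 1.0 — the weight set published for this score family, which assumes
roughly one site point per ~2.3 Å³ of pocket. Because the fine 0.35 Å grid
carries ~23× that density, the size term uses the grid-independent
effective count n = V / 2.3 Å³ (the raw member count is kept for the
`mingroup` contract and reporting). Reported scores round half-away-from-
zero to one decimal, and all thresholds are applied to reported values.

On the dense pseudo-atom fixtures the normalized *h* of small buried
cavities can reach several units (every site point is close to many wall
atoms); this inflates fixture Dscore+ relative to real proteins and is one
reason the decision thresholds, not the absolute fixture scores, are the
validation target.

## Two-stage induced-fit protocol

Sites with reported Dscore+ > 1.3 advance. The anchor is the site-point
centroid and all searching happens within a 25 Å box around it.

*Docking* is an exhaustive rigid-body search: translations on a 1 Å
lattice of the site points × 60 seeded quasi-uniform rotations, scored by
an internal pose energy — clamped attractive Lennard-Jones sum (repulsion
is handled separately), a hydrophobic-contact bonus (−0.05 kcal/mol per
apolar C–C pair within 4.5 Å), and a soft quadratic clash penalty beyond
0.6 Å of vdW overlap. Only pose ordering matters; any net-favourable pose
(energy < 0) is admitted. Naphthalene (rigid, planar) keeps its two best
poses with centroids ≥ 2 Å apart.

*Repacking*: residues with a heavy atom within 5 Å of the probe are
greedily re-assigned, worst clash first, two sweeps, the candidate set
being a compact backbone-independent rotamer table (most common rotamers
per residue type, ±30° chi1 variants) built on ideal-template chi
rotations. The objective is soft clash energy (vs probe and receptor) plus
a small preference penalty proportional to rotamer rank — and the current
conformation pays its own rank penalty, which is what lets a strained
buried rotamer relax outward once a probe perturbs its neighbourhood. If a
residue's best rotamer still clashes hard, an optional light backbone
relaxation rigidly shifts its ±2-residue window down the clash gradient
(≤ 50 × 0.05 Å steps), capped at 1.5 Å — the light-flexibility contract;
models exceeding the cap, or with unresolved hard clashes, are discarded.

*Stage 2*: on each repacked variant the pocket is re-detected (its site
points now include newly exposed regions; the union with the original
points, plus 2/4 Å outward-shifted copies of the lattice, lets the 363 Da
TSN perch across a small mouth with substituents in solvent). The TSN
rigid core is searched admitting all poses, its four substituent torsions
are then refined greedily at 60° steps (two sweeps), and only refined
poses below the ceiling survive. Each surviving pose is repacked again.
Models are collected to at least ten when the search yields them, and the
four top models — selected round-robin across the naphthalene branches so
that every induced-fit branch contributes — are re-scored by running the
full detection + descriptor stack in the 25 Å box (probe removed). The
per-site flexible result is the maximum re-scored Dscore+ over the scored
models with that model's volume (ties favour the larger volume); whether
to aggregate by maximum or mean is not settled anywhere, and maximum is
this package's declared convention.

Both probes are built at runtime from connectivity (naphthalene;
2,6-disubstituted naphthalene with ethyl, propyl and two cyclohexyl groups,
MW 362.6) with a fixed embedding seed; the exact TSN regiochemistry is a
convention, and SDF export is provided.

## Decision layer

* advance: reported rigid Dscore+ > 1.3 (strict);
* druggable after flexibility: flexible Dscore+ ≥ 1.7 and volume in
  [160, 800] Å³, both ends inclusive;
* cryptic druggable: additionally rigid volume ≤ 100 Å³, rigid enclosure
  ≤ 96% (a strict-mode flag switches to <, the two appear interchangeably
  in the source criteria), and ≥ 100 residues on the owning chain;
* oversized (> 800 Å³ rigid) and not-advanced sites are labelled as such;
  a site whose rigid values qualify fully is also flagged rigid-druggable.

Interface annotation: a pocket is a PPI-interface pocket when any TSN pose
atom lies within 2.0 Å of another protein chain (hydrogens included), and
a ligand pocket when its site cells overlap a removed ligand's vdW
envelope by > 0 Å³.

## Synthetic fixtures

Fixtures are dense pseudo-atom walls (~1.8 Å cubic/shell packing, written
as legal PDB ATOM records under the otherwise-unused residue code ZQX) so
that every pipeline stage, including file I/O, runs unmodified:

* `spherical_cavity` — closed hollow shell; each inner-shell atom sits at
  r + its own vdW radius, so the void is the designed sphere for any
  lining composition. These are the volume oracles.
* `hemispherical_pocket` / `reference_pocket` — half-ball pockets in a
  slab; the mouth-centre enclosure oracles and the field-normalization
  anchor.
* `slab` — featureless block; must yield zero sites.
* `two_cavity` — two pockets; ranking and separation checks.
* `deep_pocket` — fluorine-lined spherical pocket opening at the surface
  of a globular lattice ball; no repackable residues, so flexibility must
  not change it. A sink parameter deepens the pocket for
  burial-monotonicity families.
* `gated_cavity` — the cryptic case: the same globular ball with a
  fluorine-lined surface pocket (~79 Å³ detected) whose adjacent buried
  lobe is filled by a real tryptophan side chain built in a
  low-preference rotamer; the preferred rotamer is the unique clash-free
  alternative and swings the side chain into a snug outer-flank notch.
  Probe-triggered repacking therefore opens the lobe deterministically,
  and the merged pocket re-detects at ~310 Å³. Ground-truth volumes come
  from direct integration of the designed void regions against the
  all-atom envelope — independent of the detection pipeline. The fixture
  also carries a shallow surface groove (the open rotamer's clearance)
  that detects as a separate low-scoring site; it never passes the
  flexible gate.

The fluorine lining of carved voids is a deliberate construction: its
smaller radius and shorter-range probe minimum keep sub-100 Å³ cavities
energetically favourable (with plain carbon walls the favourable window
cannot fit inside a 100 Å³ void at all), and as a hydrophobic,
non-H-bonding element it scores like a fluorocarbon surface — phobic, not
philic. Convex ball geometry is used for the gated and deep-pocket kinds
because extended flat surfaces place shallow halo points exactly at the
0.4 enclosure threshold.

**What fixture validation shows — and does not.** Passing fixtures shows
the geometric machinery (fields, clustering, volumes, rotamer mechanics,
gating logic) is correct against independent oracles and that the
end-to-end cryptic mechanism behaves as designed across seeds. Fixtures do
not emulate real protein chemistry: uniform dense carbon walls inflate
contact scores, there are no backbone irregularities, waters, or partial
occupancies, and the published per-structure scores in the validation
tables are consumed as printed inputs, not recomputed. Claims about real
PDB structures rest on the printed-table statistics, not on the fixtures.

## Validation statistics

Per-target Variation is (max − min)/mean of a target's scores across its
crystal structures, in percent, rounded half-away-from-zero; the
flexibility column uses the published footnote values for the two targets
scored below the rigid gate. Summary spread uses the n−1 sample standard
deviation of the rounded per-target values — the convention that
reproduces both printed summary pairs (13/10 flexibility, 21/94 docking).
The FP/FN rates call a row positive when its flexible score and volume
meet the druggable criteria, with not-applicable rows negative; on the
27-row set this yields 12% / 0%.

## Problem sizes and determinism

Default problem sizes (110 rays, 60 orientations, 0.35 Å grids, fixture
balls of ~400 atoms, a 12-sphere volume sweep) were chosen so the full
test suite and the acceptance script each complete in minutes on a single
CPU while leaving every acceptance margin wide. All randomness (rotation
sets, fixture lining assignment, oracle rays) flows from explicit seeds;
two runs with the same seed produce byte-identical reports, and the
cryptic end-to-end outcome is stable across seeds by construction, not by
seed choice.

## Known limitations

* The pose energy is an internal ordering score, not a physical binding
  energy; the admission ceiling (0) is the only absolute use of its scale.
* Volume for wide-mouthed bowls includes the partially-enclosed halo above
  the mouth; volumes are comparable within this package but not calibrated
  against other cavity-volume definitions (volume algorithms disagree
  notoriously; the drug-like range would need re-derivation for any other
  definition).
* Backbone flexibility is a rigid window shift, a coarse stand-in for
  loop/helix remodelling; it is capped at 1.5 Å and off the critical path
  for the fixture suite.
* The rotamer table is compact (3–5 wells per residue, chi1 sub-sampling);
  fine side-chain strain is not modelled.
* Scores on dense pseudo-atom fixtures are systematically higher than on
  real proteins (see Dscore section); fixture thresholds are meaningful,
  absolute fixture scores are not.
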