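# Methods

## Scope and design

`pharmscreen` is a ligand-level pharmacophore screening pipeline. It covers
model representation and serialization, ligand-based model construction by
feature merging, feature perception, geometric matching, dataset curation,
union-of-models screening, and enrichment validation. Structure-based model
*derivation* (parsing protein–ligand complexes and perceiving interactions)
is out of scope: structure-based models enter the pipeline as data, through
the JSON schema, carrying their PDB id and resolution as provenance.

## Feature perception

Perception operates on a single conformer with explicit hydrogens (added
before embedding; SDF input may carry either convention).

* **HBD** — one feature per donor heavy atom matching `[#7;!H0]` or
  `[#8;!H0]` (neutral or cationic N), placed on the heavy atom. Multiple
  hydrogens collapse to one feature whose direction is the mean N/O→H unit
  vector; this mirrors sphere-on-heavy-atom model rendering. The direction
  is omitted when no hydrogen has coordinates.
* **HBA** — acceptor heavy atoms: pyridine-type aromatic N, imine N, amines
  excluding amide/sulfonamide N, ether/hydroxyl O, carbonyl-type O; nitro
  oxygens and pyrrole-type aromatic N are excluded. The direction
  approximates the lone-pair bisector: the unit vector from the mean of the
  bonded neighbours through the acceptor atom.
* **AI** — each 5- or 6-membered aromatic ring contributes one feature at
  the ring centroid with the unit normal of the least-squares ring plane
  (smallest right singular vector of the centered ring coordinates). Ring
  normals are sign-ambiguous; the stored sign is fixed deterministically and
  matching treats them as axes.
* **HC** — each maximal connected cluster of ≥ 3 contiguous low-polarity
  atoms (C, S, F, Cl, Br, I, with carbons bonded to N or O excluded)
  contributes one feature at the cluster centroid, no direction.

The SMARTS table is configuration (`PerceptionRules`); the defaults follow
common pharmacophore-tool semantics and are pinned by probe-molecule tests
(phenol's hydroxyl is both donor and acceptor; acetamide's N donates but
does not accept; nitro groups contribute nothing).

## Matching

Matching is rigid: conformational flexibility is handled solely by the
conformer ensemble, and each conformer is fitted as a rigid body.

The correspondence search enumerates injective, kind-compatible assignments
of model features to ligand features depth-first. A candidate pair (i→a)
extending a partial assignment containing (j→b) is pruned unless
|d_model(i,j) − d_ligand(a,b)| ≤ rᵢ + rⱼ — a necessary condition for both
residuals to land inside their spheres, so pruning is lossless; a
brute-force enumeration test (120 random instances, fit done independently
through `scipy.spatial.transform.Rotation.align_vectors`) pins the
equivalence.

Each surviving assignment is scored by the Kabsch least-squares rigid
superposition of the assigned ligand positions onto the model centers,
restricted to proper rotations (det R = +1) so chirality is preserved.
Acceptance requires every residual within its sphere, every direction pair
(where both sides carry one) within the cone half-angle (default 34°; AI
axes compared as min(θ, 180° − θ)), and no transformed heavy atom strictly
inside an exclusion volume (boundary points do not clash). Assignments with
fewer than three matched features are rejected as rigidly underdetermined;
`max_omitted` (default 0 — all model features required) controls partial
matching. For collinear correspondences the optimal rotation is unique only
up to a half-turn about the line axis; both proper solutions are evaluated
and the better acceptable one kept.

The fit score is the mean of (1 − residual/radius) over matched features —
1.0 for a perfect overlay, 0 at the tolerance boundary. Only binary hits
enter the headline metrics, so any monotone score would do; this one is
bounded and interpretable, and it supplies the ROC ranking (non-matching
compounds keep the score of their best failed assignment). Ties break to
the lexicographically smallest correspondence, and across conformers to the
lowest conformer index, making results deterministic.

## Conformer generation

Ensembles come from RDKit's ETKDGv3 distance-geometry embedding,
single-threaded with a fixed seed, so identical seeds give bitwise-identical
coordinates. Defaults: up to 200 conformers for training sets and 400 for
screening libraries, RMSD pruning threshold 0.25 Å. The pruning threshold
is configuration, not a fidelity claim about any particular commercial
ensemble generator: downstream stages rely only on the contract (count ≤
max, seed-deterministic, no heavy-atom pair closer than 0.8 Å).

## Curation

Actives: IC50 ≤ 1000 nM (inclusive). Inactives: IC50 > 40,000 nM for JAK1,
> 50,000 nM for JAK2/JAK3/TYK2 (strict). The intermediate band is excluded.
Multiple measurements per compound are reconciled by the geometric mean of
IC50 before thresholding — an explicit deterministic rule standing in for
per-compound manual judgment; the single-measurement path is exact so
boundary values classify exactly. Decoys are attached as externally
supplied id lists (property-matched decoy *generation* against a live decoy
service is out of scope) and must stay disjoint from measured compounds.

## Validation statistics

With the census nAC/nIA/nDC and hits split into TP (actives) and FP
(inactives + decoys): sensitivity = TP/nAC; YoA = TP/(TP+FP);
EF = YoA/(nAC/N); accuracy = (TP+TN)/N with TN = nIA + nDC − FP. Published
screening summaries are ambiguous about the specificity denominator, and no
single formula reproduces all printed values, so two explicit variants are
reported — TN/(nIA+nDC) and 1 − FP_ia/nIA — and specificity is excluded
from the built-in census check. The same check reports, but does not
assert, the one printed sensitivity (JAK3, 0.86) that disagrees with its
own counts (116/129 = 0.90). Zero-hit screens leave YoA and EF undefined
(flagged, not zero-filled). The EF filter drops models with EF strictly
below 4; undefined EF drops with reason "no hits".

ROC curves sweep a descending score threshold with tied scores entering
together; AUC by the trapezoid rule equals the Mann–Whitney statistic with
ties counted ½ (cross-checked against scikit-learn in tests).

## Synthetic benchmarks

`make_planted_benchmark` emulates the active/decoy structure of a screening
database at the feature-set level, bypassing chemistry so matching and
validation are tested independently of perception (a separate
real-molecule path — models built verbatim from perceived features of
embedded probe molecules — covers perception→matching end to end).

Actives are the model's own feature layout with isotropic Gaussian
positional noise (sd = `jitter_sd`) and small direction jitter (rotation
about a random axis, angle ~ N(0, 5°)), placed in a random rigid frame;
dummy heavy atoms sit at the feature positions. Decoys violate at least one
constraint by construction — kind permutation, one feature displaced past
2× its radius, or uniform points in the padded model bounding box — and
each candidate is *verified* to fail the matcher at generation tolerances,
with a bounded retry count (a model that cannot be falsified raises rather
than silently producing matchable "decoys"). Defaults (20 actives, 180
decoys, jitter 0) give the closed-form outcome sensitivity = YoA = AUC = 1
and EF = inverse prevalence = 10, which the end-to-end tests assert; the
jitter sweep {0, 1×, 2× radius} at 200 actives checks that sensitivity
degrades monotonically. What these benchmarks do **not** emulate: real
chemical feature distributions, property-matched decoy difficulty, or
activity cliffs — a pass demonstrates pipeline correctness, not prospective
screening power.

`make_activity_records` samples IC50 log-uniformly inside the three
threshold bands (active 1–1000 nM; intermediate up to the cutoff; inactive
up to 100× the cutoff) so labeling recovers the requested counts exactly.

## Exemplar models

The eight shipped models (one structure-based + one ligand-based per
target) match published exemplar compositions in feature and
exclusion-volume counts (e.g. JAK1_SB1: 1 HBD anchored Glu957, 1 HBA
anchored Leu959, 2 HC, 66 Xvols; JAK1_LB1: 3 HBA, 2 AI, 47 Xvols). Their
geometries are authored synthetically by `scripts/make_exemplar_models.py`:
features on a 3 Å ring with a rising z-offset (low symmetry, never
collinear), donors/acceptors pointing outward, Xvols on a 7 Å
Fibonacci-sphere shell verified to clear every feature sphere by > 0.5 Å
so planted actives never clash. They exercise the schema and pipeline; they
are not reproductions of any screening tool's optimized models, whose
coordinates are not published. Residue anchors ("Glu957") are annotation
only and never affect matching.

## Defaults and units

All coordinates and radii in Å, angles in degrees, IC50 in nM. Feature
tolerance radius 1.5 Å, Xvol radius 1.0 Å, cone half-angle 34° — common
pharmacophore-tool magnitudes, configurable everywhere; published sources
for this workflow state that tolerances were fine-tuned per model without
giving values, so tolerances are configuration, not constants. One global
seed; stage-local seeds derive by CRC-32 hashing of (seed, stage name),
keeping stages independently reproducible.

## Known limitations

* No flexible alignment: ligand-based model construction requires
  pre-aligned inputs (e.g. each ligand matched to a seed model from the
  first ligand).
* Residue bonding points are metadata, not a matched feature class.
* The correspondence search is exponential in the worst case; models of
  ≤ 10 features with kind filtering and distance pruning are fast in
  practice, but adversarial inputs with many same-kind features are not.
* Feature perception is rule-based; tautomers and charge states are taken
  as given, not enumerated.
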