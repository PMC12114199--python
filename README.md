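# pharmscreen

Pharmacophore modeling and decoy-aware virtual screening for JAK-family
kinase inhibitors (JAK1, JAK2, JAK3, TYK2).

Janus kinases regulate cytokine signalling and immune response; small
molecules that occupy their ATP pocket — including, potentially, pesticides
and other environmental chemicals — can act as unintended inhibitors.
`pharmscreen` implements the computational side of finding such compounds:
declarative 3D pharmacophore models, ligand feature perception, geometric
matching with exclusion volumes, IC50-threshold dataset curation, and
enrichment-style validation against decoy-augmented databases. It is aimed
at cheminformaticians who want a transparent, scriptable, fully testable
version of this workflow rather than a GUI tool.

## The model

A pharmacophore model is a set of typed features — hydrogen-bond donors
(HBD) and acceptors (HBA), hydrophobic contacts (HC), aromatic interactions
(AI) — each a tolerance sphere of radius *r* in 3D, optionally with a
direction cone of half-angle α, plus exclusion volumes (Xvols)
approximating receptor bulk. A conformer *satisfies* a model when an
injective, kind-compatible assignment of model features to perceived ligand
features exists such that, after the least-squares rigid superposition
(Kabsch, proper rotations only) of the assigned ligand positions onto the
model centers:

* every residual ‖x̂ᵢ − cᵢ‖ ≤ rᵢ,
* every direction pair subtends at most αᵢ,
* no transformed heavy atom lies strictly inside any Xvol.

Screening a database of nAC actives, nIA inactives and nDC decoys
(total N = nAC + nIA + nDC) yields TP retrieved actives and FP
inactive-or-decoy hits, from which

```
sensitivity = TP / nAC          YoA = TP / (TP + FP)
accuracy    = (TP + TN) / N     EF  = YoA / (nAC / N)
```

EF (enrichment factor) is the fold improvement of the hit list over random
picking; models with EF < 4 are filtered out. ROC curves rank compounds by
fit score; AUC is computed by the trapezoid rule with ties counted ½.

## Worked example

Eight exemplar models (one structure-based and one ligand-based per target)
ship with the package. Generate a planted synthetic benchmark for the JAK1
structure-based exemplar — 20 actives realizing the model exactly, 180
decoys with one feature displaced past twice its tolerance radius — then
screen and validate in one step:

```
$ pharmscreen simulate --model jak1_sb1 --n-act 20 --n-dec 180 \
      --jitter 0 --seed 5 --out bench.json
sensitivity 1.00  ef 10.00
```

All 20 actives are recovered (sensitivity 1.00) with no false positives, so
YoA = 1 and EF equals the inverse prevalence 200/20 = 10.00; `bench.json`
also records AUC 1.0. Raising `--jitter` toward the 1.5 Å tolerance radius
degrades sensitivity, which is how the benchmark probes model
restrictiveness.

The built-in census check recomputes the summary statistics of the combined
per-target model sets from their published hit counts:

```
$ pharmscreen validate --table1
JAK1: accuracy 0.97  yoa 0.55  ef 17.76  sensitivity 0.90
JAK2: accuracy 0.96  yoa 0.65  ef 10.80  sensitivity 0.90
JAK3: accuracy 0.93  yoa 0.28  ef 10.24  sensitivity 0.90
TYK2: accuracy 0.94  yoa 0.28  ef 11.84  sensitivity 0.91
PASS
```

Other subcommands: `conformers` (SMILES → seeded 3D SDF ensembles),
`curate` (activity TSV → labeled dataset), `models validate|summarize`,
`match` / `screen` (SDF library vs. model collection, union-of-models hit
semantics, optional cross-reference against an identifier list).

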