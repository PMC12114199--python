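"""Author the eight exemplar pharmacophore models shipped as package data.

One structure-based and one ligand-based model per JAK subtype, with feature
and exclusion-volume compositions mirroring published exemplar models
(JAK1_SB1: 1 HBD + 1 HBA + 2 HC, 66 Xvols; JAK1_LB1: 3 HBA + 2 AI, 47 Xvols;
and so on).  The geometries are synthetic: features sit on a low-symmetry
ring layout and exclusion volumes on a Fibonacci-sphere shell well clear of
the feature spheres, so that planted actives never clash.  Run from the
repository root:

    python scripts/make_exemplar_models.py
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from pharmscreen.model import (
    ExclusionVolume,
    ModelCollection,
    ModelFeature,
    ModelOrigin,
    PharmacophoreModel,
    save_models,
)

FEATURE_RADIUS = 1.5
XVOL_RADIUS = 1.0
ANGLE_TOL = 34.0
SHELL_RADIUS = 7.0  # Xvol shell distance from the feature centroid, Å


def layout(n: int) -> np.ndarray:
    """n low-symmetry feature positions: a 3 Å ring with a rising z offset."""
    pts = []
    for i in range(n):
        a = 2.0 * math.pi * i / n
        pts.append([3.0 * math.cos(a), 3.0 * math.sin(a), 0.7 * i])
    return np.array(pts)


def fibonacci_shell(n: int, center: np.ndarray) -> np.ndarray:
    """n near-uniform points on a sphere of radius SHELL_RADIUS around center."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - z * z))
        a = golden * i
        pts.append([r * math.cos(a), r * math.sin(a), z])
    return center + SHELL_RADIUS * np.array(pts)


def build(model_id, target, origin, spec, n_xvols):
    """spec: list of (kind, anchor) pairs."""
    pos = layout(len(spec))
    centroid = pos.mean(axis=0)
    features = []
    for (kind, anchor), p in zip(spec, pos):
        direction = None
        angle_tol = None
        if kind in ("HBD", "HBA"):
            out = p - centroid
            out[2] = 0.5  # tilt off the ring plane
            direction = out / np.linalg.norm(out)
            angle_tol = ANGLE_TOL
        elif kind == "AI":
            direction = np.array([0.0, 0.0, 1.0])
            angle_tol = ANGLE_TOL
        features.append(
            ModelFeature(kind, p, FEATURE_RADIUS, direction, angle_tol, anchor)
        )
    xvols = [ExclusionVolume(c, XVOL_RADIUS) for c in fibonacci_shell(n_xvols, centroid)]
    # geometry sanity: exclusion shell clear of every feature sphere
    for x in xvols:
        for f in features:
            assert np.linalg.norm(x.center - f.center) > f.radius + x.radius + 0.5
    return PharmacophoreModel(
        id=model_id,
        target=target,
        origin=origin,
        features=features,
        xvols=xvols,
        metadata={"note": "synthetic exemplar geometry authored for pipeline testing"},
    )


def sb(pdb_id, resolution):
    return ModelOrigin("structure_based", pdb_id=pdb_id, resolution=resolution)


def lb(*training_ids):
    return ModelOrigin("ligand_based", training_ids=training_ids)


MODELS = [
    build("jak1_sb1", "JAK1", sb("5HX8", 2.0),
          [("HBD", "Glu957"), ("HBA", "Leu959"), ("HC", None), ("HC", None)], 66),
    build("jak1_lb1", "JAK1", lb("cpd-02", "cpd-03", "cpd-04"),
          [("HBA", None), ("HBA", None), ("HBA", None), ("AI", None), ("AI", None)], 47),
    build("jak2_sb1", "JAK2", sb("6VNB", 2.1),
          [("HBD", "Leu932"), ("HBA", "Glu930"), ("HC", None), ("HC", None)], 9),
    build("jak2_lb1", "JAK2", lb("cpd-07", "cpd-08", "cpd-09", "cpd-10"),
          [("HBD", None), ("HBA", None), ("HBA", None), ("AI", None), ("AI", None)], 9),
    build("jak3_sb1", "JAK3", sb("4Z16", 1.9),
          [("HBD", "Leu905"), ("HBA", None), ("HC", None), ("HC", None), ("HC", None)], 20),
    build("jak3_lb1", "JAK3", lb("cpd-12", "cpd-13"),
          [("HBA", None), ("AI", None), ("AI", None), ("HC", None), ("HC", None)], 29),
    build("tyk2_sb1", "TYK2", sb("6VNS", 2.2),
          [("HBD", "Val981"), ("HBA", None), ("HBA", "Ser985"), ("HBA", "Ser985"),
           ("HC", None), ("HC", None)], 26),
    build("tyk2_lb1", "TYK2", lb("cpd-15", "cpd-16"),
          [("HBD", None), ("HBA", None), ("HBA", None), ("HC", None), ("AI", None)], 35),
]


def main():
    out = Path(__file__).resolve().parents[1] / "src/pharmscreen/data/exemplar_models.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    save_models(ModelCollection(MODELS), out)
    print(f"wrote {len(MODELS)} models to {out}")


if __name__ == "__main__":
    main()
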