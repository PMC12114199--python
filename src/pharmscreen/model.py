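"""Pharmacophore model representation, serialization and construction.

A pharmacophore model is a set of typed features (hydrogen-bond donor/acceptor,
hydrophobic contact, aromatic interaction), each a tolerance sphere in 3D with
an optional direction cone, plus exclusion volumes that approximate receptor
bulk.  Models are either structure-based (derived from a protein--ligand
complex) or ligand-based (built by merging the perceived features of aligned
active compounds).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

SCHEMA = "pharmscreen-model/1"

#: Default tolerance-sphere radius for model features, in Angstrom.
DEFAULT_FEATURE_RADIUS = 1.5
#: Default exclusion-volume radius, in Angstrom.
DEFAULT_XVOL_RADIUS = 1.0
#: Default half-angle of the direction cone, in degrees.
DEFAULT_ANGLE_TOL = 34.0

TARGETS = ("JAK1", "JAK2", "JAK3", "TYK2", "other")


class FeatureKind(str, Enum):
    """Pharmacophoric feature classes: donor, acceptor, hydrophobic, aromatic."""

    HBD = "HBD"
    HBA = "HBA"
    HC = "HC"
    AI = "AI"


class ModelError(ValueError):
    """Raised when a model or collection violates its invariants."""


def _as_point(value, where: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ModelError(f"{where}: expected a 3D point, got shape {arr.shape}")
    return arr


def _as_unit(value, where: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ModelError(f"{where}: expected a 3D vector, got shape {arr.shape}")
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        raise ModelError(f"{where}: zero direction vector")
    return arr / norm


@dataclass(frozen=True)
class ModelFeature:
    """One tolerance sphere of a pharmacophore model.

    The optional ``anchor`` records the interacting receptor residue (for
    example ``"Glu957"``); it is annotation only and never affects matching.
    """

    kind: FeatureKind
    center: np.ndarray
    radius: float = DEFAULT_FEATURE_RADIUS
    direction: np.ndarray | None = None
    angle_tol: float | None = None
    anchor: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "kind", FeatureKind(self.kind))
        object.__setattr__(self, "center", _as_point(self.center, "feature center"))
        if self.radius <= 0:
            raise ModelError(f"feature radius must be > 0, got {self.radius}")
        if self.direction is not None:
            object.__setattr__(
                self, "direction", _as_unit(self.direction, "feature direction")
            )
        if self.angle_tol is not None and self.direction is None:
            raise ModelError("angle_tol requires a direction")


@dataclass(frozen=True)
class ExclusionVolume:
    """Forbidden sphere: any ligand heavy atom strictly inside it voids a match."""

    center: np.ndarray
    radius: float = DEFAULT_XVOL_RADIUS

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center, "xvol center"))
        if self.radius <= 0:
            raise ModelError(f"xvol radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ModelOrigin:
    """Provenance of a model: structure-based or ligand-based."""

    type: str  # "structure_based" | "ligand_based"
    pdb_id: str | None = None
    resolution: float | None = None
    training_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.type not in ("structure_based", "ligand_based"):
            raise ModelError(f"unknown origin type {self.type!r}")
        object.__setattr__(self, "training_ids", tuple(self.training_ids))


@dataclass
class PharmacophoreModel:
    id: str
    target: str
    origin: ModelOrigin
    features: list[ModelFeature]
    xvols: list[ExclusionVolume] = field(default_factory=list)
    max_omitted: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ModelError(f"model {self.id!r}: unknown target {self.target!r}")
        if len(self.features) < 1:
            raise ModelError(f"model {self.id!r}: needs at least one feature")
        if not (0 <= self.max_omitted < len(self.features)):
            raise ModelError(
                f"model {self.id!r}: max_omitted {self.max_omitted} out of range"
            )

    @property
    def feature_centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])


@dataclass
class ModelCollection:
    models: list[PharmacophoreModel]

    def __post_init__(self):
        ids = [m.id for m in self.models]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelError(f"duplicate model ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def by_target(self) -> dict[str, list[PharmacophoreModel]]:
        out: dict[str, list[PharmacophoreModel]] = {}
        for m in self.models:
            out.setdefault(m.target, []).append(m)
        return out

    def get(self, model_id: str) -> PharmacophoreModel:
        for m in self.models:
            if m.id == model_id:
                return m
        raise KeyError(model_id)


# ---------------------------------------------------------------------------
# Serialization (JSON schema "pharmscreen-model/1")
# ---------------------------------------------------------------------------


def _feature_to_dict(f: ModelFeature) -> dict:
    d: dict = {"kind": f.kind.value, "center": list(f.center), "radius": f.radius}
    if f.direction is not None:
        d["direction"] = list(f.direction)
    if f.angle_tol is not None:
        d["angle_tol"] = f.angle_tol
    if f.anchor is not None:
        d["anchor"] = f.anchor
    return d


def _feature_from_dict(d: Mapping, where: str) -> ModelFeature:
    try:
        kind = FeatureKind(d["kind"])
    except (KeyError, ValueError):
        raise ModelError(f"{where}: unknown feature kind {d.get('kind')!r}") from None
    try:
        return ModelFeature(
            kind=kind,
            center=d["center"],
            radius=float(d.get("radius", DEFAULT_FEATURE_RADIUS)),
            direction=d.get("direction"),
            angle_tol=d.get("angle_tol"),
            anchor=d.get("anchor"),
        )
    except ModelError as exc:
        raise ModelError(f"{where}: {exc}") from None


def _model_to_dict(m: PharmacophoreModel) -> dict:
    origin: dict = {"type": m.origin.type}
    if m.origin.pdb_id is not None:
        origin["pdb_id"] = m.origin.pdb_id
    if m.origin.resolution is not None:
        origin["resolution"] = m.origin.resolution
    if m.origin.training_ids:
        origin["training_ids"] = list(m.origin.training_ids)
    return {
        "id": m.id,
        "target": m.target,
        "origin": origin,
        "max_omitted": m.max_omitted,
        "features": [_feature_to_dict(f) for f in m.features],
        "xvols": [{"center": list(x.center), "radius": x.radius} for x in m.xvols],
        "metadata": m.metadata,
    }


def _model_from_dict(d: Mapping) -> PharmacophoreModel:
    mid = d.get("id", "<missing id>")
    origin_d = d.get("origin", {})
    origin = ModelOrigin(
        type=origin_d.get("type", "ligand_based"),
        pdb_id=origin_d.get("pdb_id"),
        resolution=origin_d.get("resolution"),
        training_ids=origin_d.get("training_ids", ()),
    )
    features = [
        _feature_from_dict(fd, f"models[{mid}].features[{i}]")
        for i, fd in enumerate(d.get("features", []))
    ]
    xvols = []
    for i, xd in enumerate(d.get("xvols", [])):
        try:
            xvols.append(
                ExclusionVolume(xd["center"], float(xd.get("radius", DEFAULT_XVOL_RADIUS)))
            )
        except ModelError as exc:
            raise ModelError(f"models[{mid}].xvols[{i}]: {exc}") from None
    return PharmacophoreModel(
        id=d["id"],
        target=d["target"],
        origin=origin,
        features=features,
        xvols=xvols,
        max_omitted=int(d.get("max_omitted", 0)),
        metadata=dict(d.get("metadata", {})),
    )


def load_models(path: str | Path) -> ModelCollection:
    """Load a model collection from its JSON file, enforcing all invariants."""
    with open(path) as fh:
        doc = json.load(fh)
    return _collection_from_doc(doc)


def _collection_from_doc(doc: Mapping) -> ModelCollection:
    if doc.get("schema") != SCHEMA:
        raise ModelError(f"unsupported schema {doc.get('schema')!r}, expected {SCHEMA!r}")
    models = [_model_from_dict(md) for md in doc.get("models", [])]
    return ModelCollection(models)


def save_models(collection: ModelCollection, path: str | Path) -> None:
    """Write a collection as schema-versioned JSON; inverse of :func:`load_models`."""
    doc = {"schema": SCHEMA, "models": [_model_to_dict(m) for m in collection.models]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_exemplar_models() -> ModelCollection:
    """Load the eight exemplar models shipped with the package.

    One structure-based and one ligand-based model per JAK subtype, with
    feature and exclusion-volume compositions mirroring published exemplars
    (e.g. JAK1_SB1: one HBD anchored at Glu957, one HBA at Leu959, two HCs,
    66 Xvols).  The geometries are authored for pipeline testing; they are
    synthetic stand-ins, not reproductions of any screening tool's output.
    """
    ref = resources.files("pharmscreen").joinpath("data/exemplar_models.json")
    return _collection_from_doc(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def check_model_quality(model: PharmacophoreModel) -> list[str]:
    """Flag models failing the dataset curation quality rules.

    ``too_few_features``: three or fewer features (such models are too
    permissive to be selective).  ``low_resolution``: a structure-based model
    whose source crystal structure does not meet the sub-3-Angstrom
    resolution requirement.
    """
    flags = []
    if len(model.features) <= 3:
        flags.append("too_few_features")
    if (
        model.origin.type == "structure_based"
        and model.origin.resolution is not None
        and model.origin.resolution >= 3.0
    ):
        flags.append("low_resolution")
    return flags


def summarize_collection(collection: ModelCollection) -> dict:
    """Per-target and per-origin model counts."""
    per_target = {t: 0 for t in TARGETS}
    per_origin = {"structure_based": 0, "ligand_based": 0}
    for m in collection.models:
        per_target[m.target] += 1
        per_origin[m.origin.type] += 1
    return {
        "total": len(collection.models),
        "per_target": {t: n for t, n in per_target.items() if n},
        "per_origin": per_origin,
    }


# ---------------------------------------------------------------------------
# Ligand-based model construction (merged feature mode)
# ---------------------------------------------------------------------------


def build_ligand_based_model(
    aligned_feature_sets: Sequence,
    merge_radius: float,
    min_fraction: float = 0.5,
    *,
    model_id: str = "lb_model",
    target: str = "other",
    default_radius: float = DEFAULT_FEATURE_RADIUS,
    default_angle_tol: float = DEFAULT_ANGLE_TOL,
) -> PharmacophoreModel:
    """Merge the features of pre-aligned ligands into a consensus model.

    Features of identical kind across ligands are single-linkage clustered at
    ``merge_radius``; a cluster represented in at least ``min_fraction`` of
    the ligands becomes a model feature at the cluster centroid.  The cluster
    direction is the normalized mean direction when every member carries one.

    Inputs must already share a common frame (e.g. each ligand matched onto a
    seed model built from the first ligand); flexible 3D alignment is out of
    scope here.
    """
    if len(aligned_feature_sets) < 2:
        raise ModelError("need at least two aligned feature sets to merge")
    if merge_radius <= 0:
        raise ModelError("merge_radius must be > 0")
    if not (0 < min_fraction <= 1):
        raise ModelError("min_fraction must be in (0, 1]")

    n_sets = len(aligned_feature_sets)
    model_features: list[ModelFeature] = []
    for kind in FeatureKind:
        # pooled features of this kind, tagged with their ligand index
        pool = [
            (si, f)
            for si, fs in enumerate(aligned_feature_sets)
            for f in fs.features
            if f.kind == kind
        ]
        if not pool:
            continue
        clusters = _single_linkage(np.array([f.position for _, f in pool]), merge_radius)
        for members in clusters:
            owners = {pool[i][0] for i in members}
            if len(owners) / n_sets < min_fraction:
                continue
            feats = [pool[i][1] for i in members]
            centroid = np.mean([f.position for f in feats], axis=0)
            direction = None
            angle_tol = None
            if all(f.direction is not None for f in feats):
                mean_dir = np.mean([f.direction for f in feats], axis=0)
                if np.linalg.norm(mean_dir) > 1e-9:
                    direction = mean_dir / np.linalg.norm(mean_dir)
                    angle_tol = default_angle_tol
            model_features.append(
                ModelFeature(kind, centroid, default_radius, direction, angle_tol)
            )
    if not model_features:
        raise ModelError("no consensus features")
    model_features.sort(key=lambda f: (list(FeatureKind).index(f.kind), tuple(f.center)))
    return PharmacophoreModel(
        id=model_id,
        target=target,
        origin=ModelOrigin(
            "ligand_based",
            training_ids=tuple(fs.molecule_id for fs in aligned_feature_sets),
        ),
        features=model_features,
    )


def _single_linkage(points: np.ndarray, radius: float) -> list[list[int]]:
    """Single-linkage clusters: indices connected by pairwise distance <= radius."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # deterministic order: by smallest member index
    return sorted(groups.values(), key=min)
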