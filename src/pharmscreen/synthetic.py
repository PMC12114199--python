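"""Synthetic benchmark generation.

The generators emulate the statistical structure a decoy-aware screening
benchmark assumes: *planted actives* whose typed feature geometry realizes a
pharmacophore model up to isotropic positional jitter in a random rigid
frame, *decoys* that provably violate at least one model constraint, and
activity tables whose IC50 values land in prescribed threshold bands.

Benchmarks are feature-set-level (typed points with dummy heavy atoms at the
feature positions), bypassing chemistry so that matching and validation are
testable independently of feature perception.  Every generated decoy is
verified to fail the matcher at generation tolerances — verified, not
assumed — with a bounded retry count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from pharmscreen.curation import (
    ACTIVE_THRESHOLD_NM,
    INACTIVE_THRESHOLD_NM,
    ActivityRecord,
)
from pharmscreen.matching import DEFAULT_PARAMS, MatchParams, match_feature_set
from pharmscreen.model import PharmacophoreModel
from pharmscreen.perception import FeatureSet, LigandFeature
from pharmscreen.validation import (
    ConfusionSummary,
    MetricsReport,
    RocData,
    compute_metrics,
    roc_auc,
)

log = logging.getLogger(__name__)

DECOY_MODES = ("shuffle_kind", "displace_one", "random_points")

#: Standard deviation of the direction jitter applied to planted actives, degrees.
DIRECTION_JITTER_SD_DEG = 5.0

_MAX_DECOY_RETRIES = 50


class SyntheticError(RuntimeError):
    pass


@dataclass(frozen=True)
class BenchmarkSpec:
    """Recipe for one planted benchmark."""

    model_id: str
    n_actives: int = 20
    n_decoys: int = 180
    jitter_sd: float = 0.0
    decoy_mode: str = "displace_one"
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 0 or self.n_decoys < 0:
            raise SyntheticError("counts must be non-negative")
        if self.n_actives + self.n_decoys < 1:
            raise SyntheticError("need at least one entry")
        if self.jitter_sd < 0:
            raise SyntheticError("jitter_sd must be >= 0")
        if self.decoy_mode not in DECOY_MODES:
            raise SyntheticError(f"unknown decoy mode {self.decoy_mode!r}")


@dataclass
class BenchmarkEntry:
    label: str  # "active" | "decoy"
    feature_set: FeatureSet
    coords: np.ndarray  # dummy heavy atoms (the feature positions)


@dataclass
class PlantedBenchmark:
    model_id: str
    spec: BenchmarkSpec
    entries: list[BenchmarkEntry] = field(default_factory=list)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-10.0, 10.0, size=3)
    return rot, t


def _jitter_direction(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, DIRECTION_JITTER_SD_DEG))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    return r @ d


def _featureset_from_model(
    model: PharmacophoreModel,
    mol_id: str,
    jitter_sd: float,
    rng: np.random.Generator,
) -> tuple[FeatureSet, np.ndarray]:
    """The model's feature layout, jittered and placed in a random rigid frame."""
    rot, t = _random_rigid(rng)
    feats = []
    for i, mf in enumerate(model.features):
        pos = mf.center + rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else mf.center
        direction = mf.direction
        if direction is not None:
            direction = _jitter_direction(direction, rng)
        feats.append(
            LigandFeature(
                mf.kind,
                rot @ pos + t,
                rot @ direction if direction is not None else None,
                (i,),
            )
        )
    fs = FeatureSet(mol_id, 0, feats)
    return fs, fs.positions()


def make_decoy_featureset(
    model: PharmacophoreModel,
    mode: str = "displace_one",
    seed: int | np.random.Generator = 0,
    params: MatchParams = DEFAULT_PARAMS,
    mol_id: str = "decoy",
) -> tuple[FeatureSet, np.ndarray]:
    """A feature set that verifiably fails to match ``model``.

    ``shuffle_kind`` permutes the feature kinds over the positions (falling
    back to ``displace_one`` with a warning when all kinds are equal);
    ``displace_one`` moves one feature by more than twice its tolerance
    radius; ``random_points`` scatters points uniformly in the padded model
    bounding box.  The candidate is re-generated (bounded retries) until the
    matcher rejects it; a model that cannot be falsified raises.
    """
    if mode not in DECOY_MODES:
        raise SyntheticError(f"unknown decoy mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kinds = [f.kind for f in model.features]
    if mode == "shuffle_kind" and len(set(kinds)) == 1:
        log.warning("all features share one kind; shuffle_kind falls back to displace_one")
        mode = "displace_one"

    for _ in range(_MAX_DECOY_RETRIES):
        fs = _decoy_candidate(model, mode, rng, mol_id)
        coords = fs.positions()
        if not match_feature_set(model, fs, coords, params).matched:
            return fs, coords
    raise SyntheticError(
        f"could not generate a failing decoy for model {model.id!r} in "
        f"{_MAX_DECOY_RETRIES} attempts; the model may be unfalsifiable at these tolerances"
    )


def _decoy_candidate(
    model: PharmacophoreModel, mode: str, rng: np.random.Generator, mol_id: str
) -> FeatureSet:
    rot, t = _random_rigid(rng)
    centers = model.feature_centers
    kinds = [f.kind for f in model.features]
    dirs = [f.direction for f in model.features]

    if mode == "shuffle_kind":
        perm = rng.permutation(len(kinds))
        while all(kinds[p] == kinds[i] for i, p in enumerate(perm)):
            perm = rng.permutation(len(kinds))
        kinds = [kinds[p] for p in perm]
        dirs = [dirs[p] for p in perm]
        positions = centers
    elif mode == "displace_one":
        positions = centers.copy()
        victim = int(rng.integers(len(kinds)))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = model.features[victim].radius
        positions[victim] = positions[victim] + direction * rng.uniform(2.1 * r, 3.0 * r)
    else:  # random_points
        lo = centers.min(axis=0) - 2.0
        hi = centers.max(axis=0) + 2.0
        positions = rng.uniform(lo, hi, size=centers.shape)

    feats = [
        LigandFeature(
            kinds[i],
            rot @ positions[i] + t,
            rot @ dirs[i] if dirs[i] is not None else None,
            (i,),
        )
        for i in range(len(kinds))
    ]
    return FeatureSet(mol_id, 0, feats)


def make_planted_benchmark(
    model: PharmacophoreModel,
    spec: BenchmarkSpec,
    params: MatchParams = DEFAULT_PARAMS,
) -> PlantedBenchmark:
    """Generate a labeled library of planted actives and constraint-violating decoys.

    Seed-deterministic: the same spec yields byte-identical feature sets.
    """
    rng = np.random.default_rng(spec.seed)
    bench = PlantedBenchmark(model.id, spec)
    for i in range(spec.n_actives):
        fs, coords = _featureset_from_model(model, f"active-{i:04d}", spec.jitter_sd, rng)
        bench.entries.append(BenchmarkEntry("active", fs, coords))
    for i in range(spec.n_decoys):
        fs, coords = make_decoy_featureset(
            model, spec.decoy_mode, rng, params, mol_id=f"decoy-{i:04d}"
        )
        bench.entries.append(BenchmarkEntry("decoy", fs, coords))
    return bench


def score_benchmark(
    model: PharmacophoreModel,
    benchmark: PlantedBenchmark,
    params: MatchParams = DEFAULT_PARAMS,
) -> tuple[ConfusionSummary, MetricsReport, RocData | None]:
    """Screen a planted benchmark and compute its enrichment metrics.

    Actives are the positives; decoys enter the census as decoys with no
    inactive compartment.  The ROC ranks every entry by its match score
    (failed attempts keep their best failed score); ``None`` when the
    benchmark is single-class.
    """
    from pharmscreen.screening import screen_feature_sets

    results = screen_feature_sets(
        model, [(e.feature_set, e.coords) for e in benchmark.entries], params
    )
    labels = [e.label == "active" for e in benchmark.entries]
    tp = sum(1 for r, pos in zip(results, labels) if pos and r.matched)
    fp = sum(1 for r, pos in zip(results, labels) if not pos and r.matched)
    n_ac = sum(labels)
    n_dc = len(labels) - n_ac
    cs = ConfusionSummary(tp=tp, fp_inactive=0, fp_decoy=fp, n_ac=n_ac, n_ia=0, n_dc=n_dc)
    metrics = compute_metrics(cs)
    roc = None
    if 0 < n_ac < len(labels):
        roc = roc_auc([(r.score, pos) for r, pos in zip(results, labels)])
    return cs, metrics, roc


def make_activity_records(
    target: str,
    n_active: int,
    n_intermediate: int,
    n_inactive: int,
    seed: int = 0,
) -> list[ActivityRecord]:
    """Activity records whose IC50 values land in the three threshold bands.

    Values are log-uniform within each band (active: 1–1000 nM; intermediate:
    just above 1000 nM up to the target's inactive cutoff; inactive: above
    the cutoff up to 100x the cutoff), so labeling recovers exactly the
    requested counts.
    """
    if target not in INACTIVE_THRESHOLD_NM:
        raise SyntheticError(f"unknown target {target!r}")
    rng = np.random.default_rng(seed)
    cutoff = INACTIVE_THRESHOLD_NM[target]

    def log_uniform(lo: float, hi: float, n: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))

    records: list[ActivityRecord] = []
    bands = [
        ("act", 1.0, ACTIVE_THRESHOLD_NM, n_active),
        ("mid", ACTIVE_THRESHOLD_NM * 1.001, cutoff, n_intermediate),
        ("ina", cutoff * 1.001, cutoff * 100.0, n_inactive),
    ]
    for tag, lo, hi, n in bands:
        for i, val in enumerate(log_uniform(lo, hi, n)):
            records.append(
                ActivityRecord(f"{target}-{tag}-{i:04d}", target, float(val), "synthetic")
            )
    return records
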