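"""Activity-threshold dataset curation.

Compounds are classified per target from their IC50: active at IC50 ≤ 1000 nM;
inactive above a target-specific cutoff (40,000 nM for JAK1; 50,000 nM for
JAK2, JAK3 and TYK2, strict inequality); compounds in the intermediate band
are excluded from the benchmark.  Decoys — presumed-inactive structures with
physicochemical properties similar to the actives — are attached separately
and must stay disjoint from the measured sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ACTIVE_THRESHOLD_NM = 1000.0
INACTIVE_THRESHOLD_NM = {
    "JAK1": 40_000.0,
    "JAK2": 50_000.0,
    "JAK3": 50_000.0,
    "TYK2": 50_000.0,
}


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    target: str
    ic50_nm: float
    source: str = ""

    def __post_init__(self):
        if self.target not in INACTIVE_THRESHOLD_NM:
            raise CurationError(
                f"record {self.compound_id!r}: unknown target {self.target!r}"
            )
        if not (math.isfinite(self.ic50_nm) and self.ic50_nm > 0):
            raise CurationError(
                f"record {self.compound_id!r}: IC50 must be finite and positive, "
                f"got {self.ic50_nm}"
            )


@dataclass
class LabeledDataset:
    """Per-target benchmark: actives, inactives, decoys, and exclusions.

    The four sets are pairwise disjoint; every input activity record lands in
    exactly one of actives/inactives/excluded.
    """

    target: str
    actives: list[str] = field(default_factory=list)
    inactives: list[str] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_ac(self) -> int:
        return len(self.actives)

    @property
    def n_ia(self) -> int:
        return len(self.inactives)

    @property
    def n_dc(self) -> int:
        return len(self.decoys)

    @property
    def total(self) -> int:
        """Database size entering the metrics: actives + inactives + decoys."""
        return self.n_ac + self.n_ia + self.n_dc


def classify_ic50(target: str, ic50_nm: float) -> str:
    """Band for one IC50 value: ``active`` / ``inactive`` / ``intermediate``."""
    if ic50_nm <= ACTIVE_THRESHOLD_NM:
        return "active"
    if ic50_nm > INACTIVE_THRESHOLD_NM[target]:
        return "inactive"
    return "intermediate"


def label_dataset(records: Sequence[ActivityRecord], target: str) -> LabeledDataset:
    """Classify activity records into a labeled per-target dataset.

    Every record must belong to ``target``.  Multiple measurements for one
    compound are aggregated by the geometric mean of their IC50 before
    thresholding (a deterministic stand-in for manual reconciliation).
    """
    if target not in INACTIVE_THRESHOLD_NM:
        raise CurationError(f"unknown target {target!r}")
    by_compound: dict[str, list[float]] = {}
    for rec in records:
        if rec.target != target:
            raise CurationError(
                f"record {rec.compound_id!r} has target {rec.target}, expected {target}"
            )
        by_compound.setdefault(rec.compound_id, []).append(rec.ic50_nm)

    ds = LabeledDataset(target)
    for cid in sorted(by_compound):
        values = by_compound[cid]
        ic50 = _geometric_mean(values)
        band = classify_ic50(target, ic50)
        if band == "active":
            ds.actives.append(cid)
        elif band == "inactive":
            ds.inactives.append(cid)
        else:
            ds.excluded.append((cid, "intermediate"))
    return ds


def _geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean, exact for single values (threshold boundaries are exact)."""
    if len(values) == 1:
        return values[0]
    prod = math.prod(values)
    if math.isfinite(prod):
        return prod ** (1.0 / len(values))
    return math.exp(sum(math.log(v) for v in values) / len(values))


def attach_decoys(ds: LabeledDataset, decoy_ids: Iterable[str]) -> LabeledDataset:
    """Append decoy ids; they must be disjoint from actives and inactives."""
    decoy_ids = list(decoy_ids)
    overlap = (set(ds.actives) | set(ds.inactives)) & set(decoy_ids)
    if overlap:
        raise CurationError(
            f"decoy ids overlap actives/inactives: {sorted(overlap)}"
        )
    out = LabeledDataset(
        ds.target,
        list(ds.actives),
        list(ds.inactives),
        list(ds.decoys) + decoy_ids,
        list(ds.excluded),
    )
    return out


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a tab-separated activity table: compound_id, target, ic50_nM[, source]."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("compound_id", "compound"):
                continue
            if len(parts) < 3:
                raise CurationError(f"{path}:{lineno}: expected >= 3 columns")
            records.append(
                ActivityRecord(
                    parts[0],
                    parts[1],
                    float(parts[2]),
                    parts[3] if len(parts) > 3 else "",
                )
            )
    return records
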