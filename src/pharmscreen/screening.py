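"""Library screening with union-of-models hit semantics.

A compound is a hit for a target when at least one of that target's models
matches any of its conformers.  The cross-target unique hit count is the
cardinality of the union of the per-target hit sets (a compound matching two
targets yields two per-target hits but counts once overall).  Hits can be
cross-referenced against an external identifier list (e.g. metabolome
detections) by structure key with a normalized-name fallback.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from pharmscreen.matching import DEFAULT_PARAMS, MatchParams, MatchResult, match_feature_set, screen_molecule
from pharmscreen.model import ModelCollection, PharmacophoreModel
from pharmscreen.perception import FeatureSet

log = logging.getLogger(__name__)


@dataclass
class ScreenHit:
    molecule_id: str
    target: str
    model_ids: list[str]
    best_score: float
    best_conformer: int
    structure_key: str | None = None
    name: str | None = None
    in_reference: bool | None = None


@dataclass
class ScreenReport:
    hits: list[ScreenHit]
    errors: list[tuple[str, str]] = field(default_factory=list)  # (molecule id, message)

    def hit_ids(self, target: str | None = None) -> set[str]:
        return {
            h.molecule_id for h in self.hits if target is None or h.target == target
        }

    @property
    def unique_hit_ids(self) -> set[str]:
        """Cross-target union: each molecule counted once overall."""
        return {h.molecule_id for h in self.hits}


def screen_library(
    collection: ModelCollection,
    library: Sequence,
    params: MatchParams = DEFAULT_PARAMS,
) -> ScreenReport:
    """Screen a library of records against every model in the collection.

    Returns one :class:`ScreenHit` per (molecule, target) with at least one
    matching model, ordered by (molecule id, target).  Molecules without
    conformers are collected as per-molecule errors and the run continues.
    """
    by_target = collection.by_target()
    hits: list[ScreenHit] = []
    errors: list[tuple[str, str]] = []
    for rec in library:
        mol = rec.molecule
        if mol.num_conformers == 0:
            errors.append((mol.id, "no conformers"))
            log.warning("molecule %r skipped: no conformers", mol.id)
            continue
        for target in sorted(by_target):
            matched_ids: list[str] = []
            best_score, best_conf = 0.0, 0
            for model in by_target[target]:
                res = screen_molecule(model, mol, params)
                if res.matched:
                    matched_ids.append(model.id)
                    if res.score > best_score:
                        best_score, best_conf = res.score, res.conformer_index
            if matched_ids:
                hits.append(
                    ScreenHit(
                        mol.id,
                        target,
                        matched_ids,
                        best_score,
                        best_conf,
                        structure_key=mol.structure_key,
                        name=mol.name,
                    )
                )
    hits.sort(key=lambda h: (h.molecule_id, h.target))
    return ScreenReport(hits, errors)


def screen_feature_sets(
    model: PharmacophoreModel,
    entries: Sequence[tuple[FeatureSet, np.ndarray]],
    params: MatchParams = DEFAULT_PARAMS,
) -> list[MatchResult]:
    """Match pre-perceived feature sets (with heavy-atom coords) against one model.

    This is the chemistry-free screening path used by the synthetic planted
    benchmarks, where entries are typed point sets rather than molecules.
    """
    return [match_feature_set(model, fs, coords, params) for fs, coords in entries]


def normalize_name(name: str) -> str:
    """Lowercase and strip whitespace/punctuation (identifier-list conventions vary)."""
    return re.sub(r"[\W_]+", "", name.lower())


def cross_reference(
    hits: Sequence[ScreenHit],
    reference_ids: Iterable[str],
) -> tuple[list[ScreenHit], dict]:
    """Flag each unique hit molecule as present/absent in an identifier list.

    Reference entries may be structure keys or names; matching tries the
    structure key first, then the normalized display name.  The reference is
    deduplicated on load.  Returns the annotated hits plus summary counts.
    """
    raw = {r.strip() for r in reference_ids if r and r.strip()}
    normalized = {normalize_name(r) for r in raw}
    present_ids: set[str] = set()
    for h in hits:
        found = (h.structure_key is not None and h.structure_key in raw) or (
            h.name is not None and normalize_name(h.name) in normalized
        )
        h.in_reference = found
        if found:
            present_ids.add(h.molecule_id)
    unique = {h.molecule_id for h in hits}
    summary = {
        "unique_hits": len(unique),
        "present_in_reference": len(present_ids),
        "absent_from_reference": len(unique - present_ids),
    }
    return list(hits), summary
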