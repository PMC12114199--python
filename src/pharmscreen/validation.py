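"""Screening-performance statistics: confusion counts, enrichment metrics, ROC.

The validation vocabulary follows enrichment-style virtual-screening
benchmarks.  With ``TP`` actives retrieved, ``FP`` inactive-or-decoy hits,
``nAC``/``nIA``/``nDC`` the database census and ``total = nAC + nIA + nDC``:

* sensitivity = TP / nAC
* yield of actives YoA = TP / (TP + FP)
* enrichment factor EF = YoA / (nAC / total)  — fold improvement over random picking
* accuracy = (TP + TN) / total, with TN = nIA + nDC − FP

Two specificity variants are reported because published screening summaries
are ambiguous about the denominator: ``specificity_all`` = TN / (nIA + nDC)
and ``specificity_ia_only`` = 1 − FP_ia / nIA (absent when nIA = 0).
Models with EF below a threshold (default 4, strict) are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from pharmscreen.curation import LabeledDataset


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionSummary:
    """Hit/census counts for one model (or model union) on one dataset."""

    tp: int
    fp_inactive: int
    fp_decoy: int
    n_ac: int
    n_ia: int
    n_dc: int

    def __post_init__(self):
        for name in ("tp", "fp_inactive", "fp_decoy", "n_ac", "n_ia", "n_dc"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.tp > self.n_ac:
            raise ValidationError("tp cannot exceed n_ac")
        if self.fp_inactive > self.n_ia:
            raise ValidationError("fp_inactive cannot exceed n_ia")
        if self.fp_decoy > self.n_dc:
            raise ValidationError("fp_decoy cannot exceed n_dc")

    @property
    def fp(self) -> int:
        return self.fp_inactive + self.fp_decoy

    @property
    def fn(self) -> int:
        return self.n_ac - self.tp

    @property
    def tn(self) -> int:
        return self.n_ia + self.n_dc - self.fp

    @property
    def total(self) -> int:
        return self.n_ac + self.n_ia + self.n_dc


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    accuracy: float
    specificity_all: float
    specificity_ia_only: float | None
    yoa: float | None
    ef: float | None
    no_hits: bool = False


def confusion_from_screen(hits, ds: LabeledDataset) -> ConfusionSummary:
    """Confusion counts from screen hits under union-of-models semantics.

    ``hits`` may be ScreenHit objects or bare molecule ids.  Hits on excluded
    compounds are ignored; hit ids absent from the dataset are warned about
    and excluded from the counts.
    """
    import logging

    hit_ids = {h if isinstance(h, str) else h.molecule_id for h in hits}
    actives, inactives, decoys = set(ds.actives), set(ds.inactives), set(ds.decoys)
    excluded = {cid for cid, _ in ds.excluded}
    known = actives | inactives | decoys | excluded
    unknown = hit_ids - known
    if unknown:
        logging.getLogger(__name__).warning(
            "%d hit id(s) absent from dataset, ignored: %s",
            len(unknown),
            sorted(unknown)[:5],
        )
    return ConfusionSummary(
        tp=len(hit_ids & actives),
        fp_inactive=len(hit_ids & inactives),
        fp_decoy=len(hit_ids & decoys),
        n_ac=ds.n_ac,
        n_ia=ds.n_ia,
        n_dc=ds.n_dc,
    )


def compute_metrics(cs: ConfusionSummary) -> MetricsReport:
    """Enrichment metrics from confusion counts.

    With zero total hits, YoA and EF are undefined and reported as ``None``
    with the ``no_hits`` flag set.
    """
    if cs.n_ac < 1:
        raise ValidationError("need at least one active in the database")
    if cs.total < 1:
        raise ValidationError("empty database")
    hits = cs.tp + cs.fp
    sensitivity = cs.tp / cs.n_ac
    accuracy = (cs.tp + cs.tn) / cs.total
    neg = cs.n_ia + cs.n_dc
    specificity_all = cs.tn / neg if neg else 1.0
    specificity_ia = 1.0 - cs.fp_inactive / cs.n_ia if cs.n_ia else None
    if hits == 0:
        return MetricsReport(
            sensitivity, accuracy, specificity_all, specificity_ia, None, None, True
        )
    yoa = cs.tp / hits
    ef = yoa / (cs.n_ac / cs.total)
    return MetricsReport(sensitivity, accuracy, specificity_all, specificity_ia, yoa, ef)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocData:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_auc(scored: Sequence[tuple[float, bool]]) -> RocData:
    """ROC curve and AUC from (score, is-positive) pairs.

    The curve sweeps a descending score threshold with tied scores entering
    together; AUC by the trapezoid rule, which equals the Mann–Whitney
    statistic with ties counted one half.
    """
    scores = np.array([s for s, _ in scored], dtype=float)
    truth = np.array([bool(t) for _, t in scored])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    scores, truth = scores[order], truth[order]
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(truth[i:j].sum())
        fp += (j - i) - int(truth[i:j].sum())
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocData(fpr_arr, tpr_arr, auc)


# ---------------------------------------------------------------------------
# EF-based model filter
# ---------------------------------------------------------------------------


def filter_models_by_ef(
    per_model: Mapping[str, ConfusionSummary], threshold: float = 4.0
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop models whose enrichment factor falls below ``threshold`` (strict).

    Returns ``(retained_ids, dropped)`` where each dropped entry carries a
    reason ("ef below threshold" or "no hits" when EF is undefined).
    """
    retained: list[str] = []
    dropped: list[tuple[str, str]] = []
    for mid in sorted(per_model):
        rep = compute_metrics(per_model[mid])
        if rep.ef is None:
            dropped.append((mid, "no hits"))
        elif rep.ef < threshold:
            dropped.append((mid, f"ef {rep.ef:.2f} below threshold {threshold:g}"))
        else:
            retained.append(mid)
    return retained, dropped


# ---------------------------------------------------------------------------
# Built-in reference census (combined JAK model sets)
# ---------------------------------------------------------------------------

#: Published evaluation census of the combined JAK1/JAK2/JAK3/TYK2 model sets:
#: retrieved actives (TP), inactive and decoy hits, and database sizes.  Used
#: by the built-in census check, which recomputes the enrichment metrics from
#: these counts.
REFERENCE_CENSUS: dict[str, ConfusionSummary] = {
    "JAK1": ConfusionSummary(tp=95, fp_inactive=0, fp_decoy=79, n_ac=105, n_ia=48, n_dc=3263),
    "JAK2": ConfusionSummary(tp=167, fp_inactive=15, fp_decoy=75, n_ac=185, n_ia=49, n_dc=2840),
    "JAK3": ConfusionSummary(tp=116, fp_inactive=2, fp_decoy=292, n_ac=129, n_ia=42, n_dc=4499),
    "TYK2": ConfusionSummary(tp=68, fp_inactive=40, fp_decoy=136, n_ac=75, n_ia=61, n_dc=3050),
}

#: Printed summary metrics accompanying the census, for the PASS/FAIL check.
#: The JAK3 sensitivity as printed (0.86) disagrees with TP/nAC = 116/129 and
#: the printed specificities are not reproducible from the counts under any
#: single formula; both are reported but not asserted by the census check.
REFERENCE_METRICS: dict[str, dict[str, float]] = {
    "JAK1": {"accuracy": 0.97, "yoa": 0.55, "ef": 17.76, "sensitivity": 0.90},
    "JAK2": {"accuracy": 0.96, "yoa": 0.65, "ef": 10.80, "sensitivity": 0.90},
    "JAK3": {"accuracy": 0.93, "yoa": 0.28, "ef": 10.24, "sensitivity": 0.86},
    "TYK2": {"accuracy": 0.94, "yoa": 0.28, "ef": 11.84, "sensitivity": 0.91},
}

#: Metrics whose printed values reproduce from the census at 2-decimal rounding.
CENSUS_ASSERTED: dict[str, tuple[str, ...]] = {
    "JAK1": ("accuracy", "yoa", "ef", "sensitivity"),
    "JAK2": ("accuracy", "yoa", "ef", "sensitivity"),
    "JAK3": ("accuracy", "yoa", "ef"),
    "TYK2": ("accuracy", "yoa", "ef", "sensitivity"),
}


def census_check() -> tuple[bool, dict[str, dict[str, float]]]:
    """Recompute the reference-census metrics and compare at printed precision.

    Returns ``(ok, recomputed)`` where ``recomputed[target]`` holds the
    freshly computed accuracy, YoA, EF and sensitivity.  ``ok`` is True when
    every reproducible printed value agrees at 2-decimal rounding (the known
    discrepant entries are reported but not compared).
    """
    ok = True
    recomputed: dict[str, dict[str, float]] = {}
    for target, cs in REFERENCE_CENSUS.items():
        rep = compute_metrics(cs)
        vals = {
            "accuracy": rep.accuracy,
            "yoa": rep.yoa,
            "ef": rep.ef,
            "sensitivity": rep.sensitivity,
        }
        recomputed[target] = vals
        for metric in CENSUS_ASSERTED[target]:
            if round(vals[metric], 2) != REFERENCE_METRICS[target][metric]:
                ok = False
    return ok, recomputed
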