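"""Geometric pharmacophore matching.

A conformer satisfies a model when an injective, kind-compatible assignment
of model features to perceived ligand features exists such that, after the
least-squares rigid superposition of the assigned ligand positions onto the
model feature centers:

* every matched feature's residual distance is within its tolerance radius,
* every direction pair (where both model and ligand carry one) subtends at
  most the feature's cone half-angle,
* no transformed ligand heavy atom lies strictly inside any exclusion volume.

The correspondence search enumerates assignments depth-first with pairwise
distance pruning (a pair of assignments is feasible only if the model and
ligand inter-feature distances agree within the sum of the two tolerance
radii).  The superposition uses the Kabsch algorithm restricted to proper
rotations, so chirality is preserved.  Conformational flexibility is handled
solely by the conformer ensemble: each conformer is fitted rigidly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pharmscreen.model import FeatureKind, PharmacophoreModel, ExclusionVolume
from pharmscreen.perception import FeatureSet, perceive_features

#: A rigid fit needs at least this many point correspondences to be well-posed.
MIN_MATCHED_FEATURES = 3


@dataclass(frozen=True)
class MatchParams:
    """Matching configuration.

    ``default_angle_tol`` (degrees) applies to features that carry a
    direction but no explicit cone half-angle.  ``max_omitted`` overrides the
    model's own allowance when set.
    """

    default_angle_tol: float = 34.0
    max_omitted: int | None = None
    check_directions: bool = True


DEFAULT_PARAMS = MatchParams()


@dataclass
class MatchResult:
    matched: bool
    model_id: str
    molecule_id: str
    conformer_index: int
    correspondence: dict[int, int] = field(default_factory=dict)
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    residuals: dict[int, float] = field(default_factory=dict)
    clash: bool = False
    score: float = 0.0


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch, proper rotations only)
# ---------------------------------------------------------------------------


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Returns ``(R, t)`` with ``det(R) = +1`` minimizing
    ``sum ||R @ moving_i + t - fixed_i||^2``.
    """
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, fc - rot @ mc


def _collinear_alternatives(
    moving: np.ndarray, fixed: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate proper rotations for the fit, covering the collinear case.

    With collinear correspondences the optimal rotation is unique only up to
    a half-turn about the line axis; both solutions have identical matched
    residuals but can transform the remaining ligand atoms differently, so
    both are checked.
    """
    rot, t = kabsch(moving, fixed)
    centered = fixed - fixed.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) >= 2 and s[1] > 1e-8 * max(s[0], 1.0):
        return [(rot, t)]
    axis = vt[0]
    # proper half-turn about the degenerate axis (Rodrigues at angle pi)
    half_turn = 2.0 * np.outer(axis, axis) - np.eye(3)
    rot2 = half_turn @ rot
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    return [(rot, t), (rot2, fc - rot2 @ mc)]


# ---------------------------------------------------------------------------
# Exclusion volumes
# ---------------------------------------------------------------------------


def clash_check(points: np.ndarray, xvols: list[ExclusionVolume]) -> bool:
    """True iff any point lies strictly inside any exclusion sphere."""
    if len(xvols) == 0 or len(points) == 0:
        return False
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    centers = np.array([x.center for x in xvols])
    radii = np.array([x.radius for x in xvols])
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    return bool(np.any(d < radii[None, :]))


# ---------------------------------------------------------------------------
# Correspondence search
# ---------------------------------------------------------------------------


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _direction_ok(
    model_feature, ligand_dir: np.ndarray | None, rot: np.ndarray, params: MatchParams
) -> bool:
    if not params.check_directions:
        return True
    if model_feature.direction is None or ligand_dir is None:
        return True
    tol = (
        model_feature.angle_tol
        if model_feature.angle_tol is not None
        else params.default_angle_tol
    )
    ang = _angle_deg(model_feature.direction, rot @ ligand_dir)
    if model_feature.kind == FeatureKind.AI:
        ang = min(ang, 180.0 - ang)  # ring normals are axes, sign-ambiguous
    return ang <= tol


def _evaluate_assignment(
    model: PharmacophoreModel,
    fs: FeatureSet,
    heavy: np.ndarray,
    assignment: dict[int, int],
    params: MatchParams,
) -> tuple[bool, bool, dict[int, float], float, np.ndarray, np.ndarray]:
    """Fit one assignment; returns (accepted, clash, residuals, score, R, t)."""
    idx_m = sorted(assignment)
    moving = np.array([fs.features[assignment[i]].position for i in idx_m])
    fixed = np.array([model.features[i].center for i in idx_m])
    best = None
    for rot, t in _collinear_alternatives(moving, fixed):
        transformed = moving @ rot.T + t
        residuals = {
            i: float(np.linalg.norm(transformed[k] - model.features[i].center))
            for k, i in enumerate(idx_m)
        }
        within = all(residuals[i] <= model.features[i].radius for i in idx_m)
        dirs_ok = within and all(
            _direction_ok(model.features[i], fs.features[assignment[i]].direction, rot, params)
            for i in idx_m
        )
        clash = False
        if within and dirs_ok and model.xvols:
            clash = clash_check(heavy @ rot.T + t, model.xvols)
        accepted = within and dirs_ok and not clash
        score = float(
            np.mean(
                [
                    max(0.0, 1.0 - residuals[i] / model.features[i].radius)
                    for i in idx_m
                ]
            )
        )
        cand = (accepted, clash, residuals, score, rot, t)
        if best is None or (accepted, score) > (best[0], best[3]):
            best = cand
    return best


def match_feature_set(
    model: PharmacophoreModel,
    fs: FeatureSet,
    heavy_atom_coords: np.ndarray | None = None,
    params: MatchParams = DEFAULT_PARAMS,
) -> MatchResult:
    """Match one conformer's feature set against one model.

    Among acceptable assignments, the one maximizing the fit score
    ``mean(1 - residual / radius)`` wins; exact ties break to the
    lexicographically smallest correspondence.  When nothing is acceptable,
    the best failed attempt's score and residuals are reported with
    ``matched=False``.
    """
    heavy = (
        np.asarray(heavy_atom_coords, dtype=float).reshape(-1, 3)
        if heavy_atom_coords is not None
        else np.empty((0, 3))
    )
    result = MatchResult(False, model.id, fs.molecule_id, fs.conformer_index)

    k = len(model.features)
    max_omitted = params.max_omitted if params.max_omitted is not None else model.max_omitted
    min_matched = max(MIN_MATCHED_FEATURES, k - max_omitted)
    if k < MIN_MATCHED_FEATURES or len(fs.features) == 0:
        return result

    # candidate ligand features per model feature, kind-compatible
    candidates: list[list[int]] = [
        [j for j, lf in enumerate(fs.features) if lf.kind == mf.kind]
        for mf in model.features
    ]
    lig_pos = fs.positions()
    model_pos = model.feature_centers
    d_model = np.linalg.norm(model_pos[:, None] - model_pos[None, :], axis=2)
    d_lig = np.linalg.norm(lig_pos[:, None] - lig_pos[None, :], axis=2)
    radii = np.array([f.radius for f in model.features])

    best_key: tuple | None = None  # (-score, sorted correspondence items)
    best_eval = None
    best_assignment: dict[int, int] | None = None
    best_failed_key: tuple | None = None
    best_failed = None
    best_failed_assignment: dict[int, int] | None = None

    def consider(assignment: dict[int, int]):
        nonlocal best_key, best_eval, best_assignment
        nonlocal best_failed_key, best_failed, best_failed_assignment
        ev = _evaluate_assignment(model, fs, heavy, assignment, params)
        accepted, clash, residuals, score, rot, t = ev
        key = (-score, tuple(sorted(assignment.items())))
        if accepted:
            if best_key is None or key < best_key:
                best_key, best_eval, best_assignment = key, ev, dict(assignment)
        else:
            if best_failed_key is None or key < best_failed_key:
                best_failed_key, best_failed, best_failed_assignment = key, ev, dict(assignment)

    def search(mi: int, assignment: dict[int, int], used: set[int], omitted: int):
        if mi == k:
            if len(assignment) >= min_matched:
                consider(assignment)
            return
        # prune: even assigning every remaining feature cannot reach min_matched
        if len(assignment) + (k - mi) < min_matched:
            return
        for j in candidates[mi]:
            if j in used:
                continue
            ok = True
            for pi, pj in assignment.items():
                if abs(d_model[mi, pi] - d_lig[j, pj]) > radii[mi] + radii[pi]:
                    ok = False
                    break
            if ok:
                assignment[mi] = j
                used.add(j)
                search(mi + 1, assignment, used, omitted)
                used.discard(j)
                del assignment[mi]
        if omitted < max_omitted:
            search(mi + 1, assignment, used, omitted + 1)

    search(0, {}, set(), 0)

    chosen = best_eval if best_eval is not None else best_failed
    chosen_assignment = best_assignment if best_eval is not None else best_failed_assignment
    if chosen is None:
        return result
    accepted, clash, residuals, score, rot, t = chosen
    result.matched = accepted
    result.correspondence = dict(sorted(chosen_assignment.items()))
    result.rotation = rot
    result.translation = t
    result.residuals = residuals
    result.clash = clash
    result.score = score
    return result


def screen_molecule(
    model: PharmacophoreModel,
    molecule,
    params: MatchParams = DEFAULT_PARAMS,
    rules=None,
) -> MatchResult:
    """Match every conformer of a molecule; return the best result.

    Preference order: matched over unmatched, then higher score, then lower
    conformer index (deterministic).  Raises if the molecule carries no
    conformers — run conformer generation first.
    """
    from pharmscreen.perception import DEFAULT_RULES

    if molecule.num_conformers == 0:
        raise ValueError(
            f"molecule {molecule.id!r} has no conformers; run generate_conformers first"
        )
    rules = rules if rules is not None else DEFAULT_RULES
    best: MatchResult | None = None
    for ci in range(molecule.num_conformers):
        fs = perceive_features(molecule, ci, rules)
        res = match_feature_set(model, fs, molecule.heavy_atom_coords(ci), params)
        if best is None or (res.matched, res.score) > (best.matched, best.score):
            best = res
    return best
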