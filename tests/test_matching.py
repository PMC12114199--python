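"""Matching: self-match, rigid invariance, clash rejection, and equivalence of
the pruned correspondence search with an exhaustive brute-force oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmscreen.matching import (
    MatchParams,
    clash_check,
    kabsch,
    match_feature_set,
    screen_molecule,
)
from pharmscreen.model import (
    ExclusionVolume,
    FeatureKind,
    ModelFeature,
    ModelOrigin,
    PharmacophoreModel,
)
from pharmscreen.perception import FeatureSet, LigandFeature, perceive_features

from conftest import self_model


def random_rigid(rng):
    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-10, 10, 3)


def move_featureset(fs, rot, t):
    return FeatureSet(fs.molecule_id, fs.conformer_index, [
        LigandFeature(f.kind, rot @ f.position + t,
                      rot @ f.direction if f.direction is not None else None,
                      f.atom_indices)
        for f in fs.features
    ])


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------


class TestKabsch:
    def test_recovers_random_rigid_motions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(-5, 5, (6, 3))
            rot, t = random_rigid(rng)
            moved = pts @ rot.T + t
            r_est, t_est = kabsch(moved, pts)
            np.testing.assert_allclose(moved @ r_est.T + t_est, pts, atol=1e-9)
            assert np.linalg.det(r_est) == pytest.approx(1.0)

    def test_matches_scipy_alignment(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (5, 3))
        noisy = pts + rng.normal(0, 0.3, pts.shape)
        r_est, t_est = kabsch(noisy, pts)
        rot_ref, _ = Rotation.align_vectors(pts - pts.mean(0), noisy - noisy.mean(0))
        np.testing.assert_allclose(r_est, rot_ref.as_matrix(), atol=1e-8)

    def test_rejects_reflections(self):
        # mirror-image points: best proper rotation must keep det = +1
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirrored = pts * [1, 1, -1]
        r_est, _ = kabsch(mirrored, pts)
        assert np.linalg.det(r_est) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Exclusion volumes
# ---------------------------------------------------------------------------


class TestClashCheck:
    def test_boundary_is_strict(self):
        xv = [ExclusionVolume([0, 0, 0], 1.0)]
        assert not clash_check(np.array([[1.0, 0.0, 0.0]]), xv)  # on surface
        assert clash_check(np.array([[0.0, 0.0, 0.0]]), xv)  # at center
        assert clash_check(np.array([[0.99, 0.0, 0.0]]), xv)

    def test_empty_xvols_never_clash(self):
        assert not clash_check(np.zeros((5, 3)), [])


# ---------------------------------------------------------------------------
# match_feature_set
# ---------------------------------------------------------------------------


class TestSelfMatch:
    def test_self_match_perfect_score(self, phenol):
        model = self_model(phenol)
        fs = perceive_features(phenol)
        res = match_feature_set(model, fs, phenol.heavy_atom_coords(0))
        assert res.matched
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert max(res.residuals.values()) < 1e-9

    def test_rigid_invariance_and_inverse_transform(self, phenol):
        model = self_model(phenol)
        fs = perceive_features(phenol)
        base = match_feature_set(model, fs, phenol.heavy_atom_coords(0))
        rng = np.random.default_rng(42)
        for _ in range(50):
            rot, t = random_rigid(rng)
            moved = move_featureset(fs, rot, t)
            coords = phenol.heavy_atom_coords(0) @ rot.T + t
            res = match_feature_set(model, moved, coords)
            assert res.matched == base.matched
            assert res.score == pytest.approx(base.score, abs=1e-6)
            # the recovered transform inverts the applied motion
            np.testing.assert_allclose(res.rotation @ rot, np.eye(3), atol=1e-6)

    def test_xvol_on_ligand_atom_forces_clash(self, phenol):
        fs = perceive_features(phenol)
        heavy = phenol.heavy_atom_coords(0)
        # xvol centered on a heavy atom far from every feature sphere is
        # guaranteed to swallow that atom in the model frame
        model = self_model(phenol, xvols=[ExclusionVolume(heavy[3], 1.0)])
        res = match_feature_set(model, fs, heavy)
        assert not res.matched
        assert res.clash

    def test_empty_feature_set_unmatched(self, phenol):
        model = self_model(phenol)
        res = match_feature_set(model, FeatureSet("x", 0, []), np.zeros((1, 3)))
        assert not res.matched and res.score == 0.0

    def test_kind_mismatch_unmatched_not_error(self, phenol):
        model = self_model(phenol)
        fs = FeatureSet("x", 0, [
            LigandFeature(FeatureKind.HC, [float(i), 0, 0], None, (i,)) for i in range(4)
        ])
        res = match_feature_set(model, fs, np.zeros((1, 3)))
        assert not res.matched


class TestMonotonicity:
    def _near_miss(self, rng):
        """A model and a jittered copy of its layout (may or may not match)."""
        kinds = [FeatureKind.HBA, FeatureKind.HBD, FeatureKind.HC, FeatureKind.AI]
        centers = rng.uniform(-4, 4, (4, 3))
        model = PharmacophoreModel(
            "m", "other", ModelOrigin("ligand_based"),
            [ModelFeature(k, c, 1.0) for k, c in zip(kinds, centers)],
        )
        fs = FeatureSet("lig", 0, [
            LigandFeature(k, c + rng.normal(0, 0.8, 3), None, (i,))
            for i, (k, c) in enumerate(zip(kinds, centers))
        ])
        return model, fs

    def test_enlarging_radii_never_unmatches(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            model, fs = self._near_miss(rng)
            res = match_feature_set(model, fs, fs.positions())
            bigger = PharmacophoreModel(
                model.id, model.target, model.origin,
                [ModelFeature(f.kind, f.center, f.radius * 2.0) for f in model.features],
            )
            res2 = match_feature_set(bigger, fs, fs.positions())
            if res.matched:
                assert res2.matched

    def test_adding_xvol_never_creates_match(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            model, fs = self._near_miss(rng)
            res = match_feature_set(model, fs, fs.positions())
            blocked = PharmacophoreModel(
                model.id, model.target, model.origin, model.features,
                xvols=[ExclusionVolume(rng.uniform(-4, 4, 3), 1.5)],
            )
            res2 = match_feature_set(blocked, fs, fs.positions())
            if not res.matched:
                assert not res2.matched


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------


def oracle_best(model, fs, heavy, params):
    """Exhaustive search over all injective kind-compatible full assignments,
    with the rigid fit done independently through scipy."""
    k = len(model.features)
    lig_idx = list(range(len(fs.features)))
    best = None  # (matched, score)
    for perm in itertools.permutations(lig_idx, k):
        if any(fs.features[j].kind != model.features[i].kind for i, j in enumerate(perm)):
            continue
        moving = np.array([fs.features[j].position for j in perm])
        fixed = np.array([f.center for f in model.features])
        mc, fc = moving.mean(0), fixed.mean(0)
        rot_obj, _ = Rotation.align_vectors(fixed - fc, moving - mc)
        rot = rot_obj.as_matrix()
        t = fc - rot @ mc
        moved = moving @ rot.T + t
        residuals = np.linalg.norm(moved - fixed, axis=1)
        radii = np.array([f.radius for f in model.features])
        ok = bool(np.all(residuals <= radii))
        if ok:
            for i, j in enumerate(perm):
                mf, lf = model.features[i], fs.features[j]
                if mf.direction is None or lf.direction is None:
                    continue
                tol = mf.angle_tol if mf.angle_tol is not None else params.default_angle_tol
                ang = math.degrees(
                    math.acos(np.clip(mf.direction @ (rot @ lf.direction), -1, 1))
                )
                if mf.kind == FeatureKind.AI:
                    ang = min(ang, 180 - ang)
                if ang > tol:
                    ok = False
                    break
        if ok and model.xvols:
            ok = not clash_check(heavy @ rot.T + t, model.xvols)
        score = float(np.mean(np.clip(1 - residuals / radii, 0, None)))
        cand = (ok, score)
        if best is None or cand > best:
            best = cand
    return best if best is not None else (False, 0.0)


def test_pruned_search_equals_exhaustive_enumeration():
    """>= 100 random instances, <= 5 model features, <= 8 ligand features."""
    rng = np.random.default_rng(12345)
    params = MatchParams()
    n_checked = 0
    for trial in range(120):
        k = int(rng.integers(3, 6))
        n = int(rng.integers(k, 9))
        kinds = [FeatureKind(rng.choice(["HBD", "HBA", "HC", "AI"])) for _ in range(n)]
        centers = rng.uniform(-5, 5, (k, 3))
        radii = rng.uniform(0.8, 1.8, k)
        model = PharmacophoreModel(
            "m", "other", ModelOrigin("ligand_based"),
            [ModelFeature(kinds[i], centers[i], radii[i]) for i in range(k)],
            xvols=[ExclusionVolume(rng.uniform(-5, 5, 3), 1.0)] if trial % 3 == 0 else [],
        )
        # ligand: jittered copies of the model layout plus distractors
        positions = np.vstack([
            centers + rng.normal(0, 0.6, centers.shape),
            rng.uniform(-5, 5, (n - k, 3)),
        ])
        rot, t = random_rigid(rng)
        fs = FeatureSet("lig", 0, [
            LigandFeature(kinds[i % n], rot @ positions[i] + t, None, (i,))
            for i in range(n)
        ])
        heavy = positions @ rot.T + t
        res = match_feature_set(model, fs, heavy, params)
        want_matched, want_score = oracle_best(model, fs, heavy, params)
        assert res.matched == want_matched, f"trial {trial}"
        if want_matched:
            assert res.score == pytest.approx(want_score, abs=1e-9), f"trial {trial}"
        n_checked += 1
    assert n_checked >= 100


# ---------------------------------------------------------------------------
# screen_molecule
# ---------------------------------------------------------------------------


class TestScreenMolecule:
    def test_single_conformer_self_match(self, phenol):
        res = screen_molecule(self_model(phenol), phenol)
        assert res.matched and res.score == pytest.approx(1.0, abs=1e-9)

    def test_best_conformer_selected(self):
        from conftest import embed

        mol = embed("OCCCC(=O)NCCc1ccccc1", "flexible", n_conf=8, seed=5)
        assert mol.num_conformers >= 4
        target_conf = 3
        model = self_model(mol, conformer=target_conf, radius=0.4)
        res = screen_molecule(model, mol)
        assert res.matched
        assert res.conformer_index == target_conf

    def test_all_conformers_failing_reports_best_score(self, phenol):
        fs = perceive_features(phenol)
        # model displaced far away in one feature: nothing matches
        feats = [
            ModelFeature(f.kind, f.position, 0.5) for f in fs.features
        ]
        feats[0] = ModelFeature(feats[0].kind, feats[0].center + 50.0, 0.5)
        model = PharmacophoreModel("off", "other", ModelOrigin("ligand_based"), feats)
        res = screen_molecule(model, phenol)
        assert not res.matched
        assert 0.0 <= res.score < 1.0

    def test_zero_conformers_raises_instructive_error(self):
        from rdkit import Chem
        from pharmscreen.chem_io import Molecule

        bare = Molecule("flat", Chem.MolFromSmiles("CCO"))
        model = simple = self_model_placeholder()
        with pytest.raises(ValueError, match="generate_conformers"):
            screen_molecule(model, bare)


def self_model_placeholder():
    return PharmacophoreModel(
        "p", "other", ModelOrigin("ligand_based"),
        [ModelFeature(FeatureKind.HC, [float(i), 0, 0], 1.5) for i in range(3)],
    )
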