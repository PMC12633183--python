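"""Toy rigid docker, merged scoring and candidate ranking."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from synthscreen.capselect import Pocket
from synthscreen.fixtures import PocketSpec, make_pocket
from synthscreen.scoring import (
    ScoreWeights,
    ScoredCandidate,
    merged_score,
    octahedral_rotations,
    rank_candidates,
    toy_dock,
)


def _methane():
    mol = Chem.AddHs(Chem.MolFromSmiles("C"))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return Chem.RemoveHs(mol)


def _ethanol():
    mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return Chem.RemoveHs(mol)


class TestToyDock:
    def test_single_atom_centers_in_shell(self):
        pocket, meta = make_pocket(PocketSpec(kind="shell", radius=4.0, spacing=1.0))
        pose = toy_dock(_methane(), pocket, grid_step=1.0)[0]
        # at the shell centre every shell atom sits in the contact band
        assert np.linalg.norm(pose.coords[0] - np.asarray(meta["center"])) <= 1.0
        assert pose.dock_score == -len(pocket.coords)

    def test_all_clash_still_returns_best(self):
        # a dense solid block searched without padding: every translation
        # leaves the single atom within 2.5 A of some block atom
        pocket = Pocket(
            coords=np.stack(
                np.meshgrid(*[np.arange(-3, 3.1, 1.0)] * 3, indexing="ij"), axis=-1
            ).reshape(-1, 3)
        )
        poses = toy_dock(_methane(), pocket, grid_step=1.0, padding=0.0)
        assert len(poses) == 1
        assert poses[0].dock_score > 0

    def test_repeat_call_bit_identical(self):
        pocket, _ = make_pocket(PocketSpec(kind="shell", radius=4.0, spacing=1.0))
        a = toy_dock(_ethanol(), pocket, grid_step=1.0, top_k=5)
        b = toy_dock(_ethanol(), pocket, grid_step=1.0, top_k=5)
        for pa, pb in zip(a, b):
            assert pa.dock_score == pb.dock_score
            assert np.array_equal(pa.coords, pb.coords)

    def test_score_invariant_under_joint_rigid_transform(self):
        # lattice-compatible rotations + arbitrary translation move the
        # pocket-anchored search grid rigidly with the system
        pocket, _ = make_pocket(PocketSpec(kind="shell", radius=4.0, spacing=1.2))
        mol = _ethanol()
        base = toy_dock(mol, pocket, grid_step=1.0)[0].dock_score
        rng = np.random.default_rng(4)
        # axis-permutation rotations without sign flips keep the
        # bounding-box-anchored grid rigidly attached to the system
        perms = ((0, 1, 2), (1, 2, 0), (2, 0, 1))
        for perm in perms:
            rot = np.eye(3)[list(perm)]
            t = rng.uniform(-5, 5, size=3)
            pocket2 = Pocket(coords=pocket.coords @ rot.T + t)
            mol2 = Chem.Mol(mol)
            conf = mol2.GetConformer()
            for i in range(mol2.GetNumAtoms()):
                p = np.array(list(conf.GetAtomPosition(i)))
                conf.SetAtomPosition(i, (rot @ p + t).tolist())
            assert toy_dock(mol2, pocket2, grid_step=1.0)[0].dock_score == base

    def test_empty_conformer_rejected(self):
        pocket, _ = make_pocket(PocketSpec(kind="shell", radius=4.0, spacing=1.0))
        with pytest.raises(ValueError):
            toy_dock(Chem.MolFromSmiles("CC"), pocket)

    def test_octahedral_rotation_group(self):
        rots = octahedral_rotations()
        assert rots.shape == (24, 3, 3)
        assert np.allclose([np.linalg.det(r) for r in rots], 1.0)
        assert len({tuple(r.ravel()) for r in rots}) == 24


class TestMergedScore:
    def test_zero_cap_score_reduces_to_dock(self):
        assert merged_score(-12.5, 0) == 12.5

    def test_monotone_in_cap_score(self):
        assert merged_score(-30.0, 5) > merged_score(-30.0, 2)

    def test_direct_substitution(self):
        assert merged_score(-30.0, 3, ScoreWeights(w_cap=1.0)) == pytest.approx(
            30.0 + math.log(4.0)
        )

    def test_negative_cap_score_rejected(self):
        with pytest.raises(ValueError):
            merged_score(-10.0, -1)


def _cand(ref, dock, cap, productive=True, w=ScoreWeights()):
    return ScoredCandidate(
        fragment_ref=ref,
        dock_score=dock,
        cap_score=cap,
        merged_score=merged_score(dock, cap, w),
        productive=productive,
    )


class TestRankCandidates:
    def test_capselect_drops_unproductive(self):
        cands = [
            _cand("a", -30, 0, productive=False),
            _cand("b", -20, 4),
            _cand("c", -25, 2),
        ]
        ranked = rank_candidates(cands, "capselect")
        assert [c.fragment_ref for c in ranked] == ["c", "b"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_all_unproductive_yields_empty_list(self):
        cands = [_cand("a", -30, 0, productive=False)]
        assert rank_candidates(cands, "capselect") == []

    def test_greedy_ignores_cap_scores(self):
        base = [_cand("a", -30, 1, False), _cand("b", -20, 9), _cand("c", -25, 3)]
        permuted = [
            _cand("a", -30, 3, False),
            _cand("b", -20, 1),
            _cand("c", -25, 9),
        ]
        order = lambda cs: [c.fragment_ref for c in rank_candidates(cs, "greedy")]
        assert order(base) == order(permuted) == ["a", "c", "b"]

    def test_top_k_overlap_differs_between_modes(self):
        # a top-docking dead-end fragment: present in the greedy top-2,
        # absent from the growth-aware top-2
        cands = [
            _cand("dead", -35, 0, productive=False),
            _cand("good1", -30, 5),
            _cand("good2", -29, 4),
            _cand("weak", -15, 1, productive=False),
        ]
        top_greedy = {c.fragment_ref for c in rank_candidates(cands, "greedy")[:2]}
        top_cap = {c.fragment_ref for c in rank_candidates(cands, "capselect")[:2]}
        assert top_greedy != top_cap
        assert len(top_greedy & top_cap) < 2

    def test_weightless_merged_score_matches_greedy_on_productive(self):
        w = ScoreWeights(w_cap=0.0)
        cands = [_cand(r, d, c, w=w) for r, d, c in
                 [("a", -30, 1), ("b", -20, 9), ("c", -25, 3)]]
        greedy = [c.fragment_ref for c in rank_candidates(cands, "greedy")]
        cap = [c.fragment_ref for c in rank_candidates(cands, "capselect")]
        assert greedy == cap

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            rank_candidates([], "greedy")
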