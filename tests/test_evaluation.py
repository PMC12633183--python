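"""RMSD machinery, stage reports, baseline sampling and enrichment factors."""

import numpy as np
import pytest

from synthscreen.evaluation import (
    AtomMapping,
    PoseRecord,
    enrichment_factor,
    pose_rmsd,
    rmsd_stage_report,
    rmsd_stats,
    sample_baseline,
)
from synthscreen.fixtures import LibrarySpec, make_toy_library

from _oracles import oracle_rmsd


def _mapping(n):
    return AtomMapping(pairs=tuple((i, i) for i in range(n)))


class TestPoseRmsd:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        assert pose_rmsd(x, x.copy(), _mapping(8)) == 0.0

    def test_uniform_translation_no_fitting(self):
        # in-place RMSD: a 3 A shift reads as exactly 3 A (no superposition)
        x = np.random.default_rng(1).normal(size=(6, 3))
        assert pose_rmsd(x, x + np.array([3.0, 0, 0]), _mapping(6)) == pytest.approx(
            3.0, abs=1e-12
        )

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        xa = rng.normal(size=(10, 3))
        xb = rng.normal(size=(10, 3))
        pairs = tuple((i, 9 - i) for i in range(10))
        m = AtomMapping(pairs=pairs)
        assert pose_rmsd(xa, xb, m) == pytest.approx(
            oracle_rmsd(xa, xb, pairs), abs=1e-12
        )

    def test_short_mapping_rejected(self):
        x = np.zeros((5, 3))
        with pytest.raises(ValueError):
            pose_rmsd(x, x, _mapping(2))

    def test_out_of_range_mapping_rejected(self):
        x = np.zeros((3, 3))
        with pytest.raises(IndexError):
            pose_rmsd(x, x, AtomMapping(pairs=((0, 0), (1, 1), (2, 9))))

    def test_mapping_excludes_cap_atoms_of_a(self):
        origins_a = ["core:0", "cap:2:0", "syn:1:s1:0"]
        origins_b = ["core:0", "syn:1:s1:0", "cap:2:0", "syn:2:s9:0"]
        m = AtomMapping.from_origins(origins_a, origins_b)
        assert m.pairs == ((0, 0), (2, 1))


class TestRmsdStats:
    def test_hand_computed_quartiles(self):
        s = rmsd_stats([1.0, 2.0, 3.0, 4.0, 5.0])
        assert s.median == 3.0
        assert s.iqr == 2.0
        assert s.pct_below_3A == 40.0  # strict inequality
        assert s.n == 5

    def test_degenerate_all_zero(self):
        s = rmsd_stats([0.0] * 7)
        assert (s.median, s.iqr, s.pct_below_3A) == (0.0, 0.0, 100.0)

    def test_uniform_draws_distributional(self):
        v = np.random.default_rng(3).uniform(0, 6, size=10_000)
        s = rmsd_stats(v)
        assert s.median == pytest.approx(3.0, abs=0.15)
        assert s.pct_below_3A == pytest.approx(50.0, abs=2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd_stats([])


def _record(ref, coords, origins, parent=None, root=None, score=-10.0):
    return PoseRecord(
        ref=ref,
        parent=parent,
        root=root,
        origins=origins,
        coords=np.asarray(coords, dtype=float),
        dock_score=score,
    )


class TestStageReport:
    def test_flip_surfaces_above_three_angstrom(self):
        # enumerated pose mirrored about x -> large in-place RMSD
        origins = ["core:0", "core:1", "syn:1:s:0", "cap:2:0"]
        coords = np.array(
            [[1.0, 0, 0], [2.0, 0.5, 0], [3.0, 1.0, 0.2], [4.0, 0, 0]]
        )
        mel = {"m": _record("m", coords, origins, root="m")}
        kept = origins[:3] + ["syn:2:t:0"]
        straight = np.vstack([coords[:3], [[5.0, 0, 0]]])
        flipped = straight.copy()
        flipped[:, 0] *= -1.0
        enum = {
            "ok": _record("ok", straight, kept, parent="m", root="m", score=-12.0),
            "flip": _record("flip", flipped, kept, parent="m", root="m", score=-11.0),
        }
        report = rmsd_stage_report(mel, enum)
        vals = report["mel_vs_enum1"]
        assert len(vals) == 2
        assert min(vals) == pytest.approx(0.0, abs=1e-12)
        assert max(vals) > 3.0
        assert rmsd_stats(vals).pct_below_3A == 50.0

    def test_broken_provenance_skipped_with_tally(self, caplog):
        origins = ["core:0", "core:1", "core:2"]
        coords = np.zeros((3, 3))
        mel = {"m": _record("m", coords, origins, root="m")}
        enum = {
            "orphan": _record("orphan", coords, origins, parent="gone", root="gone")
        }
        with caplog.at_level("WARNING"):
            report = rmsd_stage_report(mel, enum)
        assert report["mel_vs_enum1"] == []
        assert "skipped" in caplog.text

    def test_three_stage_report_keys(self):
        origins = ["core:0", "core:1", "core:2"]
        coords = np.eye(3)
        mel = {"m": _record("m", coords, origins, root="m")}
        e1 = {"i": _record("i", coords, origins, parent="m", root="m")}
        e2 = {"f": _record("f", coords, origins, parent="i", root="m")}
        report = rmsd_stage_report(mel, e1, e2)
        assert set(report) == {"mel_vs_enum1", "enum1_vs_enum2", "mel_vs_enum2"}
        assert all(v == [0.0] for v in report.values())


@pytest.fixture(scope="module")
def baseline_lib():
    return make_toy_library(
        LibrarySpec(two_component=((4, 5),), three_component=(), seed=5)
    )


class TestSampleBaseline:

    def test_self_matching_histogram(self, baseline_lib):
        from synthscreen.chem_space import enumerate_full_space

        pool = enumerate_full_space(baseline_lib)
        sample = sample_baseline(baseline_lib, n=len(pool), reference=[m for _, m in pool], seed=0)
        ref_counts = {}
        got_counts = {}
        for _, m in pool:
            ref_counts[m.GetNumHeavyAtoms() // 2] = (
                ref_counts.get(m.GetNumHeavyAtoms() // 2, 0) + 1
            )
        for _, m in sample:
            got_counts[m.GetNumHeavyAtoms() // 2] = (
                got_counts.get(m.GetNumHeavyAtoms() // 2, 0) + 1
            )
        for b in ref_counts:
            assert abs(ref_counts[b] - got_counts.get(b, 0)) <= 1

    def test_zero_sample(self, baseline_lib):
        assert sample_baseline(baseline_lib, 0, reference=[], seed=0) == []

    def test_seeded_reproducibility(self, baseline_lib):
        from synthscreen.chem_space import enumerate_full_space

        ref = [m for _, m in enumerate_full_space(baseline_lib)][:5]
        a = sample_baseline(baseline_lib, 8, ref, seed=9)
        b = sample_baseline(baseline_lib, 8, ref, seed=9)
        assert [i for i, _ in a] == [i for i, _ in b]


class TestEnrichmentFactor:
    def test_identical_sets_give_unity(self):
        scores = [-5.0, -4.0, -3.0, -2.0]
        for T in (1, 2, 4):
            r = enrichment_factor(scores, list(scores), T)
            assert r.ef == 1.0
            assert not r.censored

    def test_hand_counted_small_case(self):
        r = enrichment_factor([-5.0, -4.0], [-5.0, -3.0], T=1)
        assert r.score_cutoff == -5.0
        assert (r.hits_test, r.hits_baseline) == (1, 1)
        assert r.ef == 1.0

    def test_censored_lower_bound(self):
        r = enrichment_factor([-10.0, -9.0, -8.0, -1.0], [-1.0] * 4, T=1)
        assert r.censored
        assert r.hits_baseline == 0
        assert r.ef == pytest.approx((1 / 4) / (1 / 4))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        test = rng.normal(size=60)
        base = rng.normal(size=80)
        f = lambda s: np.sign(s) * np.abs(s) ** 3 - 2.0  # strictly increasing
        for T in (5, 20):
            a = enrichment_factor(test, base, T)
            b = enrichment_factor(f(test), f(base), T)
            assert (a.hits_test, a.hits_baseline, a.ef) == (
                b.hits_test,
                b.hits_baseline,
                b.ef,
            )

    def test_random_selection_enrichment_near_unity(self):
        rng = np.random.default_rng(7)
        efs = []
        for _ in range(40):
            pool = rng.normal(size=400)
            test = rng.choice(pool, size=200, replace=False)
            base = rng.choice(pool, size=200, replace=False)
            efs.append(enrichment_factor(test, base, T=20).ef)
        assert np.mean(efs) == pytest.approx(1.0, abs=0.15)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            enrichment_factor([-1.0], [-1.0], T=0)
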