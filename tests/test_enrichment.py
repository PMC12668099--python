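"""Matched-background construction and permutation enrichment rules."""

import numpy as np
import pandas as pd
import pytest

from cimtomics.enrichment import (MatchedBackground, default_schedule,
                                  geneset_enrichment, map_cpgs_to_genes,
                                  match_background, tfbs_enrichment)


def _universe(n=500, seed=0, chrom_count=5, spacing=20_000):
    rng = np.random.default_rng(seed)
    ids = [f"cg{i:05d}" for i in range(n)]
    per = -(-n // chrom_count)
    return pd.DataFrame({
        "mean": rng.uniform(0.1, 0.9, n),
        "sd": rng.uniform(0.02, 0.15, n),
        "chrom": [f"chr{1 + i // per}" for i in range(n)],
        "pos": [1_000_000 + (i % per) * spacing for i in range(n)],
    }, index=pd.Index(ids))


class TestMatchBackground:
    def test_schedule_expands_linearly(self):
        sched = default_schedule()
        assert sched[0] == (0.025, 0.0025)
        assert sched[-1] == (0.25, 0.025)
        assert len(sched) == 10

    def test_exact_twins_found_at_step_one(self):
        # a universe of exact moment twins beyond 5 kb matches tightly
        uni = _universe(300)
        uni["mean"] = 0.5
        uni["sd"] = 0.05
        bg = match_background(["cg00000"], uni, n_sets=100, seed=1)
        assert (bg.matching_log["mean_tol"] == 0.025).all()
        assert not bg.matching_log["with_replacement"].any()

    def test_distance_constraint_never_violated(self):
        uni = _universe(400)
        test = ["cg00000", "cg00150", "cg00399"]
        bg = match_background(test, uni, n_sets=50, seed=2)
        for j, cpg in enumerate(test):
            row = uni.loc[cpg]
            for s in bg.sets:
                other = uni.loc[s[j]]
                if other["chrom"] == row["chrom"]:
                    assert abs(other["pos"] - row["pos"]) > 5000

    def test_background_never_contains_test_cpgs(self):
        uni = _universe(300)
        test = ["cg00010", "cg00020"]
        bg = match_background(test, uni, n_sets=80, seed=3)
        for s in bg.sets:
            assert not set(s) & set(test)

    def test_tolerances_hold_at_reported_step(self):
        uni = _universe(600, seed=5)
        test = ["cg00007"]
        bg = match_background(test, uni, n_sets=30, seed=4)
        tol_m = bg.matching_log["mean_tol"].iloc[0]
        tol_s = bg.matching_log["sd_tol"].iloc[0]
        row = uni.loc["cg00007"]
        for s in bg.sets:
            other = uni.loc[s[0]]
            assert abs(other["mean"] - row["mean"]) <= tol_m + 1e-12
            assert abs(other["sd"] - row["sd"]) <= tol_s + 1e-12

    def test_nearby_twins_forced_to_looser_steps(self):
        # only moment twins within 5 kb: matching must relax tolerances
        uni = _universe(120, chrom_count=1, spacing=1000)
        uni["mean"] = np.linspace(0.1, 0.9, 120)
        uni["sd"] = 0.05
        test = ["cg00060"]
        bg = match_background(test, uni, n_sets=10, seed=0)
        assert bg.matching_log["mean_tol"].iloc[0] > 0.025

    def test_replacement_fallback_warns(self):
        uni = _universe(40)
        with pytest.warns(UserWarning, match="WITH replacement"):
            bg = match_background(["cg00000"], uni, n_sets=200, seed=1)
        assert bg.matching_log["with_replacement"].iloc[0]

    def test_universe_must_exceed_test_set(self):
        uni = _universe(5)
        with pytest.raises(ValueError, match="strictly larger"):
            match_background(list(uni.index), uni)

    def test_sets_are_size_matched_and_seeded(self):
        uni = _universe(300)
        test = ["cg00001", "cg00100"]
        a = match_background(test, uni, n_sets=25, seed=7)
        b = match_background(test, uni, n_sets=25, seed=7)
        assert a.sets == b.sets
        assert all(len(s) == len(test) for s in a.sets)

    def test_matching_preserves_moment_distribution(self):
        # matched sets should be statistically indistinguishable from
        # the test set in mean methylation (KS check over seeds)
        from scipy import stats
        uni = _universe(3000, seed=1)
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(10):
            test = list(rng.choice(uni.index, 40, replace=False))
            bg = match_background(test, uni, n_sets=30, seed=seed)
            bg_means = np.concatenate(
                [uni.loc[s, "mean"].to_numpy() for s in bg.sets])
            ps.append(stats.ks_2samp(uni.loc[test, "mean"], bg_means).pvalue)
        assert np.median(ps) > 0.01


class TestGeneMapping:
    def _pairs(self):
        return pd.DataFrame({
            "source": ["cg1", "cg1", "cg1", "cg2", "cg2"],
            "target": ["gA", "gB", "gC", "gA", "gD"],
            "p": [0.01, 0.02, 0.5, 0.001, 0.04]})

    def test_threshold_and_union_semantics(self):
        got = map_cpgs_to_genes(["cg1", "cg2"], self._pairs(), 0.05)
        assert got == {"gA", "gB", "gD"}  # gC filtered, gA de-duplicated

    def test_no_passing_pairs_empty(self):
        assert map_cpgs_to_genes(["cg9"], self._pairs()) == set()


class TestGenesetEnrichment:
    def test_test_set_equal_to_a_background_is_not_significant(self):
        test = {"g1", "g2", "g3"}
        bgs = [test, {"g4"}, {"g5"}]
        res = geneset_enrichment(test, bgs, {"path": {"g1", "g2"}})
        assert not res["significant"].iloc[0]

    def test_pathway_unique_to_test_set_is_significant(self):
        test = {"g1", "g2", "g3", "g4"}
        bgs = [{"x1"}, {"x2"}, {"x3"}]
        res = geneset_enrichment(test, bgs, {"path": {"g1", "g2", "g3"}})
        row = res.iloc[0]
        assert row["significant"] and row["empirical_p"] == 0.0
        assert row["fold_change"] == np.inf and not row["reported"]

    def test_fold_change_against_itself_is_one(self):
        test = {"g1", "g2"}
        res = geneset_enrichment(test, [test] * 10, {"path": {"g1"}})
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert not res["significant"].iloc[0]

    def test_empty_collections_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            geneset_enrichment({"g1"}, [{"g2"}], {})


class TestTfbsEnrichment:
    def _positions(self):
        return pd.DataFrame({"chrom": ["chr1"] * 4,
                             "pos": [100, 20_000, 40_000, 60_000]},
                            index=["cgA", "cgB", "cgC", "cgD"])

    def _bg(self, sets, test):
        return MatchedBackground(test_cpgs=test, sets=sets,
                                 matching_log=pd.DataFrame())

    def test_genome_wide_tf_is_never_significant(self):
        pos = self._positions()
        tf = {"TFall": [("chr1", 0, 1_000_000)]}
        bg = self._bg([["cgC", "cgD"]] * 5, ["cgA", "cgB"])
        res = tfbs_enrichment(["cgA", "cgB"], bg, pos, tf)
        assert res["observed"].iloc[0] == 2
        assert not res["significant"].iloc[0]
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_tf_covering_only_test_cpgs_is_significant(self):
        pos = self._positions()
        tf = {"TFtest": [("chr1", 90, 110), ("chr1", 19_990, 20_010)]}
        bg = self._bg([["cgC", "cgD"]] * 5, ["cgA", "cgB"])
        res = tfbs_enrichment(["cgA", "cgB"], bg, pos, tf)
        assert res["observed"].iloc[0] == 2
        assert res["significant"].iloc[0]

    def test_half_open_interval_convention(self):
        # 1-based point p overlaps [start, end) iff start <= p-1 < end
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [101, 100]},
                           index=["in", "out"])
        tf = {"TF": [("chr1", 100, 101)]}
        bg = self._bg([["out"]] * 3, ["in"])
        res = tfbs_enrichment(["in"], bg, pos, tf)
        assert res["observed"].iloc[0] == 1
        assert res["bg_mean"].iloc[0] == 0.0

    def test_malformed_interval_rejected(self):
        pos = self._positions()
        bg = self._bg([["cgC"]], ["cgA"])
        with pytest.raises(ValueError, match="malformed"):
            tfbs_enrichment(["cgA"], bg, pos, {"TF": [("chr1", 50, 50)]})
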