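"""Risk-score labelling, splitting, weighting, scoring and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_curve

from cimtomics import mrs
from cimtomics.synthetic import make_normative_table
from cimtomics.types import MrsModel, NormativeTable

from conftest import make_matrix


def _table(p75=0.8):
    return NormativeTable(pd.DataFrame({
        "age_lo": [30.0], "age_hi": [85.0], "sex": ["*"],
        "ethnicity": ["*"], "p75": [p75]}))


class TestLabelElevated:
    def _covs(self, n, age=50.0):
        return pd.DataFrame({"age": age, "sex": 0, "stratum": "Chinese"},
                            index=[f"s{i}" for i in range(n)])

    def test_at_threshold_counts_as_elevated(self):
        pheno = pd.Series([0.8, 0.79], index=["s0", "s1"])
        labels = mrs.label_elevated(pheno, self._covs(2), _table(0.8))
        assert labels.tolist() == [True, False]

    def test_all_below_threshold(self):
        pheno = pd.Series([0.5, 0.6], index=["s0", "s1"])
        assert not mrs.label_elevated(pheno, self._covs(2),
                                      _table(0.8)).any()

    def test_out_of_range_ages_excluded(self):
        pheno = pd.Series([0.9, 0.9], index=["s0", "s1"])
        covs = self._covs(2)
        covs.loc["s1", "age"] = 92.0
        labels = mrs.label_elevated(pheno, covs, _table())
        assert list(labels.index) == ["s0"]

    def test_unmapped_cell_is_error(self):
        table = NormativeTable(pd.DataFrame({
            "age_lo": [30.0], "age_hi": [85.0], "sex": [0],
            "ethnicity": ["Malay"], "p75": [0.8]}))
        pheno = pd.Series([0.9], index=["s0"])
        with pytest.raises(ValueError, match="no normative cell"):
            mrs.label_elevated(pheno, self._covs(1), table)

    def test_self_consistent_quarter_per_cell(self, small_cohort):
        table = make_normative_table(small_cohort)
        labels = mrs.label_elevated(small_cohort.phenotype,
                                    small_cohort.covariates, table)
        assert 0.17 <= labels.mean() <= 0.33


class TestStratifiedSplit:
    def test_single_stratum_70_30(self):
        ids = [f"s{i}" for i in range(100)]
        strata = pd.Series("all", index=ids)
        train, test = mrs.stratified_split(ids, strata, 0.7, seed=1)
        assert len(train) == 70 and len(test) == 30
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_paper_sized_split(self):
        # 1,353 samples, six joint strata -> 70/30 gives ~948/~405
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(1353)]
        eth = rng.choice(["Chinese", "Malay", "Indian"], 1353,
                         p=[0.78, 0.11, 0.11])
        elev = rng.random(1353) < 0.25
        strata = pd.Series([f"{e}|{x}" for e, x in zip(eth, elev)],
                           index=ids)
        train, test = mrs.stratified_split(ids, strata, 0.7, seed=0)
        assert abs(len(train) - 948) <= 6
        assert abs(len(test) - 405) <= 6

    def test_prevalence_balance_across_seeds(self):
        ids = [f"s{i}" for i in range(400)]
        strata = pd.Series(["A"] * 100 + ["B"] * 300, index=ids)
        for seed in range(20):
            train, test = mrs.stratified_split(ids, strata, 0.7, seed=seed)
            frac_a_train = sum(s < "s1" or len(s) == 2 for s in [])
            a_train = sum(1 for s in train if strata[s] == "A")
            a_test = sum(1 for s in test if strata[s] == "A")
            assert abs(a_train / len(train) - 0.25) < 0.01
            assert abs(a_test / len(test) - 0.25) < 0.01

    def test_singleton_stratum_goes_to_train(self):
        ids = ["a", "b", "c", "d", "lonely"]
        strata = pd.Series(["g1"] * 4 + ["g2"], index=ids)
        with pytest.warns(UserWarning, match="single sample"):
            train, _ = mrs.stratified_split(ids, strata, 0.7, seed=0)
        assert "lonely" in train

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(50)]
        strata = pd.Series("one", index=ids)
        a = mrs.stratified_split(ids, strata, 0.7, seed=9)
        b = mrs.stratified_split(ids, strata, 0.7, seed=9)
        assert a == b


class TestFitWeightsAndScore:
    def test_single_stratum_weight_equals_its_z(self, rng):
        n = 300
        beta = rng.uniform(0.2, 0.8, size=(n, 20))
        m = make_matrix(beta)
        pheno = pd.Series(np.exp(0.5 * beta[:, 0]
                                 + rng.normal(0, 0.05, n)),
                          index=m.sample_ids)
        covs = pd.DataFrame({"age": rng.uniform(30, 80, n),
                             "sex": rng.integers(0, 2, n),
                             "stratum": "Chinese"}, index=m.sample_ids)
        model = mrs.fit_weights(m, pheno, covs, ["cg000"], normalise=False)
        from cimtomics.ewas import run_ewas
        rec = run_ewas(m.subset_cpgs(["cg000"]), pheno, covs,
                       ["age", "sex"])
        z = float(np.sign(rec["effect"].iloc[0])
                  * stats.norm.isf(rec["p"].iloc[0] / 2))
        assert model.weights[0] == pytest.approx(z, abs=1e-6)

    def test_strong_effect_gets_positive_weight(self, small_cohort):
        model = mrs.fit_weights(
            small_cohort.methylation, small_cohort.phenotype,
            small_cohort.covariates, ["cg000002"])
        assert model.weights[0] > 3

    def test_zero_weights_score_zero(self, rng):
        m = make_matrix(rng.uniform(0.2, 0.8, size=(20, 5)))
        model = MrsModel(cpgs=["cg001", "cg003"], weights=[0.0, 0.0])
        assert (mrs.score(model, m) == 0).all()

    def test_score_linearity_in_weights(self, rng):
        m = make_matrix(rng.uniform(0.2, 0.8, size=(20, 5)))
        model1 = MrsModel(cpgs=["cg001", "cg003"], weights=[1.0, -2.0])
        model2 = MrsModel(cpgs=["cg001", "cg003"], weights=[2.0, -4.0])
        np.testing.assert_allclose(2 * mrs.score(model1, m),
                                   mrs.score(model2, m), atol=1e-12)

    def test_single_cpg_unit_weight_returns_normalised_beta(self, rng):
        m = make_matrix(rng.uniform(0.2, 0.8, size=(10, 6)))
        model = MrsModel(cpgs=["cg002"], weights=[1.0])
        from cimtomics.ewas import quantile_normalise
        expected = quantile_normalise(m).values["cg002"]
        np.testing.assert_allclose(mrs.score(model, m), expected, atol=1e-12)

    def test_missing_cpg_named_in_error(self, rng):
        m = make_matrix(rng.uniform(0.2, 0.8, size=(10, 3)))
        model = MrsModel(cpgs=["cg999"], weights=[1.0])
        with pytest.raises(KeyError, match="cg999"):
            mrs.score(model, m)

    def test_model_roundtrip(self):
        model = MrsModel(cpgs=["a", "b"], weights=[1.5, -0.5],
                         weight_mode="basic/z", seed=3)
        back = MrsModel.from_frame(model.to_frame())
        assert back.cpgs == model.cpgs
        np.testing.assert_allclose(back.weights, model.weights)


class TestAucAndDelong:
    def test_rank_auc_equals_trapezoid(self, rng):
        y = rng.random(400) < 0.3
        s = rng.standard_normal(400) + y
        fpr, tpr, _ = roc_curve(y, s)
        trap = np.trapezoid(tpr, fpr)
        assert mrs.auc_rank(y, s) == pytest.approx(trap, abs=1e-10)

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        assert mrs.auc_rank(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_delong_identical_scores_p_one(self, rng):
        y = rng.random(100) < 0.4
        s = rng.standard_normal(100)
        a1, a2, p = mrs.delong_test(y, s, s)
        assert a1 == a2 and p == 1.0

    def test_delong_detects_better_score(self, rng):
        y = rng.random(600) < 0.4
        good = y + rng.normal(0, 0.5, 600)
        noise = rng.standard_normal(600)
        a1, a2, p = mrs.delong_test(y, good, noise)
        assert a1 > a2 and p < 1e-6


class TestEvaluate:
    def _setup(self, seed, effect=1.5, n=500):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        covs = pd.DataFrame({
            "age": rng.uniform(30, 80, n), "sex": rng.integers(0, 2, n),
            "stratum": rng.choice(["Chinese", "Malay", "Indian"], n,
                                  p=[0.6, 0.2, 0.2]),
            "smoking": rng.choice(["never", "former", "current"], n)},
            index=ids)
        score = pd.Series(rng.standard_normal(n), index=ids)
        logits = -1.2 + effect * score.to_numpy()
        labels = pd.Series(
            rng.random(n) < 1 / (1 + np.exp(-logits)), index=ids)
        return score, labels, covs

    def test_informative_score_beats_demographics(self):
        score, labels, covs = self._setup(0)
        rep = mrs.evaluate(score, labels, covs)
        assert rep.auc["M1"][0] > rep.auc["M2"][0]
        assert rep.delong_p["M1_vs_M2"] < 0.01
        assert rep.quartile_or.loc[2, "quartile"] == "Q4"
        assert rep.quartile_or.loc[2, "or"] > 1
        assert rep.group_diff_p < 1e-4
        for name, (a, lo, hi) in rep.auc.items():
            assert lo <= a <= hi

    def test_single_class_labels_rejected(self):
        score, labels, covs = self._setup(1)
        with pytest.raises(ValueError, match="both"):
            mrs.evaluate(score, pd.Series(True, index=labels.index), covs)

    def test_null_score_shows_no_gain(self):
        score, labels, covs = self._setup(2, effect=0.0)
        rep = mrs.evaluate(score, labels, covs)
        assert abs(rep.auc["M1"][0] - rep.auc["M2"][0]) < 0.1
        assert rep.delong_p["M1_vs_M2"] > 0.001
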