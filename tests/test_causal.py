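"""Wald-ratio SMR and ABF colocalisation against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from cimtomics.causal import (coloc_abf, harmonise_alleles, p12_sensitivity,
                              smr_wald, wakefield_labf)
from cimtomics.synthetic import simulate_coloc_region


def _panel(betas, ses, snps=None):
    snps = snps or [f"rs{i}" for i in range(len(betas))]
    return pd.DataFrame({"snp": snps, "beta": betas, "se": ses})


def enumeration_pp(b1, s1, b2, s2, priors, sd1=0.15, sd2=0.15):
    """Independent oracle: sum posterior mass over every causal-SNP
    assignment configuration with plain products (no log-space)."""
    p1, p2, p12 = priors
    bf1 = [float(np.exp(wakefield_labf(b, s, sd1)))
           for b, s in zip(b1, s1)]
    bf2 = [float(np.exp(wakefield_labf(b, s, sd2)))
           for b, s in zip(b2, s2)]
    m = len(bf1)
    w = [1.0, 0.0, 0.0, 0.0, 0.0]
    for j in range(m):
        w[1] += p1 * bf1[j]
        w[2] += p2 * bf2[j]
        w[4] += p12 * bf1[j] * bf2[j]
        for k in range(m):
            if k != j:
                w[3] += p1 * p2 * bf1[j] * bf2[k]
    total = sum(w)
    return np.array(w) / total


class TestSmrWald:
    def test_ratio(self):
        res = smr_wald({"snp": "rs1", "beta": 0.5, "se": 0.05},
                       {"snp": "rs1", "beta": 0.25, "se": 0.05})
        assert res.beta_smr == pytest.approx(0.5)

    def test_null_outcome_gives_p_one(self):
        res = smr_wald({"snp": "rs1", "beta": 0.5, "se": 0.05},
                       {"snp": "rs1", "beta": 0.0, "se": 0.1})
        assert res.beta_smr == 0.0
        assert res.p_smr == pytest.approx(1.0)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ZeroDivisionError):
            smr_wald({"snp": "rs1", "beta": 0.0, "se": 0.05},
                     {"snp": "rs1", "beta": 0.1, "se": 0.1})

    def test_instrument_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            smr_wald({"snp": "rs1", "beta": 0.5, "se": 0.05},
                     {"snp": "rs2", "beta": 0.1, "se": 0.1})

    def test_delta_se_formula(self):
        be, se_e, bo, se_o = 0.4, 0.05, 0.12, 0.03
        res = smr_wald({"snp": "rs1", "beta": be, "se": se_e},
                       {"snp": "rs1", "beta": bo, "se": se_o})
        expected = abs(bo / be) * np.sqrt(se_o ** 2 / bo ** 2
                                          + se_e ** 2 / be ** 2)
        assert res.se_smr == pytest.approx(expected, abs=1e-12)

    def test_strong_instrument_limit_matches_outcome_z(self):
        # as se_exp -> 0 the SMR z-score converges to the outcome z-score
        z_out = 0.12 / 0.03
        for se_e in (1e-4, 1e-6, 1e-8):
            res = smr_wald({"snp": "rs1", "beta": 0.4, "se": se_e},
                           {"snp": "rs1", "beta": 0.12, "se": 0.03})
            z = res.beta_smr / res.se_smr
            assert z ** 2 == pytest.approx(z_out ** 2, rel=1e-4)

    def test_tsmr_statistic_agrees_asymptotically(self):
        res_d = smr_wald({"snp": "rs1", "beta": 0.4, "se": 0.01},
                         {"snp": "rs1", "beta": 0.05, "se": 0.02})
        res_t = smr_wald({"snp": "rs1", "beta": 0.4, "se": 0.01},
                         {"snp": "rs1", "beta": 0.05, "se": 0.02},
                         statistic="tsmr")
        assert res_d.p_smr == pytest.approx(res_t.p_smr, rel=0.05)

    def test_mediation_chain_recovery(self):
        # SNP -> methylation (0.4 / SD dosage) -> log-cIMT (0.1 / SD beta):
        # the Wald ratio targets the per-unit-beta slope of the CpG effect
        from cimtomics.qtl import cis_scan, select_instruments
        from cimtomics.synthetic import CohortSpec, simulate_cohort
        hits = 0
        for seed in range(10):
            spec = CohortSpec(n_per_stratum={"Chinese": 2000}, n_cpgs=12,
                              n_snps_per_region=15,
                              effect_table=[("snp01_008", "cg000001", 0.4),
                                            ("cg000001", "phenotype", 0.1)],
                              seed=seed)
            cohort = simulate_cohort(spec)
            truth = cohort.truth.set_index(["feature", "target"])
            target = truth.loc[("cg000001", "phenotype"), "slope_per_unit"]
            meqtl = cis_scan(cohort.genotypes, cohort.snp_positions,
                             cohort.methylation.values[["cg000001"]],
                             cohort.methylation.positions)
            inst = select_instruments(meqtl).iloc[0]
            y = np.log(cohort.phenotype.to_numpy())
            g = cohort.genotypes[inst["source"]].to_numpy()
            fit = stats.linregress(g, y)
            res = smr_wald(
                {"snp": inst["source"], "beta": inst["effect"],
                 "se": inst["se"]},
                {"snp": inst["source"], "beta": fit.slope,
                 "se": fit.stderr})
            hits += abs(res.beta_smr - target) < 3 * res.se_smr
        assert hits >= 9


class TestHarmonise:
    def _row(self, ea, oa, beta=0.1):
        return pd.Series({"snp": "rs1", "effect_allele": ea,
                          "other_allele": oa, "beta": beta, "se": 0.02})

    def test_matching_alleles_untouched(self):
        out = harmonise_alleles(self._row("A", "G"), self._row("A", "G"))
        assert out["beta"] == 0.1

    def test_swapped_alleles_flip_beta(self):
        out = harmonise_alleles(self._row("A", "G"), self._row("G", "A"))
        assert out["beta"] == -0.1

    def test_palindromic_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="palindromic"):
            assert harmonise_alleles(self._row("A", "T"),
                                     self._row("A", "T")) is None

    def test_mismatch_is_error(self):
        with pytest.raises(ValueError, match="allele mismatch"):
            harmonise_alleles(self._row("A", "G"), self._row("A", "C"))


class TestWakefield:
    def test_null_snp_is_penalised(self):
        assert wakefield_labf(0.0, 0.1, 0.15) < 0

    def test_vacuous_prior_limit(self):
        assert wakefield_labf(0.3, 0.1, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quadrature_oracle(self):
        # log BF = log of int N(bhat; b, V) N(b; 0, W) db / N(bhat; 0, V)
        beta, se, w = 0.1, 0.02, 0.15
        def integrand(b):
            return stats.norm.pdf(beta, b, se) * stats.norm.pdf(b, 0, w)
        marg, _ = integrate.quad(integrand, -2, 2)
        oracle = np.log(marg / stats.norm.pdf(beta, 0, se))
        assert wakefield_labf(beta, se, w) == pytest.approx(oracle, abs=1e-8)


class TestColocAbf:
    def test_posteriors_sum_to_one_and_match_enumeration(self, rng):
        for _ in range(25):
            m = int(rng.integers(2, 6))
            b1, b2 = rng.normal(0, 0.2, m), rng.normal(0, 0.2, m)
            s1, s2 = rng.uniform(0.02, 0.2, m), rng.uniform(0.02, 0.2, m)
            res = coloc_abf(_panel(b1, s1), _panel(b2, s2))
            assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
            oracle = enumeration_pp(b1, s1, b2, s2, res.priors)
            np.testing.assert_allclose(res.pp, oracle, atol=1e-9)

    def test_all_null_panels_favour_h0(self):
        m = 50
        res = coloc_abf(_panel(np.zeros(m), np.full(m, 0.01)),
                        _panel(np.zeros(m), np.full(m, 0.01)))
        assert res.pp[0] > 0.95 and res.call == "none"

    def test_snp_order_invariance(self, rng):
        m = 8
        b1, b2 = rng.normal(0, 0.3, m), rng.normal(0, 0.3, m)
        s = rng.uniform(0.01, 0.1, m)
        p1, p2 = _panel(b1, s), _panel(b2, s)
        res = coloc_abf(p1, p2)
        perm = rng.permutation(m)
        res_p = coloc_abf(p1.iloc[perm], p2.iloc[perm])
        np.testing.assert_allclose(res.pp, res_p.pp, atol=1e-12)

    def test_common_rescaling_of_one_panel_is_invariant_in_z(self, rng):
        # scaling betas and ses together preserves z; with the prior SD
        # scaled by the same factor the posteriors are unchanged
        m = 6
        b, s = rng.normal(0, 0.3, m), rng.uniform(0.02, 0.1, m)
        b2, s2 = rng.normal(0, 0.3, m), rng.uniform(0.02, 0.1, m)
        res = coloc_abf(_panel(b, s), _panel(b2, s2))
        res_scaled = coloc_abf(_panel(3 * b, 3 * s), _panel(b2, s2),
                               prior_sd1=3 * 0.15)
        np.testing.assert_allclose(res.pp, res_scaled.pp, atol=1e-10)

    def test_empty_intersection_names_both_panels(self):
        a = _panel([0.1, 0.2], [0.05, 0.05], snps=["rs1", "rs2"])
        b = _panel([0.1, 0.2], [0.05, 0.05], snps=["rs3", "rs4"])
        with pytest.raises(ValueError, match="panel1.*panel2"):
            coloc_abf(a, b)

    def test_invalid_priors_rejected(self):
        a = _panel([0.1, 0.2], [0.05, 0.05])
        with pytest.raises(ValueError, match="priors"):
            coloc_abf(a, a, priors=(1e-4, 1e-4, 1e-3))

    def test_h3_scenario_prefers_distinct_variants(self):
        wins = 0
        for seed in range(20):
            p1, p2 = simulate_coloc_region("H3", 3000, 3000, 100, seed,
                                           effect=0.4)
            res = coloc_abf(p1, p2)
            wins += res.pp[3] > res.pp[4]
        assert wins >= 15  # distinct variants dominate in most draws


class TestP12Sensitivity:
    def test_singleton_grid_equals_single_call(self, rng):
        m = 6
        p1 = _panel(rng.normal(0, 0.3, m), rng.uniform(0.02, 0.1, m))
        p2 = _panel(rng.normal(0, 0.3, m), rng.uniform(0.02, 0.1, m))
        results, _ = p12_sensitivity(p1, p2, [1e-5])
        single = coloc_abf(p1, p2)
        np.testing.assert_allclose(results[0].pp, single.pp, atol=1e-12)

    def test_h4_posterior_monotone_in_p12(self):
        p1, p2 = simulate_coloc_region("H4", 500, 500, 40, 3, effect=0.15)
        grid = np.geomspace(1e-6, 5e-5, 6)
        results, _ = p12_sensitivity(p1, p2, grid)
        h4 = [r.pp[4] for r in results]
        assert all(np.diff(h4) >= -1e-12)

    def test_strong_h4_is_robust_across_grid(self):
        p1, p2 = simulate_coloc_region("H4", 5000, 5000, 200, 1, effect=0.4)
        _, robust = p12_sensitivity(p1, p2, np.geomspace(1e-6, 9.9e-5, 8))
        assert robust

    def test_grid_outside_priors_rejected(self):
        p1, p2 = simulate_coloc_region("H0", 100, 100, 20, 0)
        with pytest.raises(ValueError, match="grid"):
            p12_sensitivity(p1, p2, [1e-3])
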