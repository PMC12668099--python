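"""Stratified EWAS of log-cIMT followed by the two-stage Stouffer screen.

Stage 1 pools the three discovery strata by sqrt(N)-weighted Stouffer;
CpGs below the stage-1 alpha that are measured in the replication
cohorts advance to the trans-ancestry stage, where the Bonferroni
threshold is alpha divided by the number of advanced CpGs. Sentinels
are the threshold-passers, at most one per chromosome.
"""

import dataclasses

from cimtomics.ewas import quantile_normalise, run_ewas
from cimtomics.meta import two_stage_screen
from cimtomics.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(
    n_per_stratum={"Chinese": 650, "Malay": 130, "Indian": 130},
    n_cpgs=400,
    effect_table=[("cg000010", "phenotype", 0.09),
                  ("cg000100", "phenotype", 0.09)],
    seed=3)
asian = simulate_cohort(spec)
european = simulate_cohort(dataclasses.replace(
    spec, n_per_stratum={"SHIP": 400, "NSHD": 300}, seed=4))


def per_stratum_ewas(cohort):
    meth = quantile_normalise(cohort.methylation)
    out = {}
    for name, members in cohort.covariates.groupby("stratum"):
        ids = members.index
        out[name] = run_ewas(meth.subset_samples(ids),
                             cohort.phenotype.loc[ids],
                             cohort.covariates.loc[ids],
                             ["age", "sex", "smoking"])
    return out


screen = two_stage_screen(per_stratum_ewas(asian), per_stratum_ewas(european),
                          stage1_alpha=0.05, bonferroni_base=0.05,
                          positions=asian.methylation.positions)
print(f"stage 1 CpGs with p<0.05: "
      f"{(screen.stage1['p'] < 0.05).sum()} of {len(screen.stage1)}")
print(f"advanced to trans-ancestry stage: {screen.n_advanced}")
print(f"Bonferroni threshold 0.05/{screen.n_advanced} = "
      f"{screen.threshold:.3g}")
print("sentinel CpGs (lowest p per chromosome below threshold):")
cols = ["feature", "z", "p", "n_total", "i2", "chrom"]
print(screen.sentinels[[c for c in cols
                        if c in screen.sentinels.columns]].to_string(
                            index=False))
# The two injected CpGs should surface as sentinels; z is the pooled
# Stouffer statistic and i2 the cross-study heterogeneity.
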