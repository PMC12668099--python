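"""Methylation risk score: derivation, scoring and evaluation.

The score is MRS = sum_i w_i b_i over the sentinel CpGs, where b_i is
the quantile-normalised beta value and w_i is, by default, the
Stouffer-combined z-score of the CpG from ethnicity-stratified
regressions of log-cIMT on the CpG (a pooled-coefficient mode is also
available). Elevated cIMT is defined as being at or above the age-,
sex- and ethnicity-specific 75th normative percentile. Evaluation uses
ROC/AUC with DeLong tests across nested logistic models and
quartile-based odds ratios.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import meta
from .ewas import build_design, quantile_normalise, run_ewas
from .types import MethylationMatrix, MrsModel, NormativeTable

logger = logging.getLogger(__name__)

__all__ = ["label_elevated", "stratified_split", "fit_weights", "score",
           "evaluate", "auc_rank", "delong_test", "EvaluationReport"]

BASIC_MODEL = ["age", "sex"]


def label_elevated(phenotype: pd.Series, covariates: pd.DataFrame,
                   normative: NormativeTable) -> pd.Series:
    """Boolean per-sample label: cIMT at or above the normative cell's P75.

    Samples whose age falls outside every table bin are excluded (their
    count is logged); a sample inside the age range with no matching
    sex/ethnicity cell is an error.
    """
    t = normative.table
    age_lo, age_hi = t["age_lo"].min(), t["age_hi"].max()
    labels, dropped = {}, 0
    for sid in phenotype.index:
        age = covariates.at[sid, "age"]
        if not (age_lo <= age < age_hi):
            dropped += 1
            continue
        thr = normative.lookup(age, covariates.at[sid, "sex"],
                               covariates.at[sid, "stratum"])
        if np.isnan(thr):
            raise ValueError(
                f"no normative cell for sample {sid}: age={age:.1f}, "
                f"sex={covariates.at[sid, 'sex']}, "
                f"ethnicity={covariates.at[sid, 'stratum']}")
        labels[sid] = bool(phenotype[sid] >= thr)
    if dropped:
        logger.info("excluded %d samples outside the normative age range",
                    dropped)
    return pd.Series(labels, name="elevated")


def stratified_split(sample_ids, strata: pd.Series, fraction: float = 0.7,
                     seed: int = 0) -> tuple[list, list]:
    """Disjoint, exhaustive train/test split stratified on joint labels.

    ``strata`` maps sample id to a joint stratum label (e.g. ethnicity
    x elevated). Train sizes use largest-remainder rounding: each
    stratum first gets floor(fraction * n) training samples, then the
    strata with the largest fractional remainders absorb the leftover
    so the total equals round(fraction * N). Size-1 strata go to train
    with a warning. The shuffle within strata is seeded.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    sample_ids = list(sample_ids)
    strata = strata.reindex(sample_ids)
    rng = np.random.default_rng(seed)
    groups = {k: list(v.index) for k, v in strata.groupby(strata, sort=True)}
    sizes = {k: len(v) for k, v in groups.items()}
    floors = {k: int(np.floor(fraction * n)) for k, n in sizes.items()}
    total_train = int(round(fraction * len(sample_ids)))
    leftover = total_train - sum(floors.values())
    remainders = sorted(groups, key=lambda k: (fraction * sizes[k])
                        - floors[k], reverse=True)
    for k in remainders[:max(leftover, 0)]:
        floors[k] += 1
    train, test = [], []
    for k, members in groups.items():
        if sizes[k] == 1:
            warnings.warn(f"stratum {k!r} has a single sample; kept in train")
            train += members
            continue
        members = list(members)
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n_tr = min(max(floors[k], 1), sizes[k] - 1)
        train += shuffled[:n_tr]
        test += shuffled[n_tr:]
    return train, test


def _comprehensive_model(covariates: pd.DataFrame) -> list[str]:
    extra = [c for c in covariates.columns
             if c.startswith("cell") or c.startswith("pc")]
    return ["age", "sex", "smoking"] + extra


def fit_weights(matrix: MethylationMatrix, phenotype: pd.Series,
                covariates: pd.DataFrame, sentinels: list[str],
                mode: str = "basic", weight_kind: str = "z",
                min_stratum: int = 20, seed: int | None = None,
                normalise: bool = True) -> MrsModel:
    """Derive per-CpG weights on the training set.

    Per ethnic stratum, log-cIMT is regressed on each sentinel CpG plus
    either age + sex (``basic``) or the full EWAS covariate set
    (``comprehensive``); per-stratum results are combined by
    sqrt(N)-weighted Stouffer. ``weight_kind="z"`` takes the combined
    z-score as the weight (default); ``"coefficient"`` takes the IVW
    pooled coefficient. Strata below ``min_stratum`` training samples
    are merged into one pooled stratum.
    """
    if mode not in {"basic", "comprehensive"}:
        raise ValueError("mode must be 'basic' or 'comprehensive'")
    model = BASIC_MODEL if mode == "basic" else _comprehensive_model(covariates)
    # normalise on the full matrix first: a few-CpG submatrix carries too
    # little distributional information to normalise on its own
    sub = (quantile_normalise(matrix) if normalise else matrix)
    sub = sub.subset_cpgs(sentinels)
    strata = covariates["stratum"]
    counts = strata.value_counts()
    small = counts[counts < min_stratum].index
    eff_strata = strata.where(~strata.isin(small), "pooled")

    per_study = {}
    for name, members in eff_strata.groupby(eff_strata, sort=True):
        ids = members.index
        try:
            rec = run_ewas(sub.subset_samples(ids), phenotype.loc[ids],
                           covariates.loc[ids], model)
        except ValueError as exc:
            logger.warning("stratum %s dropped: %s", name, exc)
            continue
        if len(rec):
            per_study[str(name)] = rec
    if not per_study:
        raise ValueError("no stratum produced a usable fit")
    combined = (meta.stouffer_meta(per_study) if weight_kind == "z"
                else meta.ivw_meta(per_study))
    combined = combined.set_index("feature")
    missing = [c for c in sentinels if c not in combined.index]
    if missing:
        raise ValueError(f"no weight estimable for CpGs {missing}")
    weights = (combined.loc[sentinels, "z"] if weight_kind == "z"
               else combined.loc[sentinels, "effect"]).to_numpy(float)
    digest = hashlib.sha256(
        ",".join(sorted(map(str, matrix.sample_ids))).encode()).hexdigest()[:16]
    return MrsModel(cpgs=list(sentinels), weights=weights,
                    weight_mode=f"{mode}/{weight_kind}",
                    training_hash=digest, seed=seed,
                    per_stratum=combined.reset_index())


def score(model: MrsModel, matrix: MethylationMatrix,
          normalise: bool = True) -> pd.Series:
    """MRS per sample: weighted sum of (quantile-normalised) betas."""
    missing = [c for c in model.cpgs if c not in matrix.cpg_ids]
    if missing:
        raise KeyError(f"scored matrix lacks model CpGs {missing}")
    sub = (quantile_normalise(matrix) if normalise else matrix)
    sub = sub.subset_cpgs(model.cpgs)
    vals = sub.values.to_numpy(float) @ model.weights
    return pd.Series(vals, index=matrix.sample_ids, name="mrs")


# --------------------------------------------------------------------------
# AUC and DeLong


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic (ties get half credit)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores, method="average")
    return (ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]), method="average")
    r_pos = stats.rankdata(pos, method="average")
    r_neg = stats.rankdata(neg, method="average")
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # structural components, positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # structural components, negatives
    return auc, v10, v01


def delong_variance(labels, scores) -> float:
    labels = np.asarray(labels, dtype=bool)
    _, v10, v01 = _delong_components(labels, np.asarray(scores, float))
    return float(np.var(v10, ddof=1) / len(v10)
                 + np.var(v01, ddof=1) / len(v01))


def delong_test(labels, scores1, scores2) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same samples.

    Returns (auc1, auc2, two-sided p). Identical scorings give p = 1.
    """
    labels = np.asarray(labels, dtype=bool)
    s1 = np.asarray(scores1, float)
    s2 = np.asarray(scores2, float)
    a1, v10_1, v01_1 = _delong_components(labels, s1)
    a2, v10_2, v01_2 = _delong_components(labels, s2)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / len(v10_1) \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / len(v01_1)
    diff = a1 - a2
    if var <= 0:
        return a1, a2, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return a1, a2, float(2.0 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """Discrimination and risk-gradient summary on the test set."""

    auc: dict                    # model -> (auc, ci_lo, ci_hi)
    delong_p: dict               # "M1_vs_M2" -> p
    quartile_or: pd.DataFrame    # quartile, or, ci_lo, ci_hi, p
    interaction_lrt_p: float
    group_diff_p: float
    n_test: int
    n_elevated: int
    flags: list = field(default_factory=list)

    def __post_init__(self):
        for name, (a, lo, hi) in self.auc.items():
            if not (0.0 <= a <= 1.0 and lo <= a <= hi):
                raise ValueError(f"inconsistent AUC/CI for {name}")


def _fit_logit(y: np.ndarray, X: pd.DataFrame, flags: list, tag: str):
    """Logistic fit with a ridge fallback when separation breaks MLE."""
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if (not res.mle_retvals.get("converged", True)
                or not np.isfinite(res.bse).all()
                or res.bse.max() > 1e3):
            raise RuntimeError("separation / no convergence")
        return res, res.predict(Xc)
    except Exception:
        flags.append(f"{tag}: separation/non-convergence; "
                     "L2-penalised fallback used")
        res = sm.Logit(y, Xc).fit_regularized(
            alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
        return res, res.predict(Xc)


def evaluate(mrs: pd.Series, labels: pd.Series, covariates: pd.DataFrame,
             quartile_source: pd.Series | None = None) -> EvaluationReport:
    """Nested-model discrimination and quartile risk gradients.

    M1 = MRS + age + sex + ethnicity; M2 = age + sex + ethnicity;
    M3 = M1 + smoking. AUCs come from each model's fitted
    probabilities; model contrasts use paired DeLong tests; quartile
    odds ratios come from a logistic model of elevated status on MRS
    quartile (Q1 reference) + demographics; the ethnicity-interaction
    LRT compares M1 with and without MRS x ethnicity terms.
    """
    ids = labels.index
    mrs = mrs.loc[ids]
    covs = covariates.loc[ids]
    y = labels.to_numpy(dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("evaluation needs both elevated and normal samples")
    flags: list = []

    demo = build_design(covs, ["age", "sex", "stratum"])
    demo_smoke = build_design(covs, ["age", "sex", "stratum", "smoking"])
    designs = {
        "M1": pd.concat([mrs.rename("mrs"), demo], axis=1),
        "M2": demo,
        "M3": pd.concat([mrs.rename("mrs"), demo_smoke], axis=1),
    }
    preds, auc = {}, {}
    for name, X in designs.items():
        _, phat = _fit_logit(y, X, flags, name)
        preds[name] = np.asarray(phat)
        a = auc_rank(y > 0.5, preds[name])
        half = 1.959963984540054 * np.sqrt(
            delong_variance(y > 0.5, preds[name]))
        auc[name] = (a, max(a - half, 0.0), min(a + half, 1.0))
    delong_p = {}
    for pair in (("M1", "M2"), ("M3", "M2"), ("M3", "M1")):
        _, _, p = delong_test(y > 0.5, preds[pair[0]], preds[pair[1]])
        delong_p[f"{pair[0]}_vs_{pair[1]}"] = p

    # quartile gradient (cut-points from the evaluated scores by default)
    src = mrs if quartile_source is None else quartile_source
    edges = np.quantile(src.to_numpy(float), [0.25, 0.5, 0.75])
    quart = np.searchsorted(edges, mrs.to_numpy(float), side="right")
    qdum = pd.get_dummies(pd.Categorical(quart, categories=[0, 1, 2, 3]),
                          prefix="Q", drop_first=True).set_index(ids)
    res_q, _ = _fit_logit(y, pd.concat([qdum.astype(float), demo], axis=1),
                          flags, "quartile")
    rows = []
    params = res_q.params
    try:
        ci = res_q.conf_int()
        bse = res_q.bse
    except Exception:  # penalised fit: no analytic covariance
        ci = pd.DataFrame(np.nan, index=params.index, columns=[0, 1])
        bse = pd.Series(np.nan, index=params.index)
    for j, label in zip((1, 2, 3), ("Q2", "Q3", "Q4")):
        name = f"Q_{j}"
        coef = params[name]
        pj = (2.0 * stats.norm.sf(abs(coef / bse[name]))
              if np.isfinite(bse[name]) and bse[name] > 0 else np.nan)
        rows.append((label, float(np.exp(coef)),
                     float(np.exp(ci.loc[name, 0])),
                     float(np.exp(ci.loc[name, 1])), pj))
    quartile_or = pd.DataFrame(rows, columns=["quartile", "or", "ci_lo",
                                              "ci_hi", "p"])

    # MRS x ethnicity interaction via likelihood-ratio test
    eth = build_design(covs, ["stratum"])
    inter = eth.mul(mrs.to_numpy(float), axis=0)
    inter.columns = [f"mrs_x_{c}" for c in eth.columns]
    full_X = pd.concat([designs["M1"], inter], axis=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_red = sm.Logit(y, sm.add_constant(
                designs["M1"].astype(float), has_constant="add")).fit(disp=0)
            fit_full = sm.Logit(y, sm.add_constant(
                full_X.astype(float), has_constant="add")).fit(disp=0)
        lr = 2.0 * (fit_full.llf - fit_red.llf)
        interaction_p = float(stats.chi2.sf(max(lr, 0.0), inter.shape[1]))
    except Exception:
        flags.append("interaction LRT failed (separation)")
        interaction_p = float("nan")

    grp = stats.ttest_ind(mrs[labels].to_numpy(float),
                          mrs[~labels].to_numpy(float), equal_var=False)
    return EvaluationReport(auc=auc, delong_p=delong_p,
                            quartile_or=quartile_or,
                            interaction_lrt_p=interaction_p,
                            group_diff_p=float(grp.pvalue),
                            n_test=len(ids),
                            n_elevated=int(labels.sum()), flags=flags)
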