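"""Per-stratum epigenome-wide association scans.

Each CpG is tested by ordinary least squares of log-transformed cIMT on
its (quantile-normalised) beta value plus covariates, with two-sided
p-values from the t distribution at the residual degrees of freedom.
The scan is vectorised across CpGs via Frisch–Waugh partialling: both
the outcome and every CpG column are residualised against the shared
covariate design, after which each CpG fit reduces to a simple
regression whose coefficient, SE and t statistic equal those of the
full model exactly.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ASSOC_COLUMNS, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalise", "run_ewas", "sensitivity_reruns", "build_design"]


def quantile_normalise(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample's value distribution onto the common reference.

    The reference is the across-sample mean of each sample's sorted
    values; each sample's values are replaced by the reference entry at
    their rank, ties receiving the mean of the implied values. Samples
    whose values are all identical carry no ranking information and are
    passed through unchanged with a warning.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n, m = vals.shape
    if n < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    ref = np.sort(vals, axis=1).mean(axis=0)
    out = np.empty_like(vals)
    constant = np.ptp(vals, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} all-constant sample(s) passed through "
            "unchanged by quantile normalisation")
    for i in range(n):
        if constant[i]:
            out[i] = vals[i]
            continue
        ranks = stats.rankdata(vals[i], method="average")
        out[i] = np.interp(ranks, np.arange(1, m + 1), ref)
    res = pd.DataFrame(out, index=matrix.values.index,
                       columns=matrix.values.columns)
    return MethylationMatrix(res.clip(0.0, 1.0), matrix.positions)


def build_design(covariates: pd.DataFrame, model: list[str] | None) -> pd.DataFrame:
    """Expand a covariate model into a numeric design (no intercept column).

    String/categorical columns become treatment-coded dummies; a
    ``never`` level (smoking) is used as the reference when present.
    List-valued names are not supported — cell proportions and technical
    PCs must already be separate numeric columns.
    """
    if not model:
        return pd.DataFrame(index=covariates.index)
    cols = []
    for name in model:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not found")
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique(), key=str)
            if "never" in levels:  # reference level for smoking status
                levels.remove("never")
                levels.insert(0, "never")
            cat = pd.Categorical(col, categories=levels)
            dummies = pd.get_dummies(cat, prefix=name, drop_first=True)
            dummies.index = covariates.index
            cols.append(dummies.astype(float))
        else:
            cols.append(col.astype(float).to_frame(name))
    return pd.concat(cols, axis=1)


def _partial_ols(y: np.ndarray, X: np.ndarray, q_cov: np.ndarray,
                 df_resid: int):
    """Frisch–Waugh simple regressions of y on each column of X.

    ``q_cov`` is an orthonormal basis (QR Q factor) of the covariate
    design including the intercept. Returns effect, se, t, p arrays.
    """
    y_t = y - q_cov @ (q_cov.T @ y)
    X_t = X - q_cov @ (q_cov.T @ X)
    sxx = np.einsum("ij,ij->j", X_t, X_t)
    sxy = X_t.T @ y_t
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        ssr = float(y_t @ y_t) - beta * sxy
        sigma2 = np.maximum(ssr, 0.0) / df_resid
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return beta, se, t, p, sxx


def run_ewas(matrix: MethylationMatrix, phenotype: pd.Series,
             covariates: pd.DataFrame | None = None,
             model: list[str] | None = None) -> pd.DataFrame:
    """EWAS of log(phenotype) on each CpG plus covariates.

    Parameters
    ----------
    matrix
        Methylation beta values (normalise beforehand if desired).
    phenotype
        Positive per-sample cIMT (mm); regressed as its natural log.
    covariates
        Per-sample covariate table aligned on sample id.
    model
        Covariate column names to adjust for (categoricals expanded).

    Returns
    -------
    DataFrame with columns ``feature, effect, se, stat, p, n``; CpGs
    whose design is rank deficient (zero residual variance in the CpG)
    are skipped with a logged reason.
    """
    phenotype = phenotype.reindex(matrix.sample_ids)
    if covariates is not None:
        covariates = covariates.reindex(matrix.sample_ids)
    design = build_design(covariates, model) if model else pd.DataFrame(
        index=matrix.sample_ids)

    keep = phenotype.notna()
    if len(design.columns):
        keep &= design.notna().all(axis=1)
    pheno = phenotype[keep]
    if (pheno <= 0).any():
        raise ValueError("phenotype must be strictly positive (log outcome)")
    y = np.log(pheno.to_numpy(dtype=float))
    Xcov = np.column_stack([np.ones(keep.sum())] +
                           ([design.loc[keep].to_numpy(float)]
                            if len(design.columns) else []))
    n_cov = Xcov.shape[1]
    if keep.sum() <= n_cov + 2:
        raise ValueError("too few complete cases for the covariate model")
    q_cov, _ = np.linalg.qr(Xcov)

    vals = matrix.values.loc[keep.values].to_numpy(dtype=float)
    cpgs = np.asarray(matrix.cpg_ids)
    has_nan = np.isnan(vals).any(axis=0)
    df_resid = vals.shape[0] - n_cov - 1

    rows = {c: np.full(len(cpgs), np.nan) for c in
            ("effect", "se", "stat", "p")}
    ns = np.full(len(cpgs), vals.shape[0], dtype=int)

    clean = ~has_nan
    if clean.any():
        beta, se, t, p, sxx = _partial_ols(y, vals[:, clean], q_cov, df_resid)
        bad = ~(sxx > 1e-12 * vals.shape[0])
        for arr, src in zip(rows.values(), (beta, se, t, p)):
            src = np.where(bad, np.nan, src)
            arr[clean] = src
    for j in np.nonzero(has_nan)[0]:
        mask = ~np.isnan(vals[:, j])
        nj = int(mask.sum())
        ns[j] = nj
        if nj <= n_cov + 2:
            continue
        qj, _ = np.linalg.qr(Xcov[mask])
        b, s, t, p, sxx = _partial_ols(
            y[mask], vals[mask, j:j + 1], qj, nj - n_cov - 1)
        if sxx[0] > 1e-12 * nj:
            rows["effect"][j], rows["se"][j] = b[0], s[0]
            rows["stat"][j], rows["p"][j] = t[0], p[0]

    out = pd.DataFrame({"feature": cpgs, **rows, "n": ns})
    skipped = out["se"].isna()
    if skipped.any():
        logger.info("skipped %d rank-deficient/underpowered CpGs",
                    int(skipped.sum()))
        out = out[~skipped].reset_index(drop=True)
    # guard against p == 0 underflow so records stay valid downstream
    tiny = np.finfo(float).tiny
    out["p"] = out["p"].clip(lower=tiny)
    return out[list(ASSOC_COLUMNS)]


def sensitivity_reruns(records: pd.DataFrame, matrix: MethylationMatrix,
                       phenotype: pd.Series, covariates: pd.DataFrame,
                       model: list[str] | None = None,
                       extra_covariates: list[str] | None = None,
                       sample_filter: pd.Series | None = None) -> pd.DataFrame:
    """Re-run the EWAS for sentinel CpGs under an augmented model or filter.

    Returns the re-estimated records with a ``direction_consistent``
    flag against the original effect signs.
    """
    sentinels = list(records["feature"])
    sub = matrix.subset_cpgs(sentinels)
    full_model = list(model or []) + list(extra_covariates or [])
    if sample_filter is not None:
        sample_filter = sample_filter.reindex(sub.sample_ids).fillna(False)
        if sample_filter.sum() < 0.1 * len(sample_filter):
            warnings.warn("sample filter retains <10% of samples")
        sub = sub.subset_samples(sub.sample_ids[sample_filter.values])
        phenotype = phenotype[sample_filter[sample_filter].index]
        covariates = covariates.loc[phenotype.index]
    rerun = run_ewas(sub, phenotype, covariates, full_model or None)
    merged = rerun.merge(records[["feature", "effect"]], on="feature",
                         suffixes=("", "_orig"))
    merged["direction_consistent"] = (
        np.sign(merged["effect"]) == np.sign(merged["effect_orig"]))
    return merged.drop(columns="effect_orig")
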