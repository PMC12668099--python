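"""Sample-size-weighted Stouffer and fixed-effects IVW meta-analysis.

Stouffer combination converts each study's two-sided p-value and effect
direction into a signed z-score and pools z_meta = sum(sqrt(N_i) z_i) /
sqrt(sum N_i). It is the default across cohorts here because cIMT
acquisition protocols and covariate models differ between studies, so
effect sizes are not directly comparable while z-scores are. The IVW
path (effect_meta = sum(w_i b_i)/sum(w_i), w_i = 1/se_i^2) is used
where effects share a scale, e.g. pooling cis-meQTL scans.

Heterogeneity is summarised by Cochran's Q and I^2 = max(0, (Q - df)/Q).
On the Stouffer path the per-study z-scores are treated as unit-variance
effects when computing Q; an effect-scale mode is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["stouffer_meta", "ivw_meta", "two_stage_screen", "ScreenResult",
           "signed_z", "bonferroni_threshold"]

_TINY = np.finfo(float).tiny  # smallest positive normal double


def signed_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed z from a two-sided p-value: sign * Phi^-1(1 - p/2).

    p-values that would underflow the normal quantile are clamped at the
    smallest positive normal double with a warning.
    """
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped at the smallest positive normal")
        p = np.maximum(p, _TINY)
    return np.where(np.asarray(sign) < 0, -1.0, 1.0) * stats.norm.isf(p / 2.0)


def _aligned(studies: dict[str, pd.DataFrame]):
    """Align per-study tables on the union of features.

    Returns (features index, study names, Z, N, B, SE) where missing
    entries are NaN. Direction comes from an explicit ``direction``
    column when present, else from the sign of ``effect``.
    """
    names = list(studies)
    frames = []
    for name, df in studies.items():
        sign = (df["direction"] if "direction" in df.columns
                else np.sign(df["effect"])).to_numpy()
        z = signed_z(df["p"].to_numpy(), sign)
        frames.append(pd.DataFrame({
            "feature": df["feature"].to_numpy(), "study": name, "z": z,
            "n": df["n"].to_numpy(float),
            "effect": df["effect"].to_numpy(float) if "effect" in df else np.nan,
            "se": df["se"].to_numpy(float) if "se" in df else np.nan,
        }))
    long = pd.concat(frames, ignore_index=True)
    piv = long.pivot_table(index="feature", columns="study", sort=False,
                           values=["z", "n", "effect", "se"], aggfunc="first")
    features = piv.index
    get = lambda key: piv[key].reindex(columns=names).to_numpy(float)
    return features, names, get("z"), get("n"), get("effect"), get("se")


def _het(est: np.ndarray, per_study: np.ndarray, w: np.ndarray):
    """Cochran's Q, its p-value and I^2 from weighted per-study deviations."""
    dev = per_study - est[:, None]
    q = np.nansum(w * dev ** 2, axis=1)
    k = np.sum(~np.isnan(per_study) & ~np.isnan(w), axis=1)
    df = np.maximum(k - 1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / q), 0.0)
    q_p = np.where(df > 0, stats.chi2.sf(q, np.maximum(df, 1)), np.nan)
    return q, i2, q_p, k


def _direction_string(z: np.ndarray) -> list[str]:
    sym = np.where(np.isnan(z), "?", np.where(z < 0, "-", "+"))
    return ["".join(row) for row in sym]


def stouffer_meta(studies: dict[str, pd.DataFrame], *,
                  het_on: str = "z") -> pd.DataFrame:
    """Combine per-study association records by sqrt(N)-weighted Stouffer.

    Features present in a single study are passed through unchanged and
    flagged (``single_study``). ``het_on`` selects whether Q/I^2 are
    computed on per-study z-scores ("z", unit variance) or on effects
    ("effect", weights 1/se^2).

    Returns a table with ``feature, z, p, n_total, q, i2, q_p,
    directions, weights, n_studies, single_study``.
    """
    features, names, Z, N, B, SE = _aligned(studies)
    present = ~np.isnan(Z) & ~np.isnan(N)
    k = present.sum(axis=1)
    sqn = np.where(present, np.sqrt(N), 0.0)
    zsum = np.nansum(np.where(present, sqn * Z, 0.0), axis=1)
    n_total = np.nansum(np.where(present, N, 0.0), axis=1)
    z_meta = zsum / np.sqrt(n_total)
    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))

    if het_on == "z":
        w = np.where(present, 1.0, np.nan)
        center = np.nanmean(np.where(present, Z, np.nan), axis=1)
        q, i2, q_p, _ = _het(center, np.where(present, Z, np.nan), w)
    elif het_on == "effect":
        w = 1.0 / SE ** 2
        est = np.nansum(w * B, axis=1) / np.nansum(w, axis=1)
        q, i2, q_p, _ = _het(est, B, w)
    else:
        raise ValueError("het_on must be 'z' or 'effect'")

    wfrac = sqn / sqn.sum(axis=1, keepdims=True)
    out = pd.DataFrame({
        "feature": features, "z": z_meta, "p": np.clip(p_meta, _TINY, 1.0),
        "n_total": n_total.astype(int), "q": q, "i2": i2, "q_p": q_p,
        "directions": _direction_string(np.where(present, Z, np.nan)),
        "weights": [",".join(f"{x:.4g}" for x in row) for row in wfrac],
        "n_studies": k, "single_study": k == 1,
    })
    single = out["single_study"].to_numpy()
    if single.any():
        # pass the sole study's z and p through untouched
        zs = np.where(present, Z, 0.0).sum(axis=1)
        out.loc[single, "z"] = zs[single]
        out.loc[single, "p"] = np.clip(
            2.0 * stats.norm.sf(np.abs(zs[single])), _TINY, 1.0)
        out.loc[single, ["q", "i2", "q_p"]] = np.nan
    return out.reset_index(drop=True)


def ivw_meta(studies: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted combination of effects.

    Studies with se <= 0 are dropped with a warning. Returns ``feature,
    effect, se, z, p, n_total, q, i2, q_p, directions, weights,
    n_studies, single_study``.
    """
    cleaned = {}
    for name, df in studies.items():
        bad = df["se"] <= 0
        if bad.any():
            warnings.warn(f"{name}: dropped {int(bad.sum())} rows with se<=0")
            df = df[~bad]
        cleaned[name] = df
    features, names, Z, N, B, SE = _aligned(cleaned)
    w = 1.0 / SE ** 2
    present = ~np.isnan(B) & ~np.isnan(SE)
    w = np.where(present, w, np.nan)
    wsum = np.nansum(w, axis=1)
    effect = np.nansum(np.where(present, w * B, 0.0), axis=1) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = effect / se
    q, i2, q_p, k = _het(effect, B, w)
    wfrac = w / wsum[:, None]
    out = pd.DataFrame({
        "feature": features, "effect": effect, "se": se, "z": z,
        "p": np.clip(2.0 * stats.norm.sf(np.abs(z)), _TINY, 1.0),
        "n_total": np.nansum(np.where(present, N, 0.0), axis=1).astype(int),
        "q": q, "i2": i2, "q_p": q_p,
        "directions": _direction_string(np.where(present, B, np.nan)),
        "weights": [",".join(f"{x:.4g}" for x in np.nan_to_num(row))
                    for row in wfrac],
        "n_studies": k, "single_study": k == 1,
    })
    out.loc[out["single_study"], ["q", "i2", "q_p"]] = np.nan
    return out.reset_index(drop=True)


def bonferroni_threshold(base: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("need at least one test")
    return base / n_tests


@dataclass
class ScreenResult:
    """Output of the two-stage screen."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    threshold: float
    sentinels: pd.DataFrame
    n_advanced: int


def two_stage_screen(stage1_studies: dict[str, pd.DataFrame],
                     stage2_studies: dict[str, pd.DataFrame],
                     stage1_alpha: float = 0.05,
                     bonferroni_base: float = 0.05,
                     positions: pd.DataFrame | None = None,
                     stage1_method: str = "stouffer") -> ScreenResult:
    """Two-stage screen: discovery strata, then trans-ancestry pooling.

    Stage 1 meta-analyses the discovery strata; features with
    p < ``stage1_alpha`` that are present in every Stage-2 dataset
    advance. Stage 2 pools all studies (discovery strata plus the
    additional cohorts) by Stouffer. The multiplicity threshold is
    ``bonferroni_base`` divided by the number of advanced features, and
    sentinels are the lowest-p threshold-passers, at most one per
    chromosome (requires ``positions`` with a ``chrom`` column indexed
    by feature).
    """
    if not 0 < stage1_alpha <= 1:
        raise ValueError("stage1_alpha must be in (0, 1]")
    combine1 = stouffer_meta if stage1_method == "stouffer" else ivw_meta
    stage1 = combine1(stage1_studies)
    hits = stage1.loc[stage1["p"] < stage1_alpha, "feature"]
    available = set(hits)
    for df in stage2_studies.values():
        available &= set(df["feature"])
    advanced = hits[hits.isin(available)]
    if advanced.empty:
        logger.warning("no features advanced past stage 1")
        empty = stage1.iloc[0:0]
        return ScreenResult(stage1, empty, np.nan, empty, 0)

    adv = set(advanced)
    all_studies = {
        name: df[df["feature"].isin(adv)]
        for name, df in {**stage1_studies, **stage2_studies}.items()
    }
    stage2 = stouffer_meta(all_studies)
    threshold = bonferroni_threshold(bonferroni_base, len(advanced))
    passers = stage2[stage2["p"] < threshold].copy()
    if positions is not None and len(passers):
        passers["chrom"] = positions.loc[passers["feature"], "chrom"].to_numpy()
        sentinels = (passers.sort_values("p")
                     .drop_duplicates("chrom", keep="first")
                     .reset_index(drop=True))
    else:
        sentinels = passers.reset_index(drop=True)
    logger.info("stage1 %d features, %d advanced, threshold %.3g, "
                "%d sentinels", len(stage1), len(advanced), threshold,
                len(sentinels))
    return ScreenResult(stage1, stage2, threshold, sentinels, len(advanced))
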