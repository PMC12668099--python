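"""cis-window association scans (meQTL, eQTL, eQTM) and instrument selection.

A scan regresses each target feature (CpG methylation or gene
expression) on every source feature (SNP dosage or CpG) lying within a
cis window of the target's anchor position, adjusting for covariates.
All pairs in the window are reported without p filtering; instrument
selection applies the p-value and F-statistic screens afterwards.
Distances are measured between point anchors (SNP position, CpG
position, gene TSS) and the window bound is strict (< window_bp).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ewas import _partial_ols, build_design
from .types import CIS_COLUMNS

__all__ = ["cis_scan", "select_instruments"]


def cis_scan(source_values: pd.DataFrame, source_positions: pd.DataFrame,
             target_values: pd.DataFrame, target_positions: pd.DataFrame,
             covariates: pd.DataFrame | None = None,
             model: list[str] | None = None,
             window_bp: int = 1_000_000,
             min_samples: int = 30) -> pd.DataFrame:
    """OLS of each target on each cis source, one row per pair.

    ``source_values`` / ``target_values`` are samples x features;
    positions are indexed by feature id with ``chrom`` and ``pos``
    columns (1-based points; a gene's ``pos`` is its TSS). Shared
    samples are intersected in ``source_values`` order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    shared = source_values.index.intersection(target_values.index)
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples (<{min_samples})")
    sv = source_values.loc[shared]
    tv = target_values.loc[shared]
    if covariates is not None:
        design = build_design(covariates.reindex(shared), model)
        X = np.column_stack([np.ones(len(shared)), design.to_numpy(float)])
    else:
        X = np.ones((len(shared), 1))
    q_cov, _ = np.linalg.qr(X)
    df_resid = len(shared) - X.shape[1] - 1
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")

    sp = source_positions.loc[source_positions.index.intersection(sv.columns)]
    tp = target_positions.loc[target_positions.index.intersection(tv.columns)]
    rows = []
    for chrom, tgrp in tp.groupby("chrom", sort=False):
        sgrp = sp[sp["chrom"] == chrom].sort_values("pos")
        if sgrp.empty:
            continue
        spos = sgrp["pos"].to_numpy()
        svals = sv[sgrp.index].to_numpy(float)
        for tid, tpos in tgrp["pos"].items():
            lo = np.searchsorted(spos, tpos - window_bp, side="right")
            hi = np.searchsorted(spos, tpos + window_bp, side="left")
            if hi <= lo:
                continue
            y = tv[tid].to_numpy(float)
            beta, se, t, p, sxx = _partial_ols(
                y, svals[:, lo:hi], q_cov, df_resid)
            ok = sxx > 1e-12 * len(shared)
            rows.append(pd.DataFrame({
                "source": sgrp.index[lo:hi][ok], "target": tid,
                "source_chrom": chrom, "source_pos": spos[lo:hi][ok],
                "target_pos": tpos,
                "distance": np.abs(spos[lo:hi][ok] - tpos),
                "effect": beta[ok], "se": se[ok], "p": p[ok],
                "n": len(shared), "f_stat": t[ok] ** 2,
            }))
    if not rows:
        return pd.DataFrame(columns=list(CIS_COLUMNS))
    out = pd.concat(rows, ignore_index=True)
    tiny = np.finfo(float).tiny
    out["p"] = out["p"].clip(lower=tiny)
    return out[list(CIS_COLUMNS)]


def select_instruments(pairs: pd.DataFrame, p_max: float = 1e-5,
                       f_min: float = 10.0) -> pd.DataFrame:
    """Best passing cis pair per target, for use as a genetic instrument.

    A pair passes if p < ``p_max`` and F >= ``f_min``; per target the
    smallest-p pair wins, ties broken by larger F then lexicographic
    source id. Targets with no passing pair are omitted.
    """
    passing = pairs[(pairs["p"] < p_max) & (pairs["f_stat"] >= f_min)]
    if passing.empty:
        return passing.copy()
    ordered = passing.sort_values(
        ["target", "p", "f_stat", "source"],
        ascending=[True, True, False, True], kind="mergesort")
    return ordered.drop_duplicates("target", keep="first").reset_index(drop=True)
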