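"""Summary-data causal inference: Wald-ratio SMR and ABF colocalisation.

SMR (summary-data Mendelian randomisation) estimates the effect of an
exposure (CpG methylation) on an outcome (disease risk, expression)
through a single strong cis genetic instrument as the Wald ratio
beta_smr = beta_outcome / beta_exposure, with a delta-method standard
error.

Colocalisation asks whether the exposure and outcome association
signals in a region are driven by one shared causal variant. Each SNP
receives a Wakefield approximate log Bayes factor
    log ABF = 0.5 * (log(1 - r) + r z^2),  r = W / (V + W),
with V the squared SE and W the squared prior effect SD; assuming at
most one causal variant per trait, summing ABFs over causal-variant
configurations yields posteriors for five hypotheses H0-H4 (no signal /
trait 1 only / trait 2 only / two distinct variants / one shared
variant) under priors (p1, p2, p12) per SNP.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .types import ColocResult, SmrResult

__all__ = ["smr_wald", "harmonise_alleles", "wakefield_labf", "coloc_abf",
           "p12_sensitivity", "DEFAULT_PRIORS"]

#: coloc.abf-style default per-SNP priors (p1, p2, p12).
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def harmonise_alleles(exposure: pd.Series, outcome: pd.Series) -> pd.Series:
    """Align the outcome record to the exposure's effect allele.

    Both records need ``effect_allele`` and ``other_allele``. If the
    outcome's alleles are swapped, its beta is flipped; strand-ambiguous
    palindromic SNPs (A/T, C/G) are refused with a warning (returns
    None); any other mismatch is an error.
    """
    ea_e, oa_e = str(exposure["effect_allele"]), str(exposure["other_allele"])
    ea_o, oa_o = str(outcome["effect_allele"]), str(outcome["other_allele"])
    if frozenset({ea_e, oa_e}) in _PALINDROMIC:
        warnings.warn(f"palindromic SNP {exposure.get('snp', '?')} dropped")
        return None
    if (ea_e, oa_e) == (ea_o, oa_o):
        return outcome
    if (ea_e, oa_e) == (oa_o, ea_o):
        flipped = outcome.copy()
        flipped["beta"] = -outcome["beta"]
        flipped["effect_allele"], flipped["other_allele"] = ea_e, oa_e
        return flipped
    raise ValueError(
        f"allele mismatch at {exposure.get('snp', '?')}: "
        f"{ea_e}/{oa_e} vs {ea_o}/{oa_o}")


def smr_wald(exposure, outcome, *, statistic: str = "delta") -> SmrResult:
    """Wald-ratio SMR of one outcome on one exposure via a shared SNP.

    ``exposure``/``outcome`` are mappings (dict, Series, namedtuple-like
    row) with at least ``snp``, ``beta``, ``se``; the exposure should
    already have passed the instrument screen (p < 1e-5, F >= 10). When
    both carry allele columns they must be harmonised beforehand via
    :func:`harmonise_alleles`.

    ``statistic="delta"`` uses the delta-method SE; ``"tsmr"`` uses the
    chi-square statistic T = z_e^2 z_o^2 / (z_e^2 + z_o^2) for the
    p-value (same asymptotics).
    """
    exposure = pd.Series(dict(exposure))
    outcome = pd.Series(dict(outcome))
    if str(exposure["snp"]) != str(outcome["snp"]):
        raise ValueError(
            f"instrument mismatch: {exposure['snp']} vs {outcome['snp']}")
    be, se_e = float(exposure["beta"]), float(exposure["se"])
    bo, se_o = float(outcome["beta"]), float(outcome["se"])
    if be == 0:
        raise ZeroDivisionError("exposure effect is 0: Wald ratio undefined")
    beta_smr = bo / be
    # algebraically |beta_smr| * sqrt(se_o^2/bo^2 + se_e^2/be^2), but
    # written to stay defined when the outcome effect is exactly 0
    se_smr = np.sqrt(se_o ** 2 / be ** 2 + bo ** 2 * se_e ** 2 / be ** 4)
    if statistic == "delta":
        z = beta_smr / se_smr
        p = 2.0 * stats.norm.sf(abs(z))
    elif statistic == "tsmr":
        z_e, z_o = be / se_e, bo / se_o
        t = (z_e ** 2 * z_o ** 2) / (z_e ** 2 + z_o ** 2)
        p = float(stats.chi2.sf(t, 1))
    else:
        raise ValueError("statistic must be 'delta' or 'tsmr'")
    f_stat = float(exposure.get("f_stat", (be / se_e) ** 2))
    return SmrResult(
        exposure=str(exposure.get("exposure", exposure.get("target", ""))),
        outcome=str(outcome.get("outcome", outcome.get("target", ""))),
        instrument=str(exposure["snp"]), beta_smr=beta_smr,
        se_smr=se_smr, p_smr=float(min(p, 1.0)), f_stat=f_stat)


def wakefield_labf(beta, se, prior_sd: float):
    """Wakefield approximate log Bayes factor per SNP (vectorised)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    V, W = se ** 2, prior_sd ** 2
    r = W / (V + W)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def _prior_sd(trait: str, sdY: float, prior_sd: float | None) -> float:
    if prior_sd is not None:
        return prior_sd
    if trait == "quant":
        return 0.15 * sdY
    if trait == "cc":
        return 0.2  # log-odds scale
    raise ValueError("trait must be 'quant' or 'cc'")


def coloc_abf(panel1: pd.DataFrame, panel2: pd.DataFrame,
              priors: tuple = DEFAULT_PRIORS, *, region: str = "region",
              trait1: str = "quant", trait2: str = "quant",
              sdY1: float = 1.0, sdY2: float = 1.0,
              prior_sd1: float | None = None,
              prior_sd2: float | None = None) -> ColocResult:
    """Five-hypothesis colocalisation from two per-SNP (beta, se) panels.

    Panels are DataFrames with columns ``snp``, ``beta``, ``se``; SNPs
    are intersected by id. Quantitative traits use a prior effect SD of
    0.15 * sdY; case-control panels 0.2 on the log-odds scale.

    The decision rule: ``shared`` if PP.H4 > 0.5 and PP.H4/PP.H3 >= 3;
    ``distinct`` if PP.H3 > 0.5; ``none`` if PP.H0 > 0.5; otherwise
    ``underpowered``.
    """
    p1, p2, p12 = priors
    if not (0 < p12 < min(p1, p2) < 1):
        raise ValueError("priors must satisfy 0 < p12 < p1, p2 < 1")
    a = panel1.drop_duplicates("snp").set_index("snp")
    b = panel2.drop_duplicates("snp").set_index("snp")
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError(
            f"panels share {len(shared)} SNPs (<2): "
            f"{len(a)} in panel1, {len(b)} in panel2")
    shared = shared.sort_values()  # order-invariant results
    l1 = wakefield_labf(a.loc[shared, "beta"], a.loc[shared, "se"],
                        _prior_sd(trait1, sdY1, prior_sd1))
    l2 = wakefield_labf(b.loc[shared, "beta"], b.loc[shared, "se"],
                        _prior_sd(trait2, sdY2, prior_sd2))
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)
    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(l1 + l2)
    # sum over ordered pairs of distinct SNPs = full product minus diagonal
    s3, sign = logsumexp([s1 + s2, s12], b=[1.0, -1.0], return_sign=True)
    h = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        (np.log(p1) + np.log(p2) + s3) if sign > 0 else -np.inf,
        np.log(p12) + s12,
    ])
    pp = np.exp(h - logsumexp(h))
    pp /= pp.sum()
    with np.errstate(divide="ignore"):
        ratio = pp[4] / pp[3] if pp[3] > 0 else np.inf
    if pp[4] > 0.5 and ratio >= 3:
        call = "shared"
    elif pp[3] > 0.5:
        call = "distinct"
    elif pp[0] > 0.5:
        call = "none"
    else:
        call = "underpowered"
    return ColocResult(region=region, pp=pp, priors=(p1, p2, p12),
                       n_snps=len(shared), h4_h3_ratio=float(ratio),
                       call=call)


def p12_sensitivity(panel1: pd.DataFrame, panel2: pd.DataFrame,
                    p12_grid, p1: float = 1e-4, p2: float = 1e-4,
                    **kwargs) -> tuple[list[ColocResult], bool]:
    """Re-run colocalisation over a grid of shared-causality priors.

    Returns the per-grid results and a robustness flag: True iff the
    call is ``shared`` at every grid value.
    """
    p12_grid = np.asarray(p12_grid, dtype=float)
    if np.any((p12_grid <= 0) | (p12_grid >= min(p1, p2))):
        raise ValueError("grid values must lie in (0, min(p1, p2))")
    results = [coloc_abf(panel1, panel2, (p1, p2, g), **kwargs)
               for g in p12_grid]
    robust = all(r.call == "shared" for r in results)
    return results, robust
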