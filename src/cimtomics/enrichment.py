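"""Methylation-matched permutation enrichment.

Array-based methylation platforms preferentially assay CpGs near
well-annotated genes, whose methylation level and variability differ
from the genomic background. Enrichment of a test CpG set against gene
sets or TFBS catalogues is therefore judged against permutation
backgrounds matched per test CpG on mean beta and beta SD, drawn at
least 5 kb away, with matching tolerances expanded step-wise until
enough candidates exist. An entry is significant when none of the
background sets reaches the observed overlap (0 of ``n_sets``, i.e.
empirical P < 1/n_sets).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = ["match_background", "MatchedBackground", "map_cpgs_to_genes",
           "geneset_enrichment", "tfbs_enrichment", "default_schedule"]

MIN_DISTANCE_BP = 5_000


def default_schedule(n_steps: int = 10):
    """Linear expansion of (mean, SD) matching tolerances."""
    return list(zip(np.linspace(0.025, 0.25, n_steps),
                    np.linspace(0.0025, 0.025, n_steps)))


@dataclass
class MatchedBackground:
    """Per-permutation matched CpG sets.

    ``sets[j]`` is the j-th background set — one matched CpG per test
    CpG, so every set is size-matched to the test set. ``matching_log``
    records, per test CpG, the final tolerances and candidate count.
    """

    test_cpgs: list
    sets: list
    matching_log: pd.DataFrame

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def match_background(test_cpgs, universe: pd.DataFrame, n_sets: int = 200,
                     seed: int = 0, schedule=None,
                     min_distance: int = MIN_DISTANCE_BP) -> MatchedBackground:
    """Draw ``n_sets`` background CpGs per test CpG from the universe.

    ``universe`` is indexed by CpG id with columns ``mean``, ``sd``,
    ``chrom``, ``pos``. Candidates must lie > ``min_distance`` bp from
    the test CpG (another chromosome always qualifies), must not be a
    test CpG themselves, and must match the test CpG's mean/SD within
    the tightest tolerance step that yields at least ``n_sets``
    candidates. If even the loosest step falls short, all candidates
    are resampled with replacement under a prominent warning.
    """
    test_cpgs = list(test_cpgs)
    if len(universe) <= len(test_cpgs):
        raise ValueError("universe must be strictly larger than the test set")
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    uni = universe.loc[~universe.index.isin(test_cpgs)]
    u_mean = uni["mean"].to_numpy(float)
    u_sd = uni["sd"].to_numpy(float)
    u_chrom = uni["chrom"].to_numpy()
    u_pos = uni["pos"].to_numpy(float)
    u_ids = uni.index.to_numpy()

    draws, log_rows = [], []
    for cpg in test_cpgs:
        row = universe.loc[cpg]
        far = (u_chrom != row["chrom"]) | \
              (np.abs(u_pos - float(row["pos"])) > min_distance)
        chosen = None
        for tol_m, tol_s in schedule:
            ok = far & (np.abs(u_mean - float(row["mean"])) <= tol_m) \
                     & (np.abs(u_sd - float(row["sd"])) <= tol_s)
            n_cand = int(ok.sum())
            if n_cand >= n_sets:
                chosen = rng.choice(u_ids[ok], size=n_sets, replace=False)
                log_rows.append((cpg, tol_m, tol_s, n_cand, False))
                break
        if chosen is None:
            tol_m, tol_s = schedule[-1]
            ok = far & (np.abs(u_mean - float(row["mean"])) <= tol_m) \
                     & (np.abs(u_sd - float(row["sd"])) <= tol_s)
            n_cand = int(ok.sum())
            if n_cand == 0:
                raise ValueError(f"no matchable background for {cpg}")
            warnings.warn(
                f"only {n_cand} candidates for {cpg} at the loosest "
                f"tolerance; sampling WITH replacement")
            chosen = rng.choice(u_ids[ok], size=n_sets, replace=True)
            log_rows.append((cpg, tol_m, tol_s, n_cand, True))
        draws.append(chosen)

    matrix = np.array(draws)  # test CpGs x n_sets
    sets = [list(matrix[:, j]) for j in range(n_sets)]
    log = pd.DataFrame(log_rows, columns=["cpg", "mean_tol", "sd_tol",
                                          "n_candidates", "with_replacement"])
    return MatchedBackground(test_cpgs=test_cpgs, sets=sets, matching_log=log)


def map_cpgs_to_genes(cpgs, eqtm_pairs: pd.DataFrame,
                      p_max: float = 0.05) -> set:
    """Genes linked to the CpGs by cis-eQTM pairs below ``p_max``."""
    cpgs = set(cpgs)
    hits = eqtm_pairs[(eqtm_pairs["p"] < p_max)
                      & eqtm_pairs["source"].isin(cpgs)]
    return set(hits["target"])


def _result_frame(names, observed, bg_counts, n_sets, log2_fc_min):
    rows = []
    for name, obs, bg in zip(names, observed, bg_counts):
        bg = np.asarray(bg)
        n_ge = int((bg >= obs).sum())
        mean_bg = float(bg.mean())
        fc = obs / mean_bg if mean_bg > 0 else np.inf
        significant = n_ge == 0
        reported = (significant and np.isfinite(fc) and fc > 0
                    and np.log2(fc) > log2_fc_min)
        rows.append((name, int(obs), mean_bg, fc, n_ge / n_sets,
                     significant, reported))
    return pd.DataFrame(rows, columns=["set_id", "observed", "bg_mean",
                                       "fold_change", "empirical_p",
                                       "significant", "reported"])


def geneset_enrichment(test_genes, background_gene_sets,
                       collections: dict,
                       log2_fc_min: float = 1.0) -> pd.DataFrame:
    """Overrepresentation of pathway entries in the eQTM-mapped genes.

    ``background_gene_sets`` is one gene set per permutation (each
    produced by mapping a matched background CpG set through the same
    eQTM filter). ``collections`` maps pathway name -> gene set.
    Entries with zero background mean get an infinite fold change and
    are excluded from the reported ranking.
    """
    if not collections:
        raise ValueError("empty pathway collection")
    test_genes = set(test_genes)
    bgs = [set(s) for s in background_gene_sets]
    names = list(collections)
    observed = [len(test_genes & set(collections[n])) for n in names]
    bg_counts = [[len(b & set(collections[n])) for b in bgs] for n in names]
    return _result_frame(names, observed, bg_counts, len(bgs), log2_fc_min)


def _load_trees(tfbs: dict) -> dict:
    trees = {}
    for tf, intervals in tfbs.items():
        per_chrom: dict = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(
                    f"malformed interval for {tf}: {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees[tf] = per_chrom
    return trees


def _count_overlaps(cpgs, positions: pd.DataFrame, per_chrom: dict) -> int:
    count = 0
    for cpg in cpgs:
        chrom = positions.at[cpg, "chrom"]
        pos = int(positions.at[cpg, "pos"])
        tree = per_chrom.get(chrom)
        # 1-based point -> 0-based coordinate inside half-open intervals
        if tree is not None and tree.overlaps(pos - 1):
            count += 1
    return count


def tfbs_enrichment(test_cpgs, background: MatchedBackground,
                    positions: pd.DataFrame, tfbs: dict,
                    log2_fc_min: float = 0.0) -> pd.DataFrame:
    """Positional overlap of test CpGs with per-TF binding intervals.

    ``tfbs`` maps TF name -> iterable of (chrom, start, end) with
    0-based half-open coordinates; ``positions`` is indexed by CpG id
    with 1-based ``pos``. Fold change is observed / background mean.
    """
    trees = _load_trees(tfbs)
    names = list(trees)
    observed = [_count_overlaps(test_cpgs, positions, trees[tf])
                for tf in names]
    bg_counts = [[_count_overlaps(s, positions, trees[tf])
                  for s in background.sets] for tf in names]
    return _result_frame(names, observed, bg_counts, background.n_sets,
                         log2_fc_min)
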