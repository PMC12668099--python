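"""Readers/writers for the tabular and interval formats the pipeline touches.

Conventions: all tables are tab-delimited UTF-8 with a header; BED
inputs are 0-based half-open and are converted to 1-based point
positions at the single entry point :func:`read_bed_points`; METAL-like
summary files use columns MarkerName / Effect / StdErr / P / N /
Direction.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ASSOC_COLUMNS, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_summary_stats", "write_summary_stats", "read_bed_points",
    "write_bed_points", "read_bed_intervals", "read_gmt", "write_gmt",
    "read_config", "write_config", "write_cohort", "read_cohort",
]

_METAL_MAP = {"markername": "feature", "effect": "effect",
              "stderr": "se", "p": "p", "p-value": "p", "pvalue": "p",
              "n": "n", "weight": "n", "direction": "direction",
              "zscore": "stat"}
_GENERIC = {c: c for c in (*ASSOC_COLUMNS, "direction")}


def read_summary_stats(path, dialect: str = "generic") -> pd.DataFrame:
    """Load an association-record table; malformed rows are dropped.

    ``dialect="metal"`` resolves METAL column names (MarkerName,
    Effect, StdErr, P, N, Direction) case-insensitively; a METAL
    Direction string like ``"+-?"`` is kept verbatim (per-study signs
    with ``?`` marking missing studies) and the leading sign provides
    the record-level direction.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Direction": str},
                     float_precision="round_trip")
    mapping = _METAL_MAP if dialect == "metal" else _GENERIC
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in mapping:
            rename[col] = mapping[key]
    df = df.rename(columns=rename)
    required = ["feature", "p"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    n0 = len(df)
    bad = pd.Series(False, index=df.index)
    if "se" in df:
        bad |= ~(df["se"] > 0)
    bad |= ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
        logger.warning("%s: rejected %d malformed rows (lines %s%s)",
                       path, int(bad.sum()), lines,
                       " ..." if bad.sum() > 10 else "")
        df = df[~bad]
    if "direction" in df and df["direction"].dtype == object:
        lead = df["direction"].str.strip().str[0]
        df["direction"] = np.where(lead == "-", -1.0, 1.0)
    elif "direction" not in df and "effect" in df:
        df["direction"] = np.sign(df["effect"]).replace(0, 1.0)
    if "stat" not in df and "effect" in df and "se" in df:
        df["stat"] = df["effect"] / df["se"]
    logger.info("%s: %d/%d records loaded", path, len(df), n0)
    return df.reset_index(drop=True)


def write_summary_stats(records: pd.DataFrame, path,
                        dialect: str = "generic") -> None:
    df = records.copy()
    if dialect == "metal":
        cols = {"feature": "MarkerName", "effect": "Effect",
                "se": "StdErr", "p": "P", "n": "N",
                "direction": "Direction"}
        df = df.rename(columns=cols)[[v for k, v in cols.items()
                                      if k in records.columns]]
    # %.17g guarantees a bit-exact float round-trip through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bed_points(path) -> pd.DataFrame:
    """BED (0-based half-open) -> positions indexed by the name column.

    The point position is the interval start converted to 1-based
    (start + 1); all internal coordinates are 1-based points.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    out = pd.DataFrame({"chrom": df["chrom"],
                        "pos": df["start"].astype(int) + 1})
    out.index = pd.Index(df["name"], name="feature")
    if out.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature names")
    return out


def write_bed_points(positions: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": positions["chrom"],
        "start": positions["pos"].astype(int) - 1,
        "end": positions["pos"].astype(int),
        "name": positions.index,
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed_intervals(path) -> dict:
    """BED with a name column -> {name: [(chrom, start, end), ...]}.

    Used for TFBS catalogues: the 4th column is the TF name, intervals
    stay 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.name, []).append(
            (row.chrom, int(row.start), int(row.end)))
    return out


def read_gmt(path) -> dict:
    """GMT gene sets -> {set name: set of gene ids} (description dropped)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT lines need name, description, "
                             "and at least one gene")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(collections: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collections.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# --------------------------------------------------------------------------
# cohort round-trip


def write_cohort(cohort, out_dir) -> None:
    """Write every block of a synthetic cohort as text tables + BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.methylation.values.to_csv(out / "methylation.tsv", sep="\t")
    cohort.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
    cohort.expression.to_csv(out / "expression.tsv", sep="\t")
    cohort.phenotype.to_frame().to_csv(out / "phenotype.tsv", sep="\t")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    positions = pd.concat([cohort.methylation.positions,
                           cohort.snp_positions, cohort.gene_positions])
    write_bed_points(positions, out / "positions.bed")


def read_cohort(in_dir):
    """Reload the blocks written by :func:`write_cohort`."""
    from .synthetic import CohortSpec, SyntheticCohort

    d = Path(in_dir)
    meth = pd.read_csv(d / "methylation.tsv", sep="\t", index_col=0)
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col=0)
    expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(d / "phenotype.tsv", sep="\t", index_col=0)["cimt"]
    covs = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(d / "truth.tsv", sep="\t")
    pos = read_bed_points(d / "positions.bed")
    spec = CohortSpec(n_per_stratum=covs["stratum"].value_counts().to_dict(),
                      n_cpgs=meth.shape[1], n_genes=expr.shape[1],
                      n_snps_per_region=max(geno.shape[1], 1))
    return SyntheticCohort(
        methylation=MethylationMatrix(meth, pos.loc[meth.columns]),
        genotypes=geno, snp_positions=pos.loc[geno.columns],
        expression=expr, gene_positions=pos.loc[expr.columns],
        phenotype=pheno, covariates=covs, truth=truth, spec=spec)
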