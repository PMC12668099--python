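"""Shared containers and tabular schemas.

Per-feature regression output ("association records"), meta-analysis
results and cis-pair scans are carried as pandas DataFrames with fixed
column schemas — the natural columnar currency for tens of thousands of
CpGs. Small structured results (colocalisation posteriors, SMR results,
a fitted risk-score model) are dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mandatory columns of an association-record table: one row per feature,
#: effect on the log-cIMT (or target) scale, its standard error, the
#: t/z statistic, the two-sided p-value and the sample size used.
ASSOC_COLUMNS = ("feature", "effect", "se", "stat", "p", "n")

#: Columns of a cis-pair table produced by :func:`cimtomics.qtl.cis_scan`.
CIS_COLUMNS = (
    "source", "target", "source_chrom", "source_pos", "target_pos",
    "distance", "effect", "se", "p", "n", "f_stat",
)


def validate_assoc(df: pd.DataFrame, *, name: str = "records") -> pd.DataFrame:
    """Check an association-record table against its invariants.

    Raises ``ValueError`` on missing columns, non-positive standard
    errors or p-values outside (0, 1].
    """
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{name} contains non-positive standard errors")
    p = df["p"].to_numpy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError(f"{name} contains p-values outside (0, 1]")
    return df


class MethylationMatrix:
    """Samples x CpGs beta-value matrix with genomic positions.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are CpG ids, entries are
        methylation beta values in [0, 1].
    positions
        DataFrame indexed by CpG id with columns ``chrom`` and ``pos``
        (1-based point coordinate).
    """

    def __init__(self, values: pd.DataFrame, positions: pd.DataFrame):
        if not set(values.columns) <= set(positions.index):
            missing = sorted(set(values.columns) - set(positions.index))[:5]
            raise ValueError(f"positions missing for CpGs {missing} ...")
        vals = values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = values
        self.positions = positions.loc[list(values.columns), ["chrom", "pos"]]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[ids], self.positions)

    def subset_cpgs(self, ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(ids)], self.positions)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MethylationMatrix({self.values.shape[0]} samples x "
                f"{self.values.shape[1]} CpGs)")


@dataclass
class NormativeTable:
    """Reference 75th-percentile cIMT by age bin, sex and ethnicity.

    ``table`` has columns ``age_lo``, ``age_hi`` (half-open [lo, hi)
    years), ``sex``, ``ethnicity`` and ``p75`` (mm). A row with
    ethnicity (or sex) equal to ``"*"`` matches any value — used when
    sparse cells were merged.
    """

    table: pd.DataFrame
    percentile: float = 75.0

    def __post_init__(self):
        req = {"age_lo", "age_hi", "sex", "ethnicity", "p75"}
        if not req <= set(self.table.columns):
            raise ValueError(f"normative table needs columns {sorted(req)}")
        if (self.table["p75"] <= 0).any():
            raise ValueError("percentile values must be positive")

    def lookup(self, age: float, sex, ethnicity) -> float:
        """Return the cell threshold; NaN if the age is out of range."""
        t = self.table
        m = (t["age_lo"] <= age) & (age < t["age_hi"])
        m &= (t["sex"] == sex) | (t["sex"] == "*")
        m &= (t["ethnicity"] == ethnicity) | (t["ethnicity"] == "*")
        hit = t.loc[m, "p75"]
        return float(hit.iloc[0]) if len(hit) else float("nan")


@dataclass
class SmrResult:
    """Single-instrument Wald-ratio result for one exposure-outcome pair."""

    exposure: str
    outcome: str
    instrument: str
    beta_smr: float
    se_smr: float
    p_smr: float
    f_stat: float


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalisation hypotheses.

    ``pp`` holds (PP.H0 .. PP.H4): no association, trait-1 only,
    trait-2 only, two distinct causal variants, one shared variant.
    """

    region: str
    pp: np.ndarray
    priors: tuple
    n_snps: int
    h4_h3_ratio: float
    call: str

    def __post_init__(self):
        self.pp = np.asarray(self.pp, dtype=float)
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")


@dataclass
class MrsModel:
    """Ordered sentinel CpGs and their weights for the methylation risk score."""

    cpgs: list
    weights: np.ndarray
    weight_mode: str = "basic"
    training_hash: str = ""
    seed: int | None = None
    per_stratum: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.cpgs) < 1:
            raise ValueError("a risk score needs at least one CpG")
        if len(self.cpgs) != len(self.weights):
            raise ValueError("one weight per CpG required")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cpg": self.cpgs, "weight": self.weights,
            "mode": self.weight_mode, "seed": self.seed,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MrsModel":
        seed = df["seed"].iloc[0] if "seed" in df and len(df) else None
        return cls(
            cpgs=list(df["cpg"]),
            weights=df["weight"].to_numpy(float),
            weight_mode=str(df["mode"].iloc[0]) if "mode" in df else "basic",
            seed=None if pd.isna(seed) else int(seed),
        )
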