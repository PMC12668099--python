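"""Synthetic multi-ethnic, multi-omic cohorts with known ground truth.

The generator emulates the data structure of a population methylation
study of carotid intima-media thickness: EPIC-like methylation beta
matrices with genomic positions, a positive log-normal-ish cIMT
phenotype driven by age, sex, smoking and injected CpG effects,
ethnicity strata with Table-1-like default sizes, genotype dosage
blocks with AR(1) linkage disequilibrium for cis-QTL regions, gene
expression for eQTM/eQTL, and a normative 75th-percentile cIMT table.

Conventions for injected effects (the ``effect_table``):

* ``(cpg, "phenotype", e)`` — log-cIMT increases by ``e`` per SD of the
  CpG's beta value (slope per unit beta recorded in the truth table).
* ``(snp, cpg, e)`` — the CpG's latent logit-methylation increases by
  ``e`` per SD of dosage; beta values stay inside (0, 1).
* ``(cpg, gene, e)`` / ``(snp, gene, e)`` — expression increases by
  ``e`` per SD of the source.

All randomness flows from ``spec.seed``; the same spec yields
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .types import MethylationMatrix, NormativeTable

__all__ = ["CohortSpec", "SyntheticCohort", "simulate_cohort",
           "simulate_coloc_region", "make_normative_table"]

#: Default stratum sizes of a multi-ethnic Asian discovery cohort.
DEFAULT_STRATA = {"Chinese": 1063, "Malay": 150, "Indian": 144}

_STRATUM_CODE = {"Chinese": "CHN", "Malay": "MLY", "Indian": "IND"}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_table`` rows are (feature-id, target-id, effect-size); see
    the module docstring for the scale conventions. ``noise_sd`` is the
    SD of the residual on the log-cIMT scale.
    """

    n_per_stratum: dict = field(
        default_factory=lambda: dict(DEFAULT_STRATA))
    n_cpgs: int = 200
    n_genes: int = 20
    n_snps_per_region: int = 50
    n_regions: int = 1
    effect_table: list = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 0
    ld_rho: float = 0.8
    meth_noise_sd: float = 0.4  # logit scale
    expr_noise_sd: float = 1.0
    n_tech_pcs: int = 5
    n_cell_types: int = 6

    def cpg_ids(self):
        return [f"cg{i:06d}" for i in range(1, self.n_cpgs + 1)]

    def gene_ids(self):
        return [f"gene{i:04d}" for i in range(1, self.n_genes + 1)]

    def snp_ids(self):
        return [f"snp{r:02d}_{j:03d}"
                for r in range(1, self.n_regions + 1)
                for j in range(1, self.n_snps_per_region + 1)]

    def validate(self):
        for name, n in self.n_per_stratum.items():
            if n < 1:
                raise ValueError(f"stratum {name!r} must have >= 1 sample")
        for attr in ("n_cpgs", "n_genes", "n_snps_per_region", "n_regions"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        known = set(self.cpg_ids()) | set(self.gene_ids()) | set(self.snp_ids())
        for src, tgt, eff in self.effect_table:
            if src not in known:
                raise ValueError(f"effect source {src!r} not a declared feature")
            if tgt != "phenotype" and tgt not in known:
                raise ValueError(f"effect target {tgt!r} not declared")
            float(eff)


@dataclass
class SyntheticCohort:
    """All blocks of one simulated cohort, aligned on sample id."""

    methylation: MethylationMatrix
    genotypes: pd.DataFrame
    snp_positions: pd.DataFrame
    expression: pd.DataFrame
    gene_positions: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec

    def __post_init__(self):
        n = len(self.phenotype)
        for block in (self.methylation.values, self.genotypes,
                      self.expression, self.covariates):
            if len(block) != n:
                raise ValueError("sample counts differ across blocks")
        if (self.phenotype <= 0).any():
            raise ValueError("cIMT must be positive")


def _layout_positions(ids, chrom_count=22, start=1_000_000, spacing=50_000):
    """Spread features across chromosomes; positions 1-based points."""
    n = len(ids)
    per_chrom = -(-n // chrom_count)
    chroms = [f"chr{1 + i // per_chrom}" for i in range(n)]
    pos = [start + (i % per_chrom) * spacing for i in range(n)]
    return pd.DataFrame({"chrom": chroms, "pos": pos}, index=pd.Index(ids))


def _ld_dosages(rng, n, mafs, rho):
    """Dosage matrix with AR(1) latent LD, entries in {0, 1, 2}."""
    m = len(mafs)
    if m == 1:
        corr = np.ones((1, 1))
    else:
        idx = np.arange(m)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    thresh = stats.norm.ppf(mafs)
    hap1 = (rng.standard_normal((n, m)) @ chol.T) < thresh
    hap2 = (rng.standard_normal((n, m)) @ chol.T) < thresh
    return (hap1.astype(float) + hap2.astype(float))


def _standardise(x):
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardise a constant feature")
    return (x - x.mean()) / sd, sd


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort; see the module docstring for the model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- samples & covariates -------------------------------------------
    strata, ids = [], []
    for name, n in spec.n_per_stratum.items():
        code = _STRATUM_CODE.get(name, name[:3].upper())
        ids += [f"{code}_{i:05d}" for i in range(1, n + 1)]
        strata += [name] * n
    n_total = len(ids)
    idx = pd.Index(ids, name="sample")
    age = rng.uniform(30.0, 84.0, n_total)
    sex = rng.integers(0, 2, n_total)
    smoking = rng.choice(["never", "former", "current"], n_total,
                         p=[0.6, 0.25, 0.15])
    cells = rng.dirichlet([10, 4, 3, 2, 1, 1][:spec.n_cell_types],
                          n_total) * 0.97
    pcs = rng.standard_normal((n_total, spec.n_tech_pcs))
    covariates = pd.DataFrame({
        "age": age, "sex": sex, "stratum": strata, "smoking": smoking,
        **{f"cell{i + 1}": cells[:, i] for i in range(spec.n_cell_types)},
        **{f"pc{i + 1}": pcs[:, i] for i in range(spec.n_tech_pcs)},
    }, index=idx)

    # --- feature coordinates --------------------------------------------
    cpg_ids, gene_ids, snp_ids = (spec.cpg_ids(), spec.gene_ids(),
                                  spec.snp_ids())
    cpg_pos = _layout_positions(cpg_ids)
    # each gene's TSS sits 200 kb from the like-indexed CpG (cis by design)
    gene_pos = pd.DataFrame({
        "chrom": cpg_pos["chrom"].to_numpy()[
            np.arange(spec.n_genes) % spec.n_cpgs],
        "pos": cpg_pos["pos"].to_numpy()[
            np.arange(spec.n_genes) % spec.n_cpgs] + 200_000,
    }, index=pd.Index(gene_ids))
    # SNP region r is anchored at the r-th CpG
    snp_chroms, snp_posv = [], []
    span = 500_000
    for r in range(spec.n_regions):
        anchor = cpg_pos.iloc[r % spec.n_cpgs]
        offs = np.linspace(-span // 2, span // 2,
                           spec.n_snps_per_region).astype(int)
        snp_chroms += [anchor["chrom"]] * spec.n_snps_per_region
        snp_posv += list(np.maximum(anchor["pos"] + offs, 1))
    snp_pos = pd.DataFrame({"chrom": snp_chroms, "pos": snp_posv},
                           index=pd.Index(snp_ids))

    # --- genotypes -------------------------------------------------------
    blocks = []
    for r in range(spec.n_regions):
        mafs = rng.uniform(0.1, 0.5, spec.n_snps_per_region)
        blocks.append(_ld_dosages(rng, n_total, mafs, spec.ld_rho))
    genotypes = pd.DataFrame(np.hstack(blocks) if blocks else
                             np.empty((n_total, 0)),
                             index=idx, columns=snp_ids)

    effects = [(s, t, float(e)) for s, t, e in spec.effect_table]
    truth_rows = []

    # --- methylation (latent logit scale) --------------------------------
    base_means = rng.uniform(0.15, 0.85, spec.n_cpgs)
    latent = np.tile(logit(base_means), (n_total, 1))
    stratum_shift = rng.normal(0.0, 0.1,
                               (len(spec.n_per_stratum), spec.n_cpgs))
    stratum_index = pd.Categorical(strata,
                                   list(spec.n_per_stratum)).codes
    latent += stratum_shift[stratum_index]
    for src, tgt, eff in effects:
        if src in genotypes.columns and tgt in cpg_ids:
            z, sd = _standardise(genotypes[src].to_numpy())
            j = cpg_ids.index(tgt)
            latent[:, j] += eff * z
            truth_rows.append((src, tgt, eff, "logit_per_sd_dosage",
                               sd, eff / sd))
    # per-CpG noise scale: array CpGs differ widely in variability
    noise_scale = spec.meth_noise_sd * rng.uniform(0.5, 1.5, spec.n_cpgs)
    latent += rng.standard_normal(latent.shape) * noise_scale
    beta = expit(latent)
    methylation = MethylationMatrix(
        pd.DataFrame(beta, index=idx, columns=cpg_ids), cpg_pos)

    # --- expression ------------------------------------------------------
    expr = np.tile(rng.uniform(4.0, 8.0, spec.n_genes), (n_total, 1))
    for src, tgt, eff in effects:
        if tgt in gene_ids:
            if src in cpg_ids:
                source = beta[:, cpg_ids.index(src)]
            elif src in genotypes.columns:
                source = genotypes[src].to_numpy()
            else:
                continue
            z, sd = _standardise(source)
            expr[:, gene_ids.index(tgt)] += eff * z
            truth_rows.append((src, tgt, eff, "expression_per_sd_source",
                               sd, eff / sd))
    expr += rng.normal(0.0, spec.expr_noise_sd, expr.shape)
    if expr.min() < 0:  # keep abundances non-negative without changing slopes
        expr -= expr.min()
    expression = pd.DataFrame(expr, index=idx, columns=gene_ids)

    # --- phenotype -------------------------------------------------------
    stratum_cimt = dict(zip(spec.n_per_stratum,
                            np.linspace(0.0, 0.03,
                                        len(spec.n_per_stratum))))
    ln_c = (np.log(0.65)
            + 0.004 * (age - 55.0)
            + 0.03 * sex
            + np.array([stratum_cimt[s] for s in strata])
            + 0.04 * (smoking == "current")
            + 0.02 * (smoking == "former"))
    for src, tgt, eff in effects:
        if tgt == "phenotype":
            if src not in cpg_ids:
                raise ValueError(
                    f"phenotype effects must come from CpGs, got {src!r}")
            z, sd = _standardise(beta[:, cpg_ids.index(src)])
            ln_c += eff * z
            truth_rows.append((src, tgt, eff, "log_cimt_per_sd_beta",
                               sd, eff / sd))
    ln_c += rng.normal(0.0, spec.noise_sd, n_total)
    phenotype = pd.Series(np.exp(ln_c), index=idx, name="cimt")

    truth = pd.DataFrame(truth_rows, columns=[
        "feature", "target", "effect", "scale", "source_sd",
        "slope_per_unit"])
    return SyntheticCohort(methylation, genotypes, snp_pos, expression,
                           gene_pos, phenotype, covariates, truth, spec)


# --------------------------------------------------------------------------
# colocalisation scenario panels


def _marginal_stats(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple-regression beta, se over a dosage matrix."""
    n, m = G.shape
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    beta = (Gc.T @ yc) / sxx
    ssr = float(yc @ yc) - beta ** 2 * sxx
    se = np.sqrt(np.maximum(ssr, 0.0) / (n - 2) / sxx)
    return pd.DataFrame({"beta": beta, "se": se, "n": n,
                         "eaf": G.mean(axis=0) / 2.0})


def simulate_coloc_region(scenario: str, n1: int, n2: int, n_snps: int,
                          seed: int, *, effect: float = 0.4,
                          rho: float = 0.8,
                          trait2_type: str = "quant",
                          prevalence: float = 0.2):
    """Summary-statistic panels for one colocalisation scenario.

    Scenarios: ``H0`` no causal SNP; ``H1``/``H2`` a causal SNP for one
    trait only; ``H3`` two distinct causal SNPs; ``H4`` one shared
    causal SNP. Two independent sample sets of sizes ``n1``/``n2`` are
    drawn from the same LD structure; ``effect`` is the per-allele
    effect in trait-SD units. With ``trait2_type="cc"``, trait 2 is a
    liability-threshold case/control outcome at the given prevalence
    and its summary statistics come from linear regression on the 0/1
    indicator.

    Returns ``(panel1, panel2)`` DataFrames with columns
    ``snp, beta, se, n, eaf``; each panel's ``.attrs`` records the
    scenario and the causal SNP (or None).
    """
    if n_snps < 10:
        raise ValueError("n_snps must be >= 10")
    scenario = scenario.upper()
    if scenario not in {"H0", "H1", "H2", "H3", "H4"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.1, 0.5, n_snps)
    snp_names = [f"rs{i:04d}" for i in range(1, n_snps + 1)]

    c1 = c2 = None
    if scenario in {"H1", "H3", "H4"}:
        c1 = int(rng.integers(0, n_snps))
    if scenario == "H4":
        c2 = c1
    elif scenario in {"H2", "H3"}:
        while True:
            c2 = int(rng.integers(0, n_snps))
            if scenario == "H2" or abs(c2 - c1) >= max(10, n_snps // 10):
                break

    panels = []
    for n, causal, kind in ((n1, c1, "quant"), (n2, c2, trait2_type)):
        G = _ld_dosages(rng, n, mafs, rho)
        signal = effect * G[:, causal] if causal is not None else 0.0
        liability = signal + rng.standard_normal(n)
        if kind == "cc":
            cut = np.quantile(liability, 1.0 - prevalence)
            y = (liability >= cut).astype(float)
        else:
            y = liability
        panel = _marginal_stats(G, y)
        panel.insert(0, "snp", snp_names)
        panel.attrs.update(scenario=scenario,
                           causal=None if causal is None
                           else snp_names[causal],
                           trait_type=kind)
        panels.append(panel)
    return panels[0], panels[1]


# --------------------------------------------------------------------------
# normative table

DEFAULT_AGE_EDGES = (30.0, 45.0, 55.0, 65.0, 85.0)


def make_normative_table(cohort: SyntheticCohort,
                         age_edges=DEFAULT_AGE_EDGES,
                         min_cell: int = 30,
                         percentile: float = 75.0) -> NormativeTable:
    """Empirical 75th-percentile cIMT per age-bin x sex x ethnicity.

    Cells with fewer than ``min_cell`` samples are merged across
    ethnicity (wildcard ``"*"``); if a merged cell is still too small
    it is further merged across sex. Percentiles use linear (type-7)
    interpolation.
    """
    covs = cohort.covariates
    cimt = cohort.phenotype
    edges = np.asarray(age_edges, dtype=float)
    bins = pd.cut(covs["age"], edges, right=False, labels=False)
    if bins.isna().any():
        raise ValueError("age_edges do not cover the simulated age range")
    frame = pd.DataFrame({"bin": bins.astype(int), "sex": covs["sex"],
                          "eth": covs["stratum"], "cimt": cimt})
    rows = []
    for (b, sex), grp in frame.groupby(["bin", "sex"], sort=True):
        small = []
        for eth, sub in grp.groupby("eth", sort=True):
            if len(sub) >= min_cell:
                rows.append((edges[b], edges[b + 1], sex, eth,
                             np.quantile(sub["cimt"], percentile / 100)))
            else:
                small.append(sub)
        if small:
            pooled = pd.concat(small)
            if len(pooled) >= min_cell:
                rows.append((edges[b], edges[b + 1], sex, "*",
                             np.quantile(pooled["cimt"], percentile / 100)))
            else:
                # fall back to the whole age-bin (both sexes) for tiny cells
                rows.append((edges[b], edges[b + 1], sex, "*",
                             np.quantile(grp["cimt"], percentile / 100)))
    if not rows:
        raise ValueError("no populated normative cells")
    table = pd.DataFrame(rows, columns=["age_lo", "age_hi", "sex",
                                        "ethnicity", "p75"])
    return NormativeTable(table, percentile=percentile)
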