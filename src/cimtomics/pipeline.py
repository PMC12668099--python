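"""Top-level pipeline driver: simulate -> ewas -> meta -> qtl -> causal
-> mrs -> enrichment, with per-stage outputs and a run manifest.

The driver exercises the whole analysis end-to-end on synthetic
cohorts: an Asian-like discovery cohort with ethnic strata and a
second, European-like cohort generated from the same effect table for
the trans-ancestry stage. Every stage writes tab-delimited outputs to
the run directory and the manifest records seeds, the config hash and
an SHA-256 per output file, so reruns with the same config are
bit-identical and any stage's outputs can seed downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal, enrichment, io, meta, mrs, qtl
from .ewas import quantile_normalise, run_ewas
from .synthetic import CohortSpec, make_normative_table, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]

STAGES = ("simulate", "ewas", "meta", "qtl", "causal", "mrs", "enrichment")


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds, toggles and seeds of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    # cohort
    n_per_stratum: dict = dataclasses.field(
        default_factory=lambda: {"Chinese": 650, "Malay": 120, "Indian": 120})
    european_strata: dict = dataclasses.field(
        default_factory=lambda: {"SHIP": 400, "NSHD": 300})
    n_cpgs: int = 500
    n_genes: int = 20
    n_snps_per_region: int = 40
    n_regions: int = 3
    effect_table: list = dataclasses.field(default_factory=lambda: [
        ["cg000005", "phenotype", 0.08],
        ["cg000055", "phenotype", 0.08],
        ["cg000105", "phenotype", 0.08],
        ["snp01_020", "cg000005", 0.5],
        ["cg000005", "gene0005", 0.4],
        ["snp01_020", "gene0005", 0.3],
    ])
    noise_sd: float = 0.1
    # thresholds
    stage1_alpha: float = 0.05
    bonferroni_base: float = 0.05
    stage1_method: str = "stouffer"
    window_bp: int = 1_000_000
    instrument_p_max: float = 1e-5
    instrument_f_min: float = 10.0
    coloc_priors: tuple = causal.DEFAULT_PRIORS
    p12_grid: tuple = (2.51e-6, 1e-5, 3.16e-5)
    enrichment_p: float = 1e-3
    eqtm_p: float = 0.05
    n_sets: int = 200
    split_fraction: float = 0.7
    ewas_model: tuple = ("age", "sex", "smoking")

    def validate(self):
        for name in ("stage1_alpha", "bonferroni_base", "instrument_p_max",
                     "enrichment_p", "eqtm_p", "split_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["coloc_priors"] = list(self.coloc_priors)
        d["p12_grid"] = list(self.p12_grid)
        d["ewas_model"] = list(self.ewas_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("stages", "coloc_priors", "p12_grid", "ewas_model"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def default_config(out_dir: str = "run", seed: int = 0) -> PipelineConfig:
    return PipelineConfig(out_dir=out_dir, seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gwas_panel(cohort, snps) -> pd.DataFrame:
    """Per-SNP association of log-cIMT with dosage inside the cohort."""
    y = np.log(cohort.phenotype.to_numpy(float))
    from .synthetic import _marginal_stats
    panel = _marginal_stats(cohort.genotypes[snps].to_numpy(float), y)
    panel.insert(0, "snp", list(snps))
    return panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure halts the run with the stage named in the raised
    error; outputs of completed stages persist in ``out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {"config": cfg_dict, "config_hash": cfg_hash,
                "seed": config.seed, "stages": [], "outputs": {}}
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
        manifest["outputs"][f.name] = _sha256(f)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, out, state):
    spec = CohortSpec(
        n_per_stratum=dict(config.n_per_stratum), n_cpgs=config.n_cpgs,
        n_genes=config.n_genes, n_snps_per_region=config.n_snps_per_region,
        n_regions=config.n_regions,
        effect_table=[tuple(e) for e in config.effect_table],
        noise_sd=config.noise_sd, seed=config.seed)
    state["cohort"] = simulate_cohort(spec)
    eur_spec = dataclasses.replace(
        spec, n_per_stratum=dict(config.european_strata),
        seed=config.seed + 1)
    state["european"] = simulate_cohort(eur_spec)
    io.write_cohort(state["cohort"], out / "cohort")
    state["norm_meth"] = quantile_normalise(state["cohort"].methylation)


def _ewas_per_stratum(cohort, model, normalised=None):
    meth = normalised if normalised is not None else quantile_normalise(
        cohort.methylation)
    records = {}
    for name, members in cohort.covariates.groupby("stratum", sort=True):
        ids = members.index
        records[str(name)] = run_ewas(
            meth.subset_samples(ids), cohort.phenotype.loc[ids],
            cohort.covariates.loc[ids], list(model))
    return records


def _stage_ewas(config, out, state):
    state["stage1_records"] = _ewas_per_stratum(
        state["cohort"], config.ewas_model, state.get("norm_meth"))
    state["stage2_records"] = _ewas_per_stratum(
        state["european"], config.ewas_model)
    for name, rec in {**state["stage1_records"],
                      **state["stage2_records"]}.items():
        io.write_summary_stats(rec, out / f"ewas_{name}.tsv")


def _stage_meta(config, out, state):
    screen = meta.two_stage_screen(
        state["stage1_records"], state["stage2_records"],
        stage1_alpha=config.stage1_alpha,
        bonferroni_base=config.bonferroni_base,
        positions=state["cohort"].methylation.positions,
        stage1_method=config.stage1_method)
    state["screen"] = screen
    screen.stage2.to_csv(out / "meta_stage2.tsv", sep="\t", index=False)
    screen.sentinels.to_csv(out / "sentinels.tsv", sep="\t", index=False)
    logger.info("threshold %.3g, %d sentinels", screen.threshold,
                len(screen.sentinels))


def _stage_qtl(config, out, state):
    cohort = state["cohort"]
    covs = cohort.covariates
    meth = state["norm_meth"]
    state["meqtl"] = qtl.cis_scan(
        cohort.genotypes, cohort.snp_positions, meth.values, meth.positions,
        covs, ["age", "sex", "stratum"], config.window_bp)
    state["eqtm"] = qtl.cis_scan(
        meth.values, meth.positions, cohort.expression,
        cohort.gene_positions, covs, ["age", "sex", "stratum"],
        config.window_bp)
    state["eqtl"] = qtl.cis_scan(
        cohort.genotypes, cohort.snp_positions, cohort.expression,
        cohort.gene_positions, covs, ["age", "sex", "stratum"],
        config.window_bp)
    for name in ("meqtl", "eqtm", "eqtl"):
        state[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _stage_causal(config, out, state):
    sentinels = list(state["screen"].sentinels["feature"])
    instruments = qtl.select_instruments(
        state["meqtl"][state["meqtl"]["target"].isin(sentinels)],
        config.instrument_p_max, config.instrument_f_min)
    smr_rows, coloc_rows = [], []
    for row in instruments.itertuples(index=False):
        gwas = _gwas_panel(state["cohort"],
                           state["meqtl"].loc[
                               state["meqtl"]["target"] == row.target,
                               "source"].unique())
        outcome = gwas.set_index("snp").loc[row.source]
        res = causal.smr_wald(
            {"snp": row.source, "beta": row.effect, "se": row.se,
             "f_stat": row.f_stat, "exposure": row.target},
            {"snp": row.source, "beta": outcome["beta"],
             "se": outcome["se"], "outcome": "cimt"})
        smr_rows.append(dataclasses.asdict(res))
        panel1 = state["meqtl"][state["meqtl"]["target"] == row.target]
        panel1 = panel1.rename(columns={"source": "snp", "effect": "beta"})[
            ["snp", "beta", "se"]]
        results, robust = causal.p12_sensitivity(
            panel1, gwas, config.p12_grid,
            p1=config.coloc_priors[0], p2=config.coloc_priors[1],
            region=row.target)
        default_res = causal.coloc_abf(panel1, gwas, config.coloc_priors,
                                       region=row.target)
        coloc_rows.append({
            "region": row.target, "n_snps": default_res.n_snps,
            **{f"pp_h{i}": default_res.pp[i] for i in range(5)},
            "call": default_res.call, "p12_robust": robust})
    state["smr"] = pd.DataFrame(smr_rows)
    state["coloc"] = pd.DataFrame(coloc_rows)
    state["smr"].to_csv(out / "smr.tsv", sep="\t", index=False)
    state["coloc"].to_csv(out / "coloc.tsv", sep="\t", index=False)


def _stage_mrs(config, out, state):
    cohort = state["cohort"]
    sentinels = list(state["screen"].sentinels["feature"])
    if not sentinels:
        logger.warning("no sentinels; MRS stage skipped")
        return
    table = make_normative_table(cohort)
    labels = mrs.label_elevated(cohort.phenotype, cohort.covariates, table)
    joint = (cohort.covariates.loc[labels.index, "stratum"].astype(str)
             + "|" + labels.astype(str))
    train, test = mrs.stratified_split(labels.index, joint,
                                       config.split_fraction, config.seed)
    model = mrs.fit_weights(
        cohort.methylation.subset_samples(train),
        cohort.phenotype.loc[train], cohort.covariates.loc[train],
        sentinels, seed=config.seed)
    scores = mrs.score(model, cohort.methylation.subset_samples(test))
    report = mrs.evaluate(scores, labels.loc[test],
                          cohort.covariates.loc[test])
    model.to_frame().to_csv(out / "mrs_model.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [(m, *vals) for m, vals in report.auc.items()],
        columns=["model", "auc", "ci_lo", "ci_hi"])
    summary.to_csv(out / "mrs_auc.tsv", sep="\t", index=False)
    report.quartile_or.to_csv(out / "mrs_quartiles.tsv", sep="\t",
                              index=False)
    state["mrs_report"] = report


def _stage_enrichment(config, out, state):
    cohort = state["cohort"]
    stage2 = state["screen"].stage2
    test_cpgs = list(stage2.loc[stage2["p"] < config.enrichment_p,
                                "feature"])
    if len(test_cpgs) < 1:
        logger.warning("no CpGs below the inclusive threshold; "
                       "enrichment skipped")
        return
    beta = cohort.methylation.values
    universe = pd.DataFrame({
        "mean": beta.mean(axis=0), "sd": beta.std(axis=0, ddof=1),
        "chrom": cohort.methylation.positions["chrom"],
        "pos": cohort.methylation.positions["pos"]})
    background = enrichment.match_background(
        test_cpgs, universe, n_sets=config.n_sets, seed=config.seed)
    test_genes = enrichment.map_cpgs_to_genes(
        test_cpgs, state["eqtm"], config.eqtm_p)
    bg_genes = [enrichment.map_cpgs_to_genes(s, state["eqtm"],
                                             config.eqtm_p)
                for s in background.sets]
    rng = np.random.default_rng(config.seed + 7)
    genes = list(cohort.expression.columns)
    collections = {
        f"pathway{i:02d}": set(rng.choice(
            genes, size=max(2, len(genes) // 4), replace=False))
        for i in range(1, 11)}
    gs = enrichment.geneset_enrichment(test_genes, bg_genes, collections)
    gs.to_csv(out / "enrichment_genesets.tsv", sep="\t", index=False)
    pos = cohort.methylation.positions
    tfbs = {}
    for i in range(1, 11):
        anchors = rng.choice(len(pos), size=max(3, len(pos) // 10),
                             replace=False)
        tfbs[f"TF{i:02d}"] = [
            (pos.iloc[a]["chrom"], int(pos.iloc[a]["pos"]) - 500,
             int(pos.iloc[a]["pos"]) + 500) for a in anchors]
    tf = enrichment.tfbs_enrichment(test_cpgs, background, pos, tfbs)
    tf.to_csv(out / "enrichment_tfbs.tsv", sep="\t", index=False)
    background.matching_log.to_csv(out / "enrichment_matching.tsv",
                                   sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ewas": _stage_ewas,
    "meta": _stage_meta,
    "qtl": _stage_qtl,
    "causal": _stage_causal,
    "mrs": _stage_mrs,
    "enrichment": _stage_enrichment,
}
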