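"""End-to-end pipeline driver.

Stages: probe filter -> per-CpG mixed models (interaction and group) ->
BH-FDR -> spatially corrected region calling on each model's p-values ->
direction-consistency classification and retention -> region-level eQTM and
metQTM in whatever omics overlap is available.  Each stage logs its record
counts and the active seed; outputs are reproducible for a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import combp, dmr, io, qtm
from .errors import ConfigurationError
from .ewas import fit_dmp_batch
from .simulate import (
    CohortDesign,
    ExpressionData,
    GroundTruth,
    MetaboliteData,
    MethylationDataset,
    generate_linked_omics,
    generate_manifest,
    generate_methylation,
    generate_samples,
    plant_ground_truth,
)

log = logging.getLogger("longmeth")


@dataclass
class PipelineConfig:
    """Thresholds, covariate lists, paths and seed for one pipeline run."""

    seed: int = 0
    seed_p: float = 0.1
    window: int = 500
    step: int = 50
    dist: int = 500
    min_probes: int = 4
    sidak_alpha: float = 0.10
    fdr_alpha: float = 0.10
    cis_window: int = 500_000
    beta_range_min: float = 0.03
    covariates_delta_qtm: tuple = ("age", "sex", "platform", "cell_props")
    covariates_mu_qtm: tuple = ("age", "sex", "platform", "cell_props", "ancestry")
    paths: dict = field(default_factory=dict)  # manifest/sample_sheet/matrix/tss/...
    simulate: dict = field(default_factory=dict)  # synthetic-cohort settings

    def validate(self):
        for name in ("seed_p", "sidak_alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        for name in ("window", "step", "dist", "min_probes", "cis_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        flat = dict(d)
        flat.update(flat.pop("thresholds", {}))
        cfg = cls(**{k: v for k, v in flat.items() if k in known})
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: MethylationDataset
    kept_probes: pd.Index
    dmp_interaction: pd.DataFrame
    dmp_group: pd.DataFrame
    delta_records: list
    mu_records: list
    retained_delta: list
    retained_mu: list
    eqtm: pd.DataFrame | None
    metqtm: pd.DataFrame | None
    counts: dict


def simulate_dataset(config: PipelineConfig):
    """Build the synthetic cohort described by ``config.simulate``.

    Returns ``(dataset, truth, expression, metabolites)``.
    """
    sim = dict(config.simulate)
    design_kwargs = sim.pop("design", {})
    design = CohortDesign(seed=config.seed, **design_kwargs)
    manifest = generate_manifest(seed=config.seed, **sim.pop("manifest", {}))
    samples = generate_samples(design)
    truth = plant_ground_truth(manifest, seed=config.seed, **sim.pop("truth", {}))
    dataset = generate_methylation(manifest, samples, truth, design)
    omics_kwargs = sim.pop("omics", {})
    expression, metabolites = generate_linked_omics(
        truth, samples, dataset, seed=config.seed, **omics_kwargs
    )
    return dataset, truth, expression, metabolites


def _call_and_classify(dataset, dmp, config, model):
    man = dataset.manifest.set_index("probe_id").loc[dmp.index]
    order = np.lexsort((man["pos"].to_numpy(), man["chrom"].to_numpy()))
    ids = dmp.index.to_numpy()[order]
    pos = man["pos"].to_numpy()[order]
    chrom = man["chrom"].to_numpy()[order]
    pvals = dmp["p_2df"].to_numpy()[order]
    regions = combp.call_regions(
        pvals, pos, chrom, ids, window=config.window, step=config.step,
        seed_p=config.seed_p, dist=config.dist,
    )
    records = []
    for i, region in enumerate(regions, start=1):
        if model == "interaction":
            records.append(dmr.summarize_delta_region(region, dmp, region_id=f"dDMR{i}"))
        else:
            records.append(dmr.summarize_mu_region(region, dmp, region_id=f"mDMR{i}"))
    if model == "interaction":
        retained = dmr.filter_delta_dmrs(records, config.min_probes, config.sidak_alpha)
    else:
        retained = dmr.filter_mu_dmrs(records, config.min_probes, config.sidak_alpha)
    return records, retained


def _region_scores(dataset, records, mode, covariates):
    """Per-subject PC1 score of residualised, paired-contrast CpG values."""
    if "ancestry" in covariates:
        # complete case: ancestry-adjusted scores need the PCs
        keep = dataset.samples["pc1"].notna() & dataset.samples["pc2"].notna()
        if not keep.all():
            dataset = MethylationDataset(
                values=dataset.values.loc[:, dataset.samples.index[keep]],
                manifest=dataset.manifest,
                samples=dataset.samples[keep],
            )
    scores = {}
    for rec in records:
        cols = {}
        for pid in rec.probe_ids:
            resid = qtm.residualize_repeated(
                dataset.values.loc[pid], dataset.samples, covariates,
                random_intercept=True,
            )
            cols[pid] = qtm.paired_contrast(resid, dataset.samples, mode)
        mat = pd.DataFrame(cols)
        scores[rec.region_id] = qtm.region_pc1(mat, region_id=rec.region_id, mode=mode)
    return scores


def _run_eqtm(dataset, retained_delta, retained_mu, expression, config):
    results = []
    expr_subjects = [s for s in expression.values.columns]
    post = dataset.samples[dataset.samples["visit"] == "post"]
    post = post[post["subject_id"].isin(expr_subjects)]
    # expression residuals: regress out age (at post visit) and sex
    cov = pd.DataFrame({
        "intercept": 1.0,
        "age": post.set_index("subject_id")["age"],
        "sex_female": (post.set_index("subject_id")["sex"] == "F").astype(float),
    })
    overlap = dataset.samples[dataset.samples["subject_id"].isin(expr_subjects)]
    sub = MethylationDataset(
        values=dataset.values[overlap.index], manifest=dataset.manifest, samples=overlap
    )
    for family, records, mode, covs in (
        ("delta", retained_delta, "delta", config.covariates_delta_qtm),
        ("mu", retained_mu, "mean", config.covariates_mu_qtm),
    ):
        if not records:
            continue
        scores = _region_scores(sub, records, mode, covs)
        fam_results = []
        for rec in records:
            genes = qtm.cis_features(rec, expression.tss, window=config.cis_window)
            for gid in genes:
                expr = expression.values.loc[gid].reindex(cov.index)
                X = cov.to_numpy(dtype=float)
                beta, *_ = np.linalg.lstsq(X, expr.to_numpy(dtype=float), rcond=None)
                resid = pd.Series(expr.to_numpy() - X @ beta, index=cov.index)
                fam_results.append(qtm.eqtm_test(scores[rec.region_id], resid, feature_id=gid))
        if fam_results:
            df = qtm.results_to_frame(fam_results)
            df["family"] = family
            df["q_bh"] = qtm.bh_fdr(df["p"].to_numpy())
            results.append(df)
    if not results:
        return None
    return pd.concat(results, ignore_index=True)


def _run_metqtm(dataset, retained_delta, retained_mu, metabolites, config):
    met_samples = [s for s in metabolites.values.columns if s in dataset.samples.index]
    if not met_samples:
        return None
    overlap = dataset.samples.loc[met_samples]
    sub = MethylationDataset(
        values=dataset.values[overlap.index], manifest=dataset.manifest, samples=overlap
    )
    # Box-Cox then per-visit residualisation on age and sex
    contrasts = {}
    for mid in metabolites.values.index:
        raw = metabolites.values.loc[mid, met_samples]
        transformed, _ = qtm.boxcox(raw.to_numpy(dtype=float))
        series = pd.Series(transformed, index=met_samples)
        resid = pd.Series(index=series.index, dtype=float)
        for visit in ("pre", "post"):
            vidx = overlap.index[overlap["visit"] == visit]
            resid.loc[vidx] = qtm.residualize_repeated(
                series.loc[vidx], overlap.loc[vidx], ("age", "sex"),
                random_intercept=False,
            )
        contrasts[mid] = resid
    results = []
    for family, records, mode, covs in (
        ("delta", retained_delta, "delta", config.covariates_delta_qtm),
        ("mu", retained_mu, "mean", config.covariates_mu_qtm),
    ):
        if not records:
            continue
        scores = _region_scores(sub, records, mode, covs)
        for rec in records:
            for mid, resid in contrasts.items():
                contrast = qtm.paired_contrast(resid, overlap, mode)
                panel = str(metabolites.panels.loc[mid])
                res = qtm.metqtm_test(scores[rec.region_id], contrast, panel, feature_id=mid)
                results.append(res)
    if not results:
        return None
    df = qtm.results_to_frame(results)
    return qtm.fdr_by_stratum(df, by="panel")


def run_pipeline(config: PipelineConfig | None = None, *,
                 dataset: MethylationDataset | None = None,
                 expression: ExpressionData | None = None,
                 metabolites: MetaboliteData | None = None,
                 truth: GroundTruth | None = None,
                 out_dir=None) -> PipelineResult:
    """Execute the full analysis; see module docstring for stage order."""
    config = config or PipelineConfig()
    config.validate()
    log.info("pipeline start: seed=%d", config.seed)

    if dataset is None:
        if config.simulate or not config.paths:
            dataset, truth, sim_expr, sim_mets = simulate_dataset(config)
            expression = expression if expression is not None else sim_expr
            metabolites = metabolites if metabolites is not None else sim_mets
            log.info("simulated cohort: %d probes x %d samples",
                     *dataset.values.shape)
        else:
            dataset = io.read_methylation(
                config.paths["matrix"], config.paths["manifest"],
                config.paths["sample_sheet"],
            )
            log.info("loaded cohort: %d probes x %d samples", *dataset.values.shape)

    from .ewas import filter_probes

    kept = filter_probes(dataset.manifest, beta_range_min=config.beta_range_min)
    log.info("probe filter: kept %d of %d probes", len(kept), len(dataset.manifest))
    values = dataset.values.loc[[p for p in dataset.values.index if p in set(kept)]]

    dmp_int = fit_dmp_batch(values, dataset.samples, "interaction")
    log.info("interaction DMP: %d probes tested, %d FDR<%.2f",
             int(dmp_int["p_2df"].notna().sum()),
             int((dmp_int["q_bh"] < config.fdr_alpha).sum()), config.fdr_alpha)
    dmp_grp = fit_dmp_batch(values, dataset.samples, "group")
    log.info("group DMP: %d probes tested, %d FDR<%.2f",
             int(dmp_grp["p_2df"].notna().sum()),
             int((dmp_grp["q_bh"] < config.fdr_alpha).sum()), config.fdr_alpha)

    delta_records, retained_delta = _call_and_classify(dataset, dmp_int, config, "interaction")
    log.info("delta regions: %d candidates, %d retained",
             len(delta_records), len(retained_delta))
    mu_records, retained_mu = _call_and_classify(dataset, dmp_grp, config, "group")
    log.info("mu regions: %d candidates, %d retained", len(mu_records), len(retained_mu))

    eqtm_df = None
    if expression is not None:
        eqtm_df = _run_eqtm(dataset, retained_delta, retained_mu, expression, config)
        log.info("eQTM: %d pairs tested", 0 if eqtm_df is None else len(eqtm_df))
    else:
        log.info("eQTM stage skipped: no expression data")
    metqtm_df = None
    if metabolites is not None:
        metqtm_df = _run_metqtm(dataset, retained_delta, retained_mu, metabolites, config)
        log.info("metQTM: %d pairs tested", 0 if metqtm_df is None else len(metqtm_df))
    else:
        log.info("metQTM stage skipped: no metabolite data")

    counts = {
        "probes_total": int(len(dataset.manifest)),
        "probes_kept": int(len(kept)),
        "dmp_interaction_fdr_hits": int((dmp_int["q_bh"] < config.fdr_alpha).sum()),
        "dmp_group_fdr_hits": int((dmp_grp["q_bh"] < config.fdr_alpha).sum()),
        "delta_candidates": len(delta_records),
        "delta_retained": len(retained_delta),
        "mu_candidates": len(mu_records),
        "mu_retained": len(retained_mu),
        "eqtm_pairs": 0 if eqtm_df is None else int(len(eqtm_df)),
        "metqtm_pairs": 0 if metqtm_df is None else int(len(metqtm_df)),
        "seed": int(config.seed),
    }

    result = PipelineResult(
        config=config, dataset=dataset, kept_probes=kept,
        dmp_interaction=dmp_int, dmp_group=dmp_grp,
        delta_records=delta_records, mu_records=mu_records,
        retained_delta=retained_delta, retained_mu=retained_mu,
        eqtm=eqtm_df, metqtm=metqtm_df, counts=counts,
    )
    if out_dir is not None:
        write_result(result, out_dir)
    return result


def write_result(result: PipelineResult, out_dir):
    """Persist all pipeline tables under ``out_dir`` with traceable headers."""
    out_dir = Path(out_dir)
    meta = {"config": io.config_hash(result.config.to_dict()), "seed": result.config.seed}
    io.write_table(result.dmp_interaction, out_dir / "dmp_interaction.tsv", meta=meta)
    io.write_table(result.dmp_group, out_dir / "dmp_group.tsv", meta=meta)
    io.write_regions(result.delta_records, out_dir, "regions_delta", meta=meta)
    io.write_regions(result.mu_records, out_dir, "regions_mu", meta=meta)
    if result.eqtm is not None:
        io.write_table(result.eqtm, out_dir / "eqtm.tsv", index=False, meta=meta)
    if result.metqtm is not None:
        io.write_table(result.metqtm, out_dir / "metqtm.tsv", index=False, meta=meta)
    io.write_json({"counts": result.counts}, out_dir / "summary.json", meta=meta)
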