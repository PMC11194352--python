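"""Simulation-based validation experiments.

Each function runs a self-contained experiment on synthetic cohorts --
null-calibration of the per-CpG tests, recovery of planted regions, recovery
of planted expression/metabolite links -- and returns plain numbers.  They
back both the statistical test suite and the reproducibility script.

Problem sizes default to the study scale (143 subjects, two visits; ~2,000
probes for calibration; 50 region-recovery replicates; 40 link-recovery
replicates) and keep each experiment within a few minutes on one CPU.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import combp, dmr, qtm
from .ewas import bh_fdr, filter_probes, fit_dmp_batch
from .simulate import (
    CohortDesign,
    GroundTruth,
    generate_linked_omics,
    generate_manifest,
    generate_methylation,
    generate_samples,
    plant_ground_truth,
)

RECOVERY_SLOPES = {"maintainer": -0.08, "progressor": 0.04, "reverter": 0.06}


def _null_pvalues(seed: int, n_chrom: int = 5, clusters_per_chrom: int = 50) -> np.ndarray:
    """Interaction-model p-values for one all-null cohort (~2,000 probes)."""
    design = CohortDesign(seed=seed)
    man = generate_manifest(n_chrom=n_chrom, clusters_per_chrom=clusters_per_chrom,
                            seed=seed)
    samples = generate_samples(design)
    truth = GroundTruth(null_probes=set(man["probe_id"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = generate_methylation(man, samples, truth, design)
        res = fit_dmp_batch(ds.values, samples, "interaction")
    return res["p_2df"].dropna().to_numpy()


def null_calibration(seed: int, alpha: float = 0.05) -> dict:
    """Type-I behaviour of the interaction test on one null cohort."""
    p = _null_pvalues(seed)
    return {
        "n_probes": int(p.size),
        "rejection_rate": float(np.mean(p < alpha)),
        "bh_discoveries": int(np.sum(bh_fdr(p) < 0.10)),
    }


def null_bh_zero_share(seed: int, n_seeds: int = 20) -> dict:
    """Share of null cohorts in which BH at 0.10 yields zero discoveries."""
    zero = 0
    for k in range(n_seeds):
        p = _null_pvalues(seed + 1000 * (k + 1))
        zero += int(np.sum(bh_fdr(p) < 0.10) == 0)
    return {"n_seeds": n_seeds, "zero_discovery_share": zero / n_seeds}


def delta_region_recovery(seed: int, n_reps: int = 50,
                          slopes: dict | None = None) -> dict:
    """Recovery of one planted 8-probe delta region across seeded replicates.

    A replicate succeeds when a retained delta-DMR overlaps the planted
    region.  Also reports the share of (probe, group) slope estimates within
    3 SE of their planted value.
    """
    slopes = slopes or dict(RECOVERY_SLOPES)
    hits = 0
    slope_ok = 0
    slope_total = 0
    for rep in range(n_reps):
        rep_seed = seed + 100 * (rep + 1)
        design = CohortDesign(seed=rep_seed)
        man = generate_manifest(n_chrom=2, clusters_per_chrom=10,
                                probes_per_cluster_range=(4, 10), seed=rep_seed)
        samples = generate_samples(design)
        truth = plant_ground_truth(man, seed=rep_seed, n_delta_regions=1,
                                   n_mu_regions=0, min_region_probes=8,
                                   delta_slopes=slopes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = generate_methylation(man, samples, truth, design)
            kept = set(filter_probes(man))
            vals = ds.values.loc[[p for p in ds.values.index if p in kept]]
            res = fit_dmp_batch(vals, samples, "interaction")
        manl = man.set_index("probe_id").loc[res.index]
        order = np.lexsort((manl["pos"].to_numpy(), manl["chrom"].to_numpy()))
        regions = combp.call_regions(
            res["p_2df"].to_numpy()[order], manl["pos"].to_numpy()[order],
            manl["chrom"].to_numpy()[order], res.index.to_numpy()[order],
        )
        records = [dmr.summarize_delta_region(r, res, region_id=str(i))
                   for i, r in enumerate(regions)]
        retained = dmr.filter_delta_dmrs(records)
        planted = truth.delta_regions[0]
        hits += any(
            r.chrom == planted.chrom and r.start < planted.end_pos
            and r.stop > planted.start_pos - 1 for r in retained
        )
        present = [p for p in planted.probe_ids if p in res.index]
        for pid in present:
            for g, true_slope in slopes.items():
                est = res.loc[pid, f"slope_{g}"]
                se = res.loc[pid, f"se_{g}"]
                slope_total += 1
                slope_ok += int(abs(est - true_slope) < 3 * se)
    return {
        "n_reps": n_reps,
        "recovery_rate": hits / n_reps,
        "slope_within_3se_share": slope_ok / slope_total,
    }


def qtm_link_recovery(seed: int, n_reps: int = 40, target_rho: float = 0.55,
                      target_beta: float = 0.4, n_expression: int = 36,
                      n_metabolite: int = 110) -> dict:
    """Recovery of planted expression (Spearman) and metabolite (standardised
    beta) links at the overlap sample sizes of the study design.

    Regions are scored by their mean CpG delta passed through the PCA scorer,
    so the estimates carry only the sampling noise of the correlation itself.
    """
    rhos, betas = [], []
    for rep in range(n_reps):
        rep_seed = seed + 100 * (rep + 1)
        design = CohortDesign(seed=rep_seed)
        man = generate_manifest(n_chrom=1, clusters_per_chrom=4,
                                probes_per_cluster_range=(6, 8), seed=rep_seed)
        samples = generate_samples(design)
        truth = plant_ground_truth(man, seed=rep_seed, n_delta_regions=1,
                                   n_mu_regions=0, min_region_probes=6,
                                   gene_targets=(target_rho,),
                                   metabolite_targets=(target_beta,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = generate_methylation(man, samples, truth, design)
            subjects = samples["subject_id"].unique()
            rng = np.random.default_rng(rep_seed)
            expr_sub = list(rng.choice(subjects, n_expression, replace=False))
            met_sub = list(rng.choice(subjects, n_metabolite, replace=False))
            expr, mets = generate_linked_omics(
                truth, samples, ds, seed=rep_seed,
                expression_subjects=expr_sub, metabolite_subjects=met_sub,
            )
            region = truth.delta_regions[0]

            def regional_score(subject_list):
                sub = samples[samples["subject_id"].isin(subject_list)]
                deltas = pd.DataFrame({
                    pid: qtm.paired_contrast(ds.values.loc[pid, sub.index], sub, "delta")
                    for pid in region.probe_ids
                })
                return qtm.region_pc1(deltas.mean(axis=1).to_frame("regional_mean"),
                                      region_id=region.region_id, mode="delta")

            gene = truth.linked_genes[0]
            rhos.append(qtm.eqtm_test(regional_score(expr_sub),
                                      expr.values.loc[gene.gene_id]).statistic)

            met = truth.linked_metabolites[0]
            subm = samples[samples["subject_id"].isin(met_sub)]
            transformed, _ = qtm.boxcox(mets.values.loc[met.met_id].to_numpy())
            series = pd.Series(transformed, index=mets.values.columns)
            contrast = qtm.paired_contrast(series, subm, "delta")
            betas.append(qtm.metqtm_test(regional_score(met_sub), contrast,
                                         met.panel).statistic)
    rhos = np.asarray(rhos)
    betas = np.asarray(betas)
    return {
        "n_reps": n_reps,
        "rho_estimates": rhos,
        "beta_estimates": betas,
        "rho_median": float(np.median(rhos)),
        "beta_median": float(np.median(betas)),
        "rho_in_band_share": float(np.mean((rhos > 0.25) & (rhos < 0.80))),
        "beta_within_02_share": float(np.mean(np.abs(betas - target_beta) <= 0.2)),
    }
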