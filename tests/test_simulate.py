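"""Synthetic cohort generator: determinism, geometry, planted-effect fidelity."""
import numpy as np
import pandas as pd
import pytest

from longmeth.errors import ValidationError
from longmeth.simulate import (
    CohortDesign,
    GroundTruth,
    generate_linked_omics,
    generate_manifest,
    generate_methylation,
    generate_samples,
    plant_ground_truth,
    _regional_signal,
)


def test_manifest_forced_geometry_and_determinism():
    kw = dict(n_chrom=1, clusters_per_chrom=1, probes_per_cluster_range=(4, 4),
              intra_cluster_spacing_range=(50, 50), seed=7)
    man = generate_manifest(**kw)
    clusters = man[man["cluster"].str.contains("_c")]
    assert len(clusters) == 4
    assert clusters["pos"].max() - clusters["pos"].min() == 150
    # singletons also emitted between clusters
    assert (man["cluster"].str.contains("_s")).any()
    pd.testing.assert_frame_equal(man, generate_manifest(**kw))


def test_manifest_cluster_span_bound_and_gaps():
    man = generate_manifest(n_chrom=2, clusters_per_chrom=6,
                            probes_per_cluster_range=(4, 9),
                            intra_cluster_spacing_range=(20, 120), seed=3)
    for _, grp in man[man["cluster"].str.contains("_c")].groupby("cluster"):
        assert grp["pos"].max() - grp["pos"].min() < 9 * 120
    # consecutive probes from different clusters are > 500 bp apart
    for _, chrom_grp in man.groupby("chrom"):
        ordered = chrom_grp.sort_values("pos")
        gaps = ordered["pos"].diff().iloc[1:]
        cross = ordered["cluster"].ne(ordered["cluster"].shift()).iloc[1:]
        assert (gaps[cross] > 500).all()
    assert man["probe_id"].is_unique


def test_manifest_seed_changes_positions():
    a = generate_manifest(seed=7)
    b = generate_manifest(seed=8)
    assert set(zip(a["chrom"], a["pos"])) != set(zip(b["chrom"], b["pos"]))


def test_manifest_rejects_bad_arguments():
    with pytest.raises(ValidationError):
        generate_manifest(n_chrom=0)
    with pytest.raises(ValidationError):
        generate_manifest(intra_cluster_spacing_range=(100, 600))


def test_samples_design_structure(samples):
    assert samples["subject_id"].nunique() == 143
    assert len(samples) == 286
    cell_sum = samples[["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]].sum(axis=1)
    assert cell_sum.to_numpy() == pytest.approx(1.0, abs=1e-12)
    sizes = samples.groupby("group")["subject_id"].nunique()
    assert sizes.to_dict() == {"maintainer": 60, "progressor": 42, "reverter": 41}


def test_samples_age_ordering_large_n():
    """Progressors seroconvert younger; reverters and maintainers are similar."""
    design = CohortDesign(seed=99, n_per_group={g: 1000 for g in
                                                ("maintainer", "progressor", "reverter")},
                          n_missing_ancestry=0)
    s = generate_samples(design)
    med = s[s["visit"] == "pre"].groupby("group")["age"].median()
    assert med["progressor"] < med["reverter"]
    assert med["progressor"] < med["maintainer"]
    assert abs(med["reverter"] - med["maintainer"]) < 1.5


def test_samples_determinism_and_bad_dirichlet():
    d = CohortDesign(seed=21)
    pd.testing.assert_frame_equal(generate_samples(d), generate_samples(d))
    bad = CohortDesign(seed=21)
    bad.cellprop_alpha[("maintainer", "pre")] = np.zeros(6)
    with pytest.raises(ValidationError):
        generate_samples(bad)


def test_methylation_deterministic_and_planted_delta(small_manifest, samples,
                                                     default_design):
    truth = plant_ground_truth(small_manifest, seed=5, n_delta_regions=1,
                               n_mu_regions=0, min_region_probes=6,
                               delta_slopes={"maintainer": -0.05,
                                             "progressor": 0.0, "reverter": 0.0})
    ds1 = generate_methylation(small_manifest, samples, truth, default_design)
    ds2 = generate_methylation(small_manifest, samples, truth, default_design)
    pd.testing.assert_frame_equal(ds1.values, ds2.values)

    # raw maintainer post-pre mean within 3 SE of the planted -0.05
    region = truth.delta_regions[0]
    maint = samples[samples["group"] == "maintainer"]
    pre = ds1.values.loc[region.probe_ids,
                         maint.index[maint["visit"] == "pre"]].mean(axis=0)
    post = ds1.values.loc[region.probe_ids,
                          maint.index[maint["visit"] == "post"]].mean(axis=0)
    deltas = post.to_numpy() - pre.to_numpy()
    se = deltas.std(ddof=1) / np.sqrt(len(deltas))
    assert abs(deltas.mean() - (-0.05)) < 3 * se


def test_methylation_infinite_decay_kills_spatial_correlation(small_manifest, samples):
    design = CohortDesign(seed=9, spatial_decay=np.inf)
    truth = GroundTruth(null_probes=set(small_manifest["probe_id"]))
    ds = generate_methylation(small_manifest, samples, truth, design)
    # within-cluster cross-probe correlation of per-subject deltas ~ 0
    corrs = []
    pre = samples.index[samples["visit"] == "pre"]
    post = samples.index[samples["visit"] == "post"]
    for _, grp in small_manifest.groupby("cluster"):
        if len(grp) < 2:
            continue
        d = (ds.values.loc[grp["probe_id"], post].to_numpy()
             - ds.values.loc[grp["probe_id"], pre].to_numpy())
        c = np.corrcoef(d)
        corrs.extend(c[np.triu_indices(len(grp), k=1)])
    assert abs(np.mean(corrs)) < 0.05


def test_planted_regions_do_not_overlap_and_truth_validates(small_manifest):
    truth = plant_ground_truth(small_manifest, seed=5, n_delta_regions=2,
                               n_mu_regions=1, min_region_probes=6)
    truth.validate()
    with pytest.raises(ValidationError):
        plant_ground_truth(small_manifest, seed=5, gene_targets=(1.5,))


def test_linked_expression_hits_target_correlation(small_manifest, samples,
                                                   default_design):
    """Target Spearman 0.9 at n = 200 subjects lands in the Fisher-z band."""
    from scipy import stats
    design = CohortDesign(seed=31, n_per_group={"maintainer": 70, "progressor": 65,
                                                "reverter": 65})
    s = generate_samples(design)
    truth = plant_ground_truth(small_manifest, seed=31, n_delta_regions=1,
                               n_mu_regions=0, min_region_probes=6,
                               gene_targets=(0.9,))
    ds = generate_methylation(small_manifest, s, truth, design)
    expr, _ = generate_linked_omics(truth, s, ds, seed=31)
    g = truth.linked_genes[0]
    sig = _regional_signal(ds, truth.region(g.region_id), "delta")
    rho = stats.spearmanr(expr.values.loc[g.gene_id], sig).statistic
    assert 0.8 < rho < 0.96


def test_zero_target_link_indistinguishable_from_noise(small_manifest, samples,
                                                       default_design):
    from scipy import stats
    truth = plant_ground_truth(small_manifest, seed=13, n_delta_regions=1,
                               n_mu_regions=0, min_region_probes=6,
                               gene_targets=(0.0,))
    ds = generate_methylation(small_manifest, samples, truth, default_design)
    expr, _ = generate_linked_omics(truth, samples, ds, seed=13)
    g = truth.linked_genes[0]
    sig = _regional_signal(ds, truth.region(g.region_id), "delta")
    linked = stats.spearmanr(expr.values.loc[g.gene_id], sig).statistic
    null_rhos = [stats.spearmanr(expr.values.loc[gid], sig).statistic
                 for gid in expr.values.index if gid != g.gene_id]
    lo, hi = np.quantile(null_rhos, [0.01, 0.99])
    assert lo <= linked <= hi


def test_linked_metabolite_beta_recovery(small_manifest, samples, default_design):
    truth = plant_ground_truth(small_manifest, seed=23, n_delta_regions=1,
                               n_mu_regions=0, min_region_probes=6,
                               metabolite_targets=(0.4,))
    ds = generate_methylation(small_manifest, samples, truth, default_design)
    rng = np.random.default_rng(23)
    met_sub = list(rng.choice(samples["subject_id"].unique(), 110, replace=False))
    _, mets = generate_linked_omics(truth, samples, ds, seed=23,
                                    metabolite_subjects=met_sub)
    m = truth.linked_metabolites[0]
    sig = _regional_signal(ds, truth.region(m.region_id), "delta")
    pre = mets.values.columns[mets.values.columns.str.endswith("_pre")]
    post = mets.values.columns[mets.values.columns.str.endswith("_post")]
    delta = (mets.values.loc[m.met_id, post].to_numpy()
             - mets.values.loc[m.met_id, pre].to_numpy())
    subj = [c.rsplit("_", 1)[0] for c in post]
    z = (delta - delta.mean()) / delta.std(ddof=1)
    sigz = sig.reindex(subj).to_numpy()
    beta = float(np.mean(z * (sigz - sigz.mean()) / sigz.std(ddof=1)))
    assert abs(beta - 0.4) <= 0.2
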