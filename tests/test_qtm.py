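"""Region-level QTM operations: residualisation, contrasts, PCA, tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longmeth.errors import ValidationError
from longmeth.qtm import (
    RegionScore,
    boxcox,
    cis_features,
    eqtm_test,
    fdr_by_stratum,
    metqtm_test,
    paired_contrast,
    region_pc1,
    residualize_repeated,
    tss_from_gene_table,
)


def test_residualize_no_covariates_centres_values(samples):
    y = pd.Series(np.arange(len(samples), dtype=float), index=samples.index)
    resid = residualize_repeated(y, samples, (), random_intercept=False)
    assert resid.to_numpy() == pytest.approx((y - y.mean()).to_numpy())


def test_residualize_invariant_to_covariate_shift(samples):
    rng = np.random.default_rng(0)
    y = pd.Series(rng.normal(size=len(samples)), index=samples.index)
    r1 = residualize_repeated(y, samples, ("age",), random_intercept=True)
    shifted = samples.copy()
    shifted["age"] = shifted["age"] + 100.0
    r2 = residualize_repeated(y, shifted, ("age",), random_intercept=True)
    assert r1.to_numpy() == pytest.approx(r2.to_numpy(), abs=1e-8)


def test_residualize_removes_known_age_effect(samples):
    rng = np.random.default_rng(1)
    y = pd.Series(0.1 * samples["age"] + rng.normal(0, 0.2, len(samples)),
                  index=samples.index)
    resid = residualize_repeated(y, samples, ("age", "sex"), random_intercept=True)
    r = np.corrcoef(resid, samples["age"])[0, 1]
    assert abs(r) < 0.05
    assert abs(resid.mean()) < 0.05


def test_paired_contrast_delta_mean_and_symmetry(samples):
    y = pd.Series(np.where(samples["visit"] == "post", 3.0, 1.0), index=samples.index)
    delta = paired_contrast(y, samples, "delta")
    mean = paired_contrast(y, samples, "mean")
    assert (delta == 2.0).all() and (mean == 2.0).all()
    # swapping visit labels negates delta, fixes mean
    swapped = samples.copy()
    swapped["visit"] = swapped["visit"].map({"pre": "post", "post": "pre"})
    assert paired_contrast(y, swapped, "delta").to_numpy() == pytest.approx(-delta.to_numpy())
    assert paired_contrast(y, swapped, "mean").to_numpy() == pytest.approx(mean.to_numpy())


def test_paired_contrast_drops_incomplete_subject(samples):
    y = pd.Series(1.0, index=samples.index[:-1])  # one post row missing
    with pytest.warns(UserWarning):
        out = paired_contrast(y, samples.iloc[:-1], "delta")
    assert len(out) == samples["subject_id"].nunique() - 1


def test_region_pc1_single_and_duplicated_cpg():
    rng = np.random.default_rng(2)
    x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    score = region_pc1(x.to_frame("cpg1"))
    z = (x - x.mean()) / x.std(ddof=1)
    assert score.variance_explained == pytest.approx(1.0)
    assert np.abs(score.scores.to_numpy()) == pytest.approx(np.abs(z.to_numpy()))
    two = pd.DataFrame({"a": x, "b": 2 * x + 1})  # perfectly correlated
    assert region_pc1(two).variance_explained == pytest.approx(1.0)


def test_region_pc1_equicorrelated_variance_explained():
    """For 4 CpGs with pairwise correlation 0.6 the top eigenvalue share is
    (1 + 3 * 0.6) / 4 = 0.7."""
    rng = np.random.default_rng(3)
    n, k, rho = 110, 4, 0.6
    common = rng.normal(size=n)
    mat = pd.DataFrame(
        {f"c{j}": np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=n)
         for j in range(k)},
        index=[f"s{i}" for i in range(n)],
    )
    score = region_pc1(mat)
    assert score.variance_explained == pytest.approx(0.7, abs=0.08)
    assert abs(score.scores.mean()) < 1e-10
    # orientation: score tracks the row mean positively
    assert np.corrcoef(score.scores, mat.mean(axis=1))[0, 1] > 0


def test_region_pc1_orientation_flip_preserves_pvalue():
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.normal(size=(40, 3)), index=[f"s{i}" for i in range(40)])
    score = region_pc1(mat)
    expr = pd.Series(rng.normal(size=40), index=mat.index)
    res = eqtm_test(score, expr)
    flipped = RegionScore(score.region_id, -score.scores, score.mode,
                          score.variance_explained, -score.orientation)
    res_f = eqtm_test(flipped, expr)
    assert res_f.statistic == pytest.approx(-res.statistic)
    assert res_f.p == pytest.approx(res.p)


def test_region_pc1_drops_zero_variance_cpgs():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
    with pytest.warns(UserWarning):
        score = region_pc1(mat)
    assert score.variance_explained == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        region_pc1(pd.DataFrame({"b": np.ones(20)}))


def test_cis_features_window_rule():
    region = {"chrom": "chr20", "start": 57426537, "stop": 57427974}
    tss = pd.DataFrame({
        "gene_id": ["near", "far", "other_chrom"],
        "chrom": ["chr20", "chr20", "chr1"],
        "tss": [57427974 + 400_000, 57427974 + 900_000, 57427000],
    })
    assert cis_features(region, tss) == ["near"]
    assert cis_features(region, tss.iloc[0:0]) == []


def test_tss_strand_rule():
    genes = pd.DataFrame({
        "gene_id": ["plus", "minus"], "chrom": ["chr1", "chr1"],
        "start": [100, 100], "end": [900, 900], "strand": [1, -1],
    })
    tss = tss_from_gene_table(genes).set_index("gene_id")["tss"]
    assert tss["plus"] == 100 and tss["minus"] == 900


def test_eqtm_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    idx = [f"s{i}" for i in range(36)]
    score = RegionScore("r", pd.Series(rng.normal(size=36), index=idx), "delta", 1.0, 1)
    expr = pd.Series(score.scores**3 + 5, index=idx)  # strictly monotone
    res = eqtm_test(score, expr)
    assert res.statistic == pytest.approx(1.0)
    res2 = eqtm_test(score, np.exp(expr / 10.0))
    assert res2.statistic == pytest.approx(res.statistic)
    assert res2.p == pytest.approx(res.p)


def test_eqtm_constant_expression_flagged():
    idx = [f"s{i}" for i in range(10)]
    score = RegionScore("r", pd.Series(np.arange(10.0), index=idx), "delta", 1.0, 1)
    res = eqtm_test(score, pd.Series(1.0, index=idx))
    assert res.status == "constant_input" and np.isnan(res.p)


def test_boxcox_lambda_selection_and_identity():
    rng = np.random.default_rng(7)
    _, lam = boxcox(rng.lognormal(0.0, 1.0, size=500))
    assert -0.2 <= lam <= 0.2
    _, lam = boxcox(rng.normal(50.0, 2.0, size=500))
    assert 0.6 <= lam <= 1.4  # near-identity for already-normal data
    x = np.array([1.0, 2.0, 5.0])
    y, _ = boxcox(x, lambdas=np.array([1.0]))
    assert y == pytest.approx(x - 1.0)
    with pytest.warns(UserWarning):
        boxcox(np.array([-1.0, 2.0, 3.0]))


def test_metqtm_standardised_beta_equals_pearson_r():
    rng = np.random.default_rng(8)
    idx = [f"s{i}" for i in range(110)]
    score = RegionScore("r", pd.Series(rng.normal(size=110), index=idx), "delta", 1.0, 1)
    met = pd.Series(0.4 * score.scores + rng.normal(size=110), index=idx)
    res = metqtm_test(score, met, "Lipid")
    r = stats.pearsonr(score.scores, met).statistic
    assert res.statistic == pytest.approx(r, abs=1e-12)
    # metabolite equal to the score itself -> beta exactly 1
    res1 = metqtm_test(score, score.scores.copy(), "Lipid")
    assert res1.statistic == pytest.approx(1.0)


def test_stratified_fdr_is_per_panel():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "region_id": "r", "feature_id": [f"f{i}" for i in range(30)],
        "panel": ["HILIC"] * 10 + ["Lipid"] * 20,
        "p": rng.uniform(size=30), "q_bh": np.nan, "n": 10, "statistic": 0.1,
        "status": "ok",
    })
    out = fdr_by_stratum(df)
    # permuting features within one panel leaves its q set unchanged and the
    # other panel untouched
    perm = df.copy()
    perm.iloc[0:10] = perm.iloc[0:10].sample(frac=1, random_state=0).to_numpy()
    out_perm = fdr_by_stratum(perm)
    assert sorted(out.loc[out.panel == "HILIC", "q_bh"]) == pytest.approx(
        sorted(out_perm.loc[out_perm.panel == "HILIC", "q_bh"]))
    assert out.loc[out.panel == "Lipid", "q_bh"].to_numpy() == pytest.approx(
        out_perm.loc[out_perm.panel == "Lipid", "q_bh"].to_numpy())
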