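"""Per-CpG model tests: value transforms, probe filter, FDR, mixed-model fits."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from longmeth.errors import ConfigurationError
from longmeth.ewas import (
    _encode_design,
    _fit_cs_ml,
    beta_to_m,
    bh_fdr,
    filter_probes,
    fit_dmp_batch,
    fit_group_dmp,
    fit_interaction_dmp,
    m_to_beta,
)


@pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_beta_to_m_known_values(beta, m):
    assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)


def test_beta_to_m_clamps_out_of_range_with_warning():
    with pytest.warns(UserWarning):
        out = beta_to_m(np.array([0.0, 1.0, 0.5]))
    assert np.isfinite(out).all()
    assert out[0] == pytest.approx(beta_to_m(1e-6))


@given(st.floats(min_value=0.01, max_value=0.99))
@settings(max_examples=50, derandomize=True)
def test_m_beta_round_trip(beta):
    assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, rel=1e-10)


def test_filter_probes_rules(toy_manifest):
    kept = set(filter_probes(toy_manifest))
    # a: low range on 450k only -> kept (removal needs < 3% on BOTH platforms)
    # b: low on both -> removed; c: near SNP -> removed; d: non-autosomal -> removed
    assert kept == {"a"}


def test_filter_probes_missing_column_errors(toy_manifest):
    bad = toy_manifest.drop(columns="beta_range_epic")
    with pytest.raises(ConfigurationError):
        filter_probes(bad)


def test_bh_fdr_step_up_and_edge_cases():
    # brute-force step-up: q_i = min_{j>=i} p_(j) * m / j
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    assert bh_fdr([]).size == 0
    q = bh_fdr([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and q[0] == pytest.approx(0.02)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
       st.randoms(use_true_random=False))
@settings(max_examples=40, derandomize=True)
def test_bh_fdr_properties(pvals, rnd):
    p = np.asarray(pvals)
    q = bh_fdr(p)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
    # monotone over the ranked list
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    # output order tracks input order under shuffling
    idx = list(range(len(p)))
    rnd.shuffle(idx)
    assert bh_fdr(p[idx]) == pytest.approx(q[idx])


def test_interaction_recovers_planted_slopes(planted_cohort):
    """A probe carrying slopes (R +0.06, P 0, M -0.08) at design n is detected
    and its per-group slopes land within 3 SE of truth."""
    dataset, truth = planted_cohort
    region = truth.delta_regions[0]
    res = fit_interaction_dmp(dataset.values.loc[region.probe_ids[0]], dataset.samples)
    assert res.p_2df < 1e-3
    for g, true_slope in region.effects.items():
        err = abs(res.group_visit_slopes[g] - true_slope)
        assert err < 3 * res.slope_se[g]


def test_interaction_slope_equals_visit_mean_difference(samples):
    """The reported slope is exactly the model-implied post-pre mean change."""
    rng = np.random.default_rng(0)
    s, X, _ = _encode_design(samples, "interaction")
    y = rng.normal(size=(len(s), 1))
    fit = _fit_cs_ml(X.to_numpy(), y, columns=X.columns)
    cols = list(X.columns)
    beta = fit.beta[:, 0]
    # profile for a reverter subject: post row minus pre row differs only in
    # visit-dependent columns
    for g, extra in (("maintainer", 0.0),
                     ("reverter", beta[cols.index("reverter_x_visit")]),
                     ("progressor", beta[cols.index("progressor_x_visit")])):
        slope = beta[cols.index("visit_post")] + extra
        row = pd.Series(0.0, index=cols)
        row["intercept"] = 1.0
        pre = row.copy()
        post = row.copy()
        post["visit_post"] = 1.0
        if g != "maintainer":
            pre[f"group_{g}"] = post[f"group_{g}"] = 1.0
            post[f"{g}_x_visit"] = 1.0
        implied = float((post - pre) @ beta)
        assert implied == pytest.approx(slope, abs=1e-8)


def test_zero_variance_probe_flagged_not_raised(samples):
    flat = pd.Series(1.0, index=samples.index)
    res = fit_interaction_dmp(flat, samples)
    assert res.status == "zero_variance"
    assert np.isnan(res.p_2df)


def test_group_model_recovers_planted_offsets(planted_cohort):
    """Planted offsets giving P-R = 0.09, R-M = 0.37 are recovered within 3 SE."""
    dataset, truth = planted_cohort
    region = truth.mu_regions[0]
    res = fit_group_dmp(dataset.values.loc[region.probe_ids[0]], dataset.samples)
    eff = region.effects
    expected = {
        "PvR": eff["progressor"] - eff["reverter"],
        "RvM": eff["reverter"] - eff["maintainer"],
        "PvM": eff["progressor"] - eff["maintainer"],
    }
    assert res.p_2df < 1e-3
    for k, truth_val in expected.items():
        assert abs(res.pairwise_group_diffs[k] - truth_val) < 3 * res.diff_se[k]


def test_group_model_drops_missing_ancestry_subjects(planted_cohort):
    dataset, truth = planted_cohort
    n_missing = dataset.samples["pc1"].isna().sum() // 2
    assert n_missing == 2  # design default: two subjects lack ancestry PCs
    res = fit_group_dmp(dataset.values.iloc[0], dataset.samples)
    assert res.n_used == len(dataset.samples) - 2 * n_missing


def test_group_model_all_ancestry_missing_errors(planted_cohort):
    dataset, _ = planted_cohort
    s = dataset.samples.copy()
    s[["pc1", "pc2"]] = np.nan
    with pytest.raises(ConfigurationError):
        fit_group_dmp(dataset.values.iloc[0], s)


def test_group_permutation_null_is_uniform(planted_cohort):
    """Permuting group labels across subjects destroys a planted group effect:
    the permutation distribution of p-values is uniform."""
    dataset, truth = planted_cohort
    region = truth.mu_regions[0]
    y = dataset.values.loc[region.probe_ids[0]]
    samples = dataset.samples
    subjects = samples["subject_id"].unique()
    groups = samples.groupby("subject_id")["group"].first().loc[subjects].to_numpy()
    rng = np.random.default_rng(123)
    pvals = []
    for _ in range(200):
        perm = dict(zip(subjects, rng.permutation(groups)))
        s = samples.copy()
        s["group"] = s["subject_id"].map(perm)
        pvals.append(fit_group_dmp(y, s).p_2df)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_matches_mixedlm_oracle(planted_cohort):
    """The profiled compound-symmetry ML equals the random-intercept ML fit by
    statsmodels MixedLM (independent implementation) on the same probe."""
    MixedLM = pytest.importorskip("statsmodels.regression.mixed_linear_model").MixedLM
    dataset, truth = planted_cohort
    pid = truth.delta_regions[0].probe_ids[0]
    s, X, _ = _encode_design(dataset.samples, "interaction")
    y = dataset.values.loc[pid, s.index].to_numpy()
    sm_fit = MixedLM(y, X.to_numpy(), groups=s["subject_id"].to_numpy()).fit(
        reml=False, method="lbfgs"
    )
    ours = _fit_cs_ml(X.to_numpy(), y[:, None], columns=X.columns)
    const = len(y) * (np.log(2 * np.pi) + 1)
    # the rho grid (step 0.005) bounds how closely nuisance betas can agree
    assert np.abs(sm_fit.fe_params - ours.beta[:, 0]).max() < 5e-3
    cols = list(X.columns)
    for name in ("visit_post", "progressor_x_visit", "reverter_x_visit"):
        i = cols.index(name)
        assert ours.beta[i, 0] == pytest.approx(sm_fit.fe_params[i], abs=1e-3)
    assert -0.5 * (ours.neg2ll[0] + const) == pytest.approx(sm_fit.llf, abs=5e-3)


def test_batch_and_single_probe_agree(planted_cohort):
    dataset, _ = planted_cohort
    batch = fit_dmp_batch(dataset.values.iloc[:3], dataset.samples, "interaction")
    single = fit_interaction_dmp(dataset.values.iloc[1], dataset.samples)
    assert batch["p_2df"].iloc[1] == pytest.approx(single.p_2df, rel=1e-12)
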