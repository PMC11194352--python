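"""Per-CpG mixed-model tests for a two-visit longitudinal EWAS.

Each CpG's M-values are modelled with a subject-level random intercept and
fixed effects for phenotype group, visit, and technical/biological
covariates (age, sex, array platform, six blood-cell proportions, and for
the group-effect model two genetic-ancestry principal components).

Two models are fit per probe:

* ``interaction`` -- tests whether the pre- to post-seroconversion change in
  methylation differs across the three islet-autoimmunity phenotypes
  (group x visit interaction, 2-df Wald F-test with containment denominator
  df).  The model-implied per-group visit slopes (post minus pre, M-units)
  are reported.
* ``group`` -- tests whether average methylation differs across phenotypes
  (group main effect, 2-df F-test), additionally adjusted for ancestry PCs and
  restricted to subjects with ancestry data (complete case).  The pairwise
  group contrasts P-R, R-M, P-M are reported.

With exactly two observations per subject, maximum likelihood for the
random-intercept model is equivalent to compound-symmetry GLS profiled over
the within-pair correlation rho; the profile likelihood is one-dimensional
and is minimised on a fixed grid, vectorised across probes that share a
design matrix.  rho is allowed to go mildly negative, which is the
compound-symmetry fallback for probes whose random-intercept variance
estimate would otherwise pin at zero; such probes are flagged ``cs_gls``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError

GROUPS = ("maintainer", "progressor", "reverter")  # maintainer = reference level
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
VISITS = ("pre", "post")

_BETA_EPS = 1e-6
# rho < 0 region is coarser: it is a rarely visited fallback.
_RHO_GRID = np.concatenate([np.arange(-0.5, 0.0, 0.01), np.arange(0.0, 0.9951, 0.005)])


# ---------------------------------------------------------------------------
# value-scale helpers and probe filtering


def beta_to_m(beta):
    """logit2 transform of a methylation fraction: M = log2(beta / (1 - beta)).

    Values outside (0, 1) are clamped to [1e-6, 1 - 1e-6] with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    out_of_range = (beta <= 0.0) | (beta >= 1.0)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} beta value(s) outside (0, 1) clamped",
            stacklevel=2,
        )
        beta = np.clip(beta, _BETA_EPS, 1.0 - _BETA_EPS)
    m = np.log2(beta / (1.0 - beta))
    return float(m) if m.ndim == 0 else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + 2.0 ** (-m))
    return float(beta) if beta.ndim == 0 else beta


def filter_probes(manifest: pd.DataFrame, beta_range_min: float = 0.03) -> pd.Index:
    """Apply the probe-level inclusion rules and return kept probe ids.

    A probe is kept iff it is autosomal, not within 2 bp of a known SNP, and
    its beta range is >= ``beta_range_min`` on at least one platform (probes
    nearly invariant on *both* platforms are removed).
    """
    required = ("autosomal", "near_snp", "beta_range_450k", "beta_range_epic")
    for col in required:
        if col not in manifest.columns:
            raise ConfigurationError(f"manifest is missing required column {col!r}")
        if manifest[col].isna().any():
            raise ConfigurationError(f"manifest column {col!r} contains missing values")
    low_both = (manifest["beta_range_450k"] < beta_range_min) & (
        manifest["beta_range_epic"] < beta_range_min
    )
    keep = manifest["autosomal"].astype(bool) & ~manifest["near_snp"].astype(bool) & ~low_both
    return pd.Index(manifest.loc[keep, "probe_id"])


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up q-values; NaNs pass through as NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if p[mask].size:
        if np.any((p[mask] < 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# design construction


def _check_paired(samples: pd.DataFrame) -> pd.DataFrame:
    """Sort samples as (subject, pre, post) and verify the pairing invariant."""
    s = samples.copy()
    order = s["visit"].map({"pre": 0, "post": 1})
    if order.isna().any():
        bad = sorted(s.loc[order.isna(), "visit"].unique())
        raise ValidationError(f"unknown visit labels: {bad}")
    s = s.assign(_visit_order=order).sort_values(
        ["subject_id", "_visit_order"], kind="mergesort"
    )
    per_subj = s.groupby("subject_id")["_visit_order"].agg(["size", "sum"])
    bad = per_subj[(per_subj["size"] != 2) | (per_subj["sum"] != 1)]
    if len(bad):
        raise ValidationError(
            f"subjects without exactly one pre and one post visit: {list(bad.index)[:5]}"
        )
    return s.drop(columns="_visit_order")


def _encode_design(samples: pd.DataFrame, model: str):
    """Build the fixed-effect design matrix for one of the two DMP models.

    Returns ``(sorted_samples, X, test_cols)`` where ``test_cols`` are the two
    columns whose joint nullity defines the 2-df test.
    """
    if model not in ("interaction", "group"):
        raise ValueError(f"unknown model {model!r}")
    s = _check_paired(samples)

    if model == "group":
        if "pc1" not in s.columns or "pc2" not in s.columns:
            raise ConfigurationError("group model requires ancestry columns pc1/pc2")
        missing = s["pc1"].isna() | s["pc2"].isna()
        drop_subjects = s.loc[missing, "subject_id"].unique()
        if len(drop_subjects):
            s = s[~s["subject_id"].isin(drop_subjects)]
        if not len(s):
            raise ConfigurationError("ancestry PCs missing for every subject")

    grp_p = (s["group"] == "progressor").astype(float)
    grp_r = (s["group"] == "reverter").astype(float)
    visit = (s["visit"] == "post").astype(float)
    cols = {
        "intercept": np.ones(len(s)),
        "group_progressor": grp_p,
        "group_reverter": grp_r,
        "visit_post": visit,
    }
    if model == "interaction":
        cols["progressor_x_visit"] = grp_p * visit
        cols["reverter_x_visit"] = grp_r * visit
        test_cols = ["progressor_x_visit", "reverter_x_visit"]
    else:
        test_cols = ["group_progressor", "group_reverter"]
    cols["age"] = s["age"].astype(float)
    cols["sex_female"] = (s["sex"] == "F").astype(float)
    cols["platform_epic"] = (s["platform"] == "EPIC").astype(float)
    for ct in CELL_TYPES:
        cols[ct] = s[ct].astype(float)
    if model == "group":
        cols["pc1"] = s["pc1"].astype(float)
        cols["pc2"] = s["pc2"].astype(float)

    X = pd.DataFrame(cols, index=s.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValidationError(f"missing values in covariates: {bad}")

    # Cell proportions sum to 1, so the full set is collinear with the
    # intercept; drop trailing cell types until the design has full rank.
    droppable = list(CELL_TYPES[::-1])
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        if not droppable:
            raise ConfigurationError("design matrix is rank deficient")
        victim = droppable.pop(0)
        if victim in X.columns:
            X = X.drop(columns=victim)
    return s, X, test_cols


# ---------------------------------------------------------------------------
# profiled compound-symmetry maximum likelihood


@dataclass
class _CsFit:
    """Vectorised ML fit of ``m`` probes sharing one design matrix."""

    columns: list
    neg2ll: np.ndarray  # (m,) up to an additive constant shared by nested models
    rho: np.ndarray  # (m,)
    beta: np.ndarray  # (p, m)
    sigma2: np.ndarray  # (m,) residual-scale estimate, RSS / (N - p)
    xtx_inv: dict  # rho grid index -> (p, p)
    rho_idx: np.ndarray  # (m,)
    n_obs: int

    def contrast(self, c: np.ndarray):
        """Estimate and SE of ``c @ beta`` for every probe."""
        est = c @ self.beta
        se = np.empty_like(est)
        for idx, xtxi in self.xtx_inv.items():
            mask = self.rho_idx == idx
            se[mask] = np.sqrt(self.sigma2[mask] * float(c @ xtxi @ c))
        return est, se


def _pair_halves(A: np.ndarray):
    """Split consecutive (pre, post) rows into scaled sum and difference parts."""
    pre, post = A[0::2], A[1::2]
    rt2 = np.sqrt(2.0)
    return (pre + post) / rt2, (post - pre) / rt2


def _fit_cs_ml(X: np.ndarray, Y: np.ndarray, rho_grid: np.ndarray = _RHO_GRID,
               columns=None) -> _CsFit:
    """Profile-ML fit of y_ij = x_ij'b + u_i + e_ij over the CS correlation rho.

    ``X`` is (N, p) with rows ordered subject-major, (pre, post) within
    subject; ``Y`` is (N, m) for m probes.  The profiled -2 log-likelihood
    (dropping the N(log 2pi + 1) constant, identical across nested models) is
    ``N log(RSS(rho)/N) + n log(1 - rho^2)``.
    """
    N, p = X.shape
    n = N // 2
    if 2 * n != N:
        raise ValidationError("observations must come in subject pairs")
    m = Y.shape[1]
    Xs, Xd = _pair_halves(X)
    S, D = _pair_halves(Y)
    s_norm2 = np.sum(S * S, axis=0)
    d_norm2 = np.sum(D * D, axis=0)

    best = np.full(m, np.inf)
    best_idx = np.zeros(m, dtype=int)
    qr_cache = {}
    for i, rho in enumerate(rho_grid):
        a = 1.0 / np.sqrt(1.0 + rho)
        b = 1.0 / np.sqrt(1.0 - rho)
        W = np.vstack([Xs * a, Xd * b])
        Q, R = np.linalg.qr(W)
        U = np.vstack([S * a, D * b])
        ctU = Q.T @ U
        rss = np.maximum(a * a * s_norm2 + b * b * d_norm2 - np.sum(ctU * ctU, axis=0),
                         1e-300)
        neg2ll = N * np.log(rss / N) + n * np.log1p(-rho * rho)
        improved = neg2ll < best
        best[improved] = neg2ll[improved]
        best_idx[improved] = i
        qr_cache[i] = (Q, R)

    beta = np.empty((p, m))
    sigma2 = np.empty(m)
    xtx_inv = {}
    for idx in np.unique(best_idx):
        rho = rho_grid[idx]
        a = 1.0 / np.sqrt(1.0 + rho)
        b = 1.0 / np.sqrt(1.0 - rho)
        Q, R = qr_cache[idx]
        mask = best_idx == idx
        U = np.vstack([S[:, mask] * a, D[:, mask] * b])
        ctU = Q.T @ U
        beta[:, mask] = np.linalg.solve(R, ctU)
        rss = np.maximum(np.sum(U * U, axis=0) - np.sum(ctU * ctU, axis=0), 1e-300)
        sigma2[mask] = rss / max(N - p, 1)
        r_inv = np.linalg.inv(R)
        xtx_inv[int(idx)] = r_inv @ r_inv.T
    return _CsFit(
        columns=list(columns) if columns is not None else list(range(p)),
        neg2ll=best,
        rho=rho_grid[best_idx],
        beta=beta,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
        rho_idx=best_idx,
        n_obs=N,
    )


def _containment_df2(X: pd.DataFrame, model: str) -> int:
    """Denominator df for the 2-df F-test (containment rule).

    The interaction terms are identified by within-subject (difference)
    information, the group terms by between-subject (sum) information; the
    denominator df is the subject count minus the rank of the corresponding
    half-design.
    """
    Xs, Xd = _pair_halves(X.to_numpy(dtype=float))
    half = Xd if model == "interaction" else Xs
    nz = half[:, np.abs(half).sum(axis=0) > 1e-9]
    return int(Xs.shape[0] - np.linalg.matrix_rank(nz))


def _wald_f_pvalues(fit: _CsFit, X: pd.DataFrame, test_cols, model: str) -> np.ndarray:
    """2-df Wald F-test of the ``test_cols`` coefficients for every probe."""
    cols = list(X.columns)
    q = len(test_cols)
    C = np.zeros((q, len(cols)))
    for i, tc in enumerate(test_cols):
        C[i, cols.index(tc)] = 1.0
    F = np.empty(fit.beta.shape[1])
    for idx, xtxi in fit.xtx_inv.items():
        mask = fit.rho_idx == idx
        mid = C @ xtxi @ C.T
        cb = C @ fit.beta[:, mask]
        F[mask] = np.einsum("ij,ij->j", cb, np.linalg.solve(mid, cb)) / (
            fit.sigma2[mask] * q
        )
    df2 = _containment_df2(X, model)
    return stats.f.sf(F, q, df2)


# ---------------------------------------------------------------------------
# public fitting API


@dataclass
class DmpResult:
    """Per-probe differential-methylation test record."""

    probe_id: str
    model: str  # "interaction" or "group"
    p_2df: float
    q_bh: float | None
    group_visit_slopes: dict | None  # group -> post-pre slope (M-units)
    slope_se: dict | None
    pairwise_group_diffs: dict | None  # "PvR"/"RvM"/"PvM" -> M-unit contrast
    diff_se: dict | None
    n_used: int
    status: str  # "ok", "cs_gls", or "zero_variance"


def fit_dmp_batch(values: pd.DataFrame, samples: pd.DataFrame, model: str) -> pd.DataFrame:
    """Fit the chosen DMP model for every probe (rows of ``values``).

    ``values`` is probes x samples (M-units), columns keyed by sample id.
    Returns a DataFrame indexed by probe id with the 2-df F-test p-value, the
    per-group slopes (interaction model) or pairwise contrasts (group model)
    with standard errors, BH q-values, ``n_used`` and a status flag.
    Zero-variance probes are flagged and excluded from the FDR.
    """
    s, X, test_cols = _encode_design(samples, model)
    missing = [sid for sid in s.index if sid not in values.columns]
    if missing:
        raise KeyError(f"samples absent from methylation matrix: {missing[:5]}")
    Y = values.loc[:, s.index].to_numpy(dtype=float).T  # (N, m)
    probe_ids = values.index
    m = Y.shape[1]

    good = np.var(Y, axis=0) > 1e-12
    out = pd.DataFrame(index=probe_ids)
    out["p_2df"] = np.nan
    out["status"] = "zero_variance"
    out["n_used"] = X.shape[0]
    out["rho"] = np.nan

    if model == "interaction":
        slope_cols = {g: f"slope_{g}" for g in GROUPS}
        for g in GROUPS:
            out[slope_cols[g]] = np.nan
            out[f"se_{g}"] = np.nan
    else:
        for k in ("PvR", "RvM", "PvM"):
            out[f"diff_{k}"] = np.nan
            out[f"se_{k}"] = np.nan

    if good.any():
        Xv = X.to_numpy(dtype=float)
        full = _fit_cs_ml(Xv, Y[:, good], columns=X.columns)
        p = _wald_f_pvalues(full, X, test_cols, model)
        gidx = np.where(good)[0]
        out.iloc[gidx, out.columns.get_loc("p_2df")] = p
        out.iloc[gidx, out.columns.get_loc("rho")] = full.rho
        status = np.where(full.rho < 0, "cs_gls", "ok")
        out.iloc[gidx, out.columns.get_loc("status")] = status

        cols = list(X.columns)

        def unit(name):
            c = np.zeros(len(cols))
            c[cols.index(name)] = 1.0
            return c

        if model == "interaction":
            contrasts = {
                "maintainer": unit("visit_post"),
                "progressor": unit("visit_post") + unit("progressor_x_visit"),
                "reverter": unit("visit_post") + unit("reverter_x_visit"),
            }
            for g, c in contrasts.items():
                est, se = full.contrast(c)
                out.iloc[gidx, out.columns.get_loc(f"slope_{g}")] = est
                out.iloc[gidx, out.columns.get_loc(f"se_{g}")] = se
        else:
            contrasts = {
                "PvR": unit("group_progressor") - unit("group_reverter"),
                "RvM": unit("group_reverter"),
                "PvM": unit("group_progressor"),
            }
            for k, c in contrasts.items():
                est, se = full.contrast(c)
                out.iloc[gidx, out.columns.get_loc(f"diff_{k}")] = est
                out.iloc[gidx, out.columns.get_loc(f"se_{k}")] = se

    out["q_bh"] = bh_fdr(out["p_2df"].to_numpy())
    out.index.name = "probe_id"
    return out


def _single(values, samples, model) -> DmpResult:
    if isinstance(values, pd.Series):
        row = values.to_frame().T
        row.index = ["probe"]
    else:
        arr = np.asarray(values, dtype=float)
        row = pd.DataFrame([arr], index=["probe"], columns=samples.index)
    res = fit_dmp_batch(row, samples, model).iloc[0]
    slopes = se_s = diffs = se_d = None
    if model == "interaction":
        slopes = {g: float(res[f"slope_{g}"]) for g in GROUPS}
        se_s = {g: float(res[f"se_{g}"]) for g in GROUPS}
    else:
        diffs = {k: float(res[f"diff_{k}"]) for k in ("PvR", "RvM", "PvM")}
        se_d = {k: float(res[f"se_{k}"]) for k in ("PvR", "RvM", "PvM")}
    return DmpResult(
        probe_id=str(values.name) if isinstance(values, pd.Series) and values.name else "probe",
        model=model,
        p_2df=float(res["p_2df"]),
        q_bh=None,
        group_visit_slopes=slopes,
        slope_se=se_s,
        pairwise_group_diffs=diffs,
        diff_se=se_d,
        n_used=int(res["n_used"]),
        status=str(res["status"]),
    )


def fit_interaction_dmp(probe_values, samples: pd.DataFrame) -> DmpResult:
    """Group x visit interaction model for one probe (2-df F-test + per-group slopes)."""
    return _single(probe_values, samples, "interaction")


def fit_group_dmp(probe_values, samples: pd.DataFrame) -> DmpResult:
    """Group main-effect model for one probe (2-df F-test + pairwise contrasts).

    Subjects missing ancestry PCs are dropped (complete case); ``n_used``
    reflects the retained observations.
    """
    return _single(probe_values, samples, "group")
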