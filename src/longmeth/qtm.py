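"""Region-level correlation of methylation with expression and metabolites.

For every retained region, per-CpG methylation is residualised on the model
covariates (keeping the subject-level signal), collapsed to one value per
subject (post - pre delta for differentially changing regions, pre/post mean
for average-difference regions), and summarised across CpGs by the first
principal component.  That region score is then tested against

* gene expression residuals (Spearman correlation, genes whose TSS lies
  within a cis window of the region midpoint), with BH-FDR across all
  region x cis-gene pairs of a candidate family; and
* metabolite contrasts (standardised-beta simple regression, i.e. the slope
  after z-scoring both sides, numerically the Pearson r), Box-Cox
  transformed upstream, with BH-FDR within each metabolomics panel.

PC1's sign is indeterminate, so the score is oriented to correlate
positively with the across-CpG mean: an increasing score always means
increasing methylation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ewas import CELL_TYPES, _check_paired, _fit_cs_ml, bh_fdr

_COVARIATE_EXPANDERS = {
    "sex": lambda s: {"sex_female": (s["sex"] == "F").astype(float)},
    "platform": lambda s: {"platform_epic": (s["platform"] == "EPIC").astype(float)},
    "cell_props": lambda s: {ct: s[ct].astype(float) for ct in CELL_TYPES},
    "ancestry": lambda s: {"pc1": s["pc1"].astype(float), "pc2": s["pc2"].astype(float)},
}


def _covariate_matrix(samples: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(samples))}
    for name in covariates:
        if name in _COVARIATE_EXPANDERS:
            cols.update(_COVARIATE_EXPANDERS[name](samples))
        elif name in samples.columns:
            cols[name] = samples[name].astype(float)
        else:
            raise ValidationError(f"unknown covariate {name!r}")
    X = pd.DataFrame(cols, index=samples.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValidationError(f"missing values in covariates: {bad}")
    # drop collinear columns: cell proportions first (they sum to 1 and are
    # collinear with the intercept), then other columns right to left
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        cell_cols = [c for c in X.columns if c in CELL_TYPES]
        victim = cell_cols[-1] if cell_cols else X.columns[-1]
        if victim == "intercept":
            raise ValidationError("covariate matrix irreparably rank deficient")
        warnings.warn(f"dropping collinear covariate column {victim!r}", stacklevel=3)
        X = X.drop(columns=victim)
    return X


def residualize_repeated(values: pd.Series, samples: pd.DataFrame, covariates,
                         random_intercept: bool = True) -> pd.Series:
    """Residuals after removing the fixed covariate effects.

    With ``random_intercept=True`` the fixed effects are estimated by the
    two-visit mixed model, but only the fitted *fixed* part is subtracted, so
    within-subject change survives into downstream delta/mean contrasts.
    Without it, plain OLS.  Residuals come back aligned to ``values``' index.
    """
    if random_intercept:
        s = _check_paired(samples)
        X = _covariate_matrix(s, covariates)
        y = values.loc[s.index].to_numpy(dtype=float)[:, None]
        fit = _fit_cs_ml(X.to_numpy(dtype=float), y, columns=X.columns)
        fitted = X.to_numpy(dtype=float) @ fit.beta[:, 0]
        resid = pd.Series(y[:, 0] - fitted, index=s.index)
    else:
        X = _covariate_matrix(samples, covariates)
        y = values.loc[samples.index].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X.to_numpy(dtype=float), y, rcond=None)
        resid = pd.Series(y - X.to_numpy(dtype=float) @ beta, index=samples.index)
    return resid.reindex(values.index)


def paired_contrast(residuals: pd.Series, samples: pd.DataFrame, mode: str) -> pd.Series:
    """Per-subject delta (post - pre) or mean ((post + pre) / 2) of residuals.

    Subjects missing either visit are dropped with a warning.
    """
    if mode not in ("delta", "mean"):
        raise ValueError(f"mode must be 'delta' or 'mean', got {mode!r}")
    df = pd.DataFrame({
        "value": residuals,
        "subject_id": samples.loc[residuals.index, "subject_id"],
        "visit": samples.loc[residuals.index, "visit"],
    })
    wide = df.pivot_table(index="subject_id", columns="visit", values="value",
                          aggfunc="first")
    for v in ("pre", "post"):
        if v not in wide.columns:
            wide[v] = np.nan
    incomplete = wide["pre"].isna() | wide["post"].isna()
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} subject(s) missing a visit",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    if mode == "delta":
        out = wide["post"] - wide["pre"]
    else:
        out = (wide["post"] + wide["pre"]) / 2.0
    out.name = mode
    return out


@dataclass
class RegionScore:
    """First-PC summary of a region's CpGs, one score per subject."""

    region_id: str
    scores: pd.Series  # indexed by subject id, zero mean
    mode: str  # "delta" or "mean"
    variance_explained: float
    orientation: int  # +1/-1 sign applied so score tracks mean methylation


def region_pc1(matrix: pd.DataFrame, region_id: str = "", mode: str = "delta") -> RegionScore:
    """PC1 scores of a subject x CpG matrix (columns standardised first).

    Zero-variance CpGs are dropped with a warning; the sign is fixed so the
    score correlates positively with the across-CpG row mean.
    """
    if matrix.shape[0] < 3:
        raise ValidationError("need at least 3 subjects for a region PCA")
    sd = matrix.std(axis=0, ddof=1)
    dead = sd <= 0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} zero-variance CpG(s)", stacklevel=2)
        matrix = matrix.loc[:, ~dead]
        sd = sd[~dead]
    if matrix.shape[1] == 0:
        raise ValidationError("all CpGs in region have zero variance")
    Z = (matrix - matrix.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    scores = U[:, 0] * s[0]
    ve = float(s[0] ** 2 / np.sum(s**2))
    row_mean = Z.mean(axis=1).to_numpy()
    orientation = 1
    if row_mean.std() > 0 and np.corrcoef(scores, row_mean)[0, 1] < 0:
        orientation = -1
        scores = -scores
    return RegionScore(
        region_id=region_id,
        scores=pd.Series(scores, index=matrix.index),
        mode=mode,
        variance_explained=ve,
        orientation=orientation,
    )


def cis_features(region, tss_table: pd.DataFrame, window: int = 500_000) -> list:
    """Genes whose TSS lies within ``window`` bp of the region midpoint.

    ``region`` needs ``chrom``/``start``/``stop`` attributes or keys (0-based
    half-open); ``tss_table`` needs columns ``gene_id``, ``chrom``, ``tss``.
    """
    if isinstance(region, dict):
        chrom, start, stop = region["chrom"], region["start"], region["stop"]
    else:
        chrom, start, stop = region.chrom, region.start, region.stop
    if tss_table is None or len(tss_table) == 0:
        return []
    mid = (start + stop) // 2
    same = tss_table["chrom"].astype(str) == str(chrom)
    close = (tss_table["tss"].astype(np.int64) - mid).abs() <= window
    return list(tss_table.loc[same & close, "gene_id"])


def tss_from_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Derive TSS from gene start/end and strand (minus strand: TSS = gene end)."""
    out = genes.copy()
    strand = out["strand"].astype(int)
    out["tss"] = np.where(strand >= 0, out["start"], out["end"]).astype(np.int64)
    return out[["gene_id", "chrom", "tss"]]


@dataclass
class QtmResult:
    """One region x feature association."""

    region_id: str
    feature_id: str
    panel: str  # "expression", "HILIC", "Lipid", or "GCTOF"
    statistic: float  # Spearman rho (eQTM) or standardised beta (metQTM)
    p: float
    q_bh: float | None
    n: int
    status: str = "ok"


def eqtm_test(region_score: RegionScore, expression: pd.Series,
              feature_id: str = "", exact: bool = False) -> QtmResult:
    """Spearman correlation between a region score and expression residuals.

    ``exact=True`` computes a permutation p-value (sensible only for n <= 10);
    otherwise the t approximation with midranks is used.
    """
    x, y = region_score.scores.align(expression.dropna(), join="inner")
    n = len(x)
    if n < 5:
        raise ValidationError(f"need >= 5 paired subjects, got {n}")
    if y.nunique() <= 1 or x.nunique() <= 1:
        return QtmResult(region_score.region_id, feature_id, "expression",
                         np.nan, np.nan, None, n, status="constant_input")
    if exact:
        res = stats.permutation_test(
            (x.to_numpy(),),
            lambda xs: stats.spearmanr(xs, y.to_numpy()).statistic,
            permutation_type="pairings", n_resamples=100_000, alternative="two-sided",
            random_state=0,
        )
        rho = float(stats.spearmanr(x, y).statistic)
        p = float(res.pvalue)
    else:
        rho, p = stats.spearmanr(x, y)
    return QtmResult(region_score.region_id, feature_id, "expression",
                     float(rho), float(p), None, n)


def boxcox(values, lambdas=None):
    """Box-Cox transform with lambda chosen by ML on a fixed grid [-2, 2] step 0.1.

    Nonpositive inputs are shifted by (1 - min) with a warning.  Returns
    ``(transformed, lambda)``.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.any(x <= 0):
        shift = 1.0 - x.min()
        warnings.warn(f"nonpositive values; shifting by {shift:.4g}", stacklevel=2)
        x = x + shift
    if lambdas is None:
        lambdas = np.round(np.arange(-20, 21) * 0.1, 1)
    llf = [stats.boxcox_llf(lam, x) for lam in lambdas]
    lam = float(lambdas[int(np.argmax(llf))])
    if lam == 0.0:
        y = np.log(x)
    else:
        y = (x**lam - 1.0) / lam
    return y, lam


def metqtm_test(region_score: RegionScore, metabolite_contrast: pd.Series,
                panel: str, feature_id: str = "") -> QtmResult:
    """Standardised-beta regression of a metabolite contrast on a region score.

    Both sides are z-scored, so the reported slope is a 1-SD-per-1-SD effect
    (numerically the Pearson r); the p-value is the regression t-test.
    """
    x, y = region_score.scores.align(metabolite_contrast.dropna(), join="inner")
    n = len(x)
    if n < 5:
        raise ValidationError(f"need >= 5 paired subjects, got {n}")
    if x.std(ddof=1) <= 0 or y.std(ddof=1) <= 0:
        return QtmResult(region_score.region_id, feature_id, panel,
                         np.nan, np.nan, None, n, status="constant_input")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    fit = stats.linregress(zx.to_numpy(), zy.to_numpy())
    return QtmResult(region_score.region_id, feature_id, panel,
                     float(fit.slope), float(fit.pvalue), None, n)


def results_to_frame(results) -> pd.DataFrame:
    rows = [
        {
            "region_id": r.region_id, "feature_id": r.feature_id, "panel": r.panel,
            "statistic": r.statistic, "p": r.p, "q_bh": r.q_bh, "n": r.n,
            "status": r.status,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def fdr_by_stratum(results: pd.DataFrame, by: str = "panel") -> pd.DataFrame:
    """BH-FDR applied separately within each stratum (e.g. metabolomics panel)."""
    out = results.copy()
    out["q_bh"] = np.nan
    for _, idx in out.groupby(by).groups.items():
        out.loc[idx, "q_bh"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
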