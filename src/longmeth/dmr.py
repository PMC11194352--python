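"""Retention rules and summary columns for called methylation regions.

A candidate region is only reported when the per-probe effect directions are
coherent: for a differentially *changing* region (delta-DMR) at least one
phenotype group must have 100% of its member-probe visit slopes sharing one
sign; for a differential *average* region (mu-DMR) at least one pairwise
group contrast must be unanimous across probes.  Regions additionally need
>= 4 probes and a Sidak-adjusted region p below 0.10 (defaults).

A slope of exactly zero counts with the majority sign (configurable via
``zero_counts_with_majority``); with a 50/50 sign split the consistency
share is 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combp import RegionResult
from .errors import IncompleteRegionError
from .ewas import GROUPS

CONTRASTS = ("PvR", "RvM", "PvM")


def _direction_share(values: np.ndarray, zero_counts_with_majority: bool = True) -> float:
    """Share of values carrying the majority sign (zeros counted per policy)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("empty value set")
    pos = int(np.sum(v > 0))
    neg = int(np.sum(v < 0))
    zero = n - pos - neg
    majority = max(pos, neg)
    if zero_counts_with_majority:
        majority += zero
    return majority / n


@dataclass
class DeltaDmrRecord:
    """Delta-DMR: region where the pre->post methylation change differs by group."""

    region_id: str
    chrom: str
    start: int  # 0-based half-open
    stop: int
    n_probes: int
    slk_p: float
    sidak_p: float
    leading_probe: str | None
    slope_pct: dict  # group -> share of probes with the majority slope sign
    median_slope: dict  # group -> median per-probe visit slope (M-units)
    probe_ids: list = field(default_factory=list)
    retained: bool = False


@dataclass
class MuDmrRecord:
    """Mu-DMR: region where average (pre+post) methylation differs by group."""

    region_id: str
    chrom: str
    start: int
    stop: int
    n_probes: int
    slk_p: float
    sidak_p: float
    leading_probe: str | None
    pairwise_consistency: dict  # contrast -> share of probes with majority sign
    median_pairwise_diff: dict  # contrast -> median per-probe contrast (M-units)
    probe_ids: list = field(default_factory=list)
    retained: bool = False


def _region_rows(region: RegionResult, dmp: pd.DataFrame, needed_cols) -> pd.DataFrame:
    missing = [pid for pid in region.probe_ids if pid not in dmp.index]
    if missing:
        raise IncompleteRegionError(
            f"region probes without test results: {missing[:5]}"
        )
    rows = dmp.loc[region.probe_ids]
    for col in needed_cols:
        if col not in rows.columns:
            raise IncompleteRegionError(f"per-probe results lack column {col!r}")
    return rows


def summarize_delta_region(region: RegionResult, dmp: pd.DataFrame,
                           region_id: str = "", *,
                           zero_counts_with_majority: bool = True) -> DeltaDmrRecord:
    """Direction-consistency shares and median slopes per group for one region.

    ``dmp`` must be indexed by probe id and carry ``slope_<group>`` columns
    from the interaction model.
    """
    cols = [f"slope_{g}" for g in GROUPS]
    rows = _region_rows(region, dmp, cols)
    slope_pct = {}
    median_slope = {}
    for g in GROUPS:
        v = rows[f"slope_{g}"].to_numpy(dtype=float)
        slope_pct[g] = _direction_share(v, zero_counts_with_majority)
        median_slope[g] = float(np.median(v))
    return DeltaDmrRecord(
        region_id=region_id or f"{region.chrom}:{region.start}-{region.stop}",
        chrom=region.chrom,
        start=region.start,
        stop=region.stop,
        n_probes=region.n_probes,
        slk_p=region.slk_p,
        sidak_p=region.sidak_p,
        leading_probe=region.leading_probe,
        slope_pct=slope_pct,
        median_slope=median_slope,
        probe_ids=list(region.probe_ids),
    )


def summarize_mu_region(region: RegionResult, dmp: pd.DataFrame,
                        region_id: str = "", *,
                        zero_counts_with_majority: bool = True) -> MuDmrRecord:
    """Pairwise-contrast consistency and medians for one region (group model).

    ``dmp`` must carry ``diff_PvR``/``diff_RvM``/``diff_PvM`` columns.
    """
    cols = [f"diff_{k}" for k in CONTRASTS]
    rows = _region_rows(region, dmp, cols)
    consistency = {}
    medians = {}
    for k in CONTRASTS:
        v = rows[f"diff_{k}"].to_numpy(dtype=float)
        consistency[k] = _direction_share(v, zero_counts_with_majority)
        medians[k] = float(np.median(v))
    return MuDmrRecord(
        region_id=region_id or f"{region.chrom}:{region.start}-{region.stop}",
        chrom=region.chrom,
        start=region.start,
        stop=region.stop,
        n_probes=region.n_probes,
        slk_p=region.slk_p,
        sidak_p=region.sidak_p,
        leading_probe=region.leading_probe,
        pairwise_consistency=consistency,
        median_pairwise_diff=medians,
        probe_ids=list(region.probe_ids),
    )


def _retain(record, consistency: dict, min_probes: int, sidak_alpha: float) -> bool:
    unanimous = any(v >= 1.0 for v in consistency.values())
    return (
        record.n_probes >= min_probes
        and np.isfinite(record.sidak_p)
        and record.sidak_p < sidak_alpha
        and unanimous
    )


def filter_delta_dmrs(records, min_probes: int = 4, sidak_alpha: float = 0.10):
    """Retain delta-DMRs with >= ``min_probes`` probes, Sidak p < alpha, and
    a unanimous slope direction in at least one group.  Sets ``retained`` on
    every record and returns the retained subset (input order preserved)."""
    kept = []
    for rec in records:
        rec.retained = _retain(rec, rec.slope_pct, min_probes, sidak_alpha)
        if rec.retained:
            kept.append(rec)
    return kept


def filter_mu_dmrs(records, min_probes: int = 4, sidak_alpha: float = 0.10):
    """Retain mu-DMRs whose pairwise contrasts include a unanimous direction,
    with >= ``min_probes`` probes and Sidak p < alpha."""
    kept = []
    for rec in records:
        rec.retained = _retain(rec, rec.pairwise_consistency, min_probes, sidak_alpha)
        if rec.retained:
            kept.append(rec)
    return kept


def delta_records_to_frame(records) -> pd.DataFrame:
    """Tabular view of delta-DMR records (one row per region)."""
    rows = []
    for r in records:
        row = {
            "region_id": r.region_id, "chrom": r.chrom, "start": r.start,
            "stop": r.stop, "n_probes": r.n_probes, "slk_p": r.slk_p,
            "sidak_p": r.sidak_p, "leading_probe": r.leading_probe,
            "retained": r.retained,
        }
        for g in GROUPS:
            row[f"slope_pct_{g}"] = r.slope_pct[g]
            row[f"median_slope_{g}"] = r.median_slope[g]
        rows.append(row)
    return pd.DataFrame(rows)


def mu_records_to_frame(records) -> pd.DataFrame:
    """Tabular view of mu-DMR records."""
    rows = []
    for r in records:
        row = {
            "region_id": r.region_id, "chrom": r.chrom, "start": r.start,
            "stop": r.stop, "n_probes": r.n_probes, "slk_p": r.slk_p,
            "sidak_p": r.sidak_p, "leading_probe": r.leading_probe,
            "retained": r.retained,
        }
        for k in CONTRASTS:
            row[f"consistency_{k}"] = r.pairwise_consistency[k]
            row[f"median_{k}"] = r.median_pairwise_diff[k]
        rows.append(row)
    return pd.DataFrame(rows)
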