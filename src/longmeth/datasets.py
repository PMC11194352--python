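"""Loaders for the shipped reference tables.

These small TSVs encode the published candidate-region and QTM summary
tables from the longitudinal islet-autoimmunity methylation study this
pipeline models.  They are used as validation fixtures for the retention
filters, the sign bookkeeping, and the cis-window logic -- not as inputs to
any statistical computation.

Notes on encoding:

* delta-DMR median slopes printed as "<0.01" are stored as 0.005;
* the mu-DMR table prints per-contrast medians but only a region-level
  statement that at least one pairwise contrast was unanimous across probes;
  the ``unanimous_contrast`` flag encodes that statement and the loader maps
  it onto all three contrasts;
* metabolite names that the source table prints identically for distinct
  features are disambiguated with a trailing " B".
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from . import coords
from .dmr import CONTRASTS, DeltaDmrRecord, MuDmrRecord
from .ewas import GROUPS


def _read(name: str) -> pd.DataFrame:
    with resources.files("longmeth.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_delta_table() -> pd.DataFrame:
    """Raw delta-DMR reference table (coordinates 1-based inclusive)."""
    return _read("reference_delta_dmrs.tsv")


def load_reference_mu_table() -> pd.DataFrame:
    """Raw mu-DMR reference table (coordinates 1-based inclusive)."""
    return _read("reference_mu_dmrs.tsv")


def load_reference_eqtms() -> pd.DataFrame:
    """Published cis-eQTM hits (region coordinates and gene spans, 1-based)."""
    return _read("reference_eqtms.tsv")


def load_reference_metqtms() -> pd.DataFrame:
    """Published region x metabolite associations (standardised betas)."""
    return _read("reference_metqtms.tsv")


def load_reference_delta_dmrs() -> list[DeltaDmrRecord]:
    """Delta-DMR reference rows as records ready for the retention filter."""
    out = []
    for _, row in load_reference_delta_table().iterrows():
        start, stop = coords.points_to_interval(int(row["start"]), int(row["stop"]))
        out.append(
            DeltaDmrRecord(
                region_id=row["dmr_id"], chrom=row["chrom"], start=start, stop=stop,
                n_probes=int(row["n_probes"]), slk_p=float("nan"),
                sidak_p=float(row["sidak_p"]), leading_probe=row["leading_cpg"],
                slope_pct={g: float(row[f"slope_pct_{g}"]) for g in GROUPS},
                median_slope={g: float(row[f"median_slope_{g}"]) for g in GROUPS},
            )
        )
    return out


def load_reference_mu_dmrs() -> list[MuDmrRecord]:
    """Mu-DMR reference rows as records ready for the retention filter."""
    out = []
    for _, row in load_reference_mu_table().iterrows():
        start, stop = coords.points_to_interval(int(row["start"]), int(row["stop"]))
        flag = 1.0 if int(row["unanimous_contrast"]) else 0.0
        out.append(
            MuDmrRecord(
                region_id=row["dmr_id"], chrom=row["chrom"], start=start, stop=stop,
                n_probes=int(row["n_probes"]), slk_p=float("nan"),
                sidak_p=float(row["sidak_p"]), leading_probe=row["leading_cpg"],
                pairwise_consistency={k: flag for k in CONTRASTS},
                median_pairwise_diff={k: float(row[f"median_{k}"]) for k in CONTRASTS},
            )
        )
    return out
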