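"""Readers and writers for the on-disk formats.

Formats: manifest TSV, sample sheet CSV, M-value / expression / metabolite
matrices TSV (features as rows), TSS table TSV, BED6 + TSV region tables,
ground-truth and summary JSON, YAML configuration.  Every file written here
starts with a ``# longmeth config=<hash> seed=<seed>`` comment so a run can
be traced back to its configuration; readers skip ``#`` lines.  Missing
values are empty fields, never sentinel numbers.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dmr import delta_records_to_frame, mu_records_to_frame
from .errors import ValidationError
from .simulate import GroundTruth, MethylationDataset, truth_from_dict, truth_to_dict


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(meta: dict | None) -> str:
    meta = meta or {}
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# longmeth {parts}".rstrip() + "\n"


def write_table(df: pd.DataFrame, path, *, sep: str = "\t", index: bool = True,
                meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep=sep, index=index, na_rep="")


def _read_table(path, *, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_manifest(manifest: pd.DataFrame, path, meta=None):
    write_table(manifest, path, index=False, meta=meta)


def read_manifest(path) -> pd.DataFrame:
    man = _read_table(path)
    if man["probe_id"].duplicated().any():
        dup = list(man.loc[man["probe_id"].duplicated(), "probe_id"])[:5]
        raise ValidationError(f"duplicate probe ids in manifest: {dup}")
    if (man["pos"] < 1).any():
        raise ValidationError("manifest positions must be >= 1")
    return man


def write_sample_sheet(samples: pd.DataFrame, path, meta=None):
    write_table(samples, path, sep=",", index=True, meta=meta)


def read_sample_sheet(path) -> pd.DataFrame:
    s = _read_table(path, sep=",", index_col=0)
    if s.index.duplicated().any():
        raise ValidationError(f"duplicate sample ids: {list(s.index[s.index.duplicated()])[:5]}")
    return s


def write_matrix(values: pd.DataFrame, path, meta=None):
    write_table(values, path, index=True, meta=meta)


def read_matrix(path) -> pd.DataFrame:
    m = _read_table(path, index_col=0)
    if m.index.duplicated().any():
        raise ValidationError(f"duplicate row ids in matrix: {list(m.index[m.index.duplicated()])[:5]}")
    return m


def read_methylation(matrix_path, manifest_path, sample_sheet_path) -> MethylationDataset:
    """Load and cross-validate the matrix, manifest and sample sheet.

    Probe and sample id sets must match exactly (offenders are listed);
    output rows are sorted by (chromosome, position) and columns follow the
    sample sheet order.
    """
    values = read_matrix(matrix_path)
    manifest = read_manifest(manifest_path)
    samples = read_sample_sheet(sample_sheet_path)
    extra_cols = [c for c in values.columns if c not in samples.index]
    missing_cols = [s for s in samples.index if s not in values.columns]
    if extra_cols or missing_cols:
        raise ValidationError(
            f"matrix/sample-sheet mismatch; extra={extra_cols[:5]} missing={missing_cols[:5]}"
        )
    man_ids = set(manifest["probe_id"])
    extra_rows = [p for p in values.index if p not in man_ids]
    missing_rows = [p for p in manifest["probe_id"] if p not in values.index]
    if extra_rows or missing_rows:
        raise ValidationError(
            f"matrix/manifest mismatch; extra={extra_rows[:5]} missing={missing_rows[:5]}"
        )
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    values = values.loc[manifest["probe_id"], samples.index]
    return MethylationDataset(values=values, manifest=manifest, samples=samples)


def read_tss_table(path) -> pd.DataFrame:
    """TSS table TSV with columns gene_id, chrom, tss (or start/end/strand)."""
    t = _read_table(path)
    if "tss" not in t.columns:
        from .qtm import tss_from_gene_table

        t = tss_from_gene_table(t)
    return t[["gene_id", "chrom", "tss"]]


def write_ground_truth(truth: GroundTruth, path, meta=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": meta or {}, **truth_to_dict(truth)}
    path.write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    d.pop("_meta", None)
    return truth_from_dict(d)


def bed_score(sidak_p: float) -> int:
    """BED score: min(-10 log10 sidak_p, 1000), floored at 0."""
    if not np.isfinite(sidak_p) or sidak_p <= 0:
        return 1000
    return int(min(max(-10.0 * np.log10(sidak_p), 0.0), 1000.0))


def write_regions(records, out_dir, prefix: str, meta=None):
    """Write region records as a BED6 track plus a full TSV table.

    Records carry 0-based half-open coordinates already, so BED needs no
    further arithmetic.  Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_path = out_dir / f"{prefix}.bed"
    tsv_path = out_dir / f"{prefix}.tsv"
    with open(bed_path, "w") as fh:
        fh.write(_header(meta))
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.stop}\t{r.region_id}\t{bed_score(r.sidak_p)}\t.\n"
            )
    if records and hasattr(records[0], "slope_pct"):
        df = delta_records_to_frame(records)
    elif records and hasattr(records[0], "pairwise_consistency"):
        df = mu_records_to_frame(records)
    else:
        df = pd.DataFrame(
            columns=["region_id", "chrom", "start", "stop", "n_probes",
                     "slk_p", "sidak_p", "leading_probe", "retained"]
        )
    write_table(df, tsv_path, index=False, meta=meta)
    return bed_path, tsv_path


def read_config(path) -> dict:
    """YAML configuration (JSON is a valid subset and also accepted)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError("configuration must be a mapping")
    return cfg


def write_json(obj: dict, path, meta=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": meta or {}, **obj}
    path.write_text(json.dumps(payload, indent=1, default=float))
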