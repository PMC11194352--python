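"""Synthetic longitudinal methylation cohort with planted regional effects.

Emulates the structure of a three-phenotype (reverter / maintainer /
progressor), two-visit (pre / post seroconversion) blood-methylation study:

* a probe manifest with clustered CpGs (clusters are combinable into
  regions: intra-cluster spacing < 500 bp, inter-cluster gaps > 500 bp),
  isolated singleton probes, and the annotation flags the probe filter
  consumes;
* a sample sheet with group sizes 60/42/41 (286 rows), group- and
  visit-shifted lognormal ages, sex, platform, Dirichlet blood-cell
  proportions and standard-normal ancestry PCs (optionally missing for a
  few subjects, to exercise the complete-case rule);
* an M-value matrix built as probe baseline + covariate effects + subject
  random intercept + planted group offsets (mu regions) + planted
  group-specific visit slopes (delta regions) + exponentially
  distance-decaying spatial noise within clusters + iid residual;
* expression (post visit only) and metabolite (both visits) matrices whose
  linked features track a planted region's subject-level signal at a stated
  target Spearman correlation / standardised beta.

Every generator is deterministic for a fixed seed.  Effect sizes default to
the 0.03-0.16 M-unit scale typical of blood EWAS hits.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ewas import CELL_TYPES, GROUPS

PANELS = ("HILIC", "Lipid", "GCTOF")

# Table-1-like structure: progressors seroconvert younger; visits ~1.5 y apart.
_DEFAULT_AGE_MEDIAN = {
    ("maintainer", "pre"): 5.7, ("maintainer", "post"): 8.0,
    ("progressor", "pre"): 2.2, ("progressor", "post"): 4.9,
    ("reverter", "pre"): 6.0, ("reverter", "post"): 7.1,
}
# Blood-cell Dirichlet concentration ~ 60 x median proportions
_DEFAULT_CELL_ALPHA = np.array([0.13, 0.21, 0.02, 0.14, 0.08, 0.42]) * 60.0


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


@dataclass
class CohortDesign:
    """Study-design parameters for the synthetic cohort."""

    n_per_group: dict = field(
        default_factory=lambda: {"maintainer": 60, "progressor": 42, "reverter": 41}
    )
    age_median: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_MEDIAN))
    age_sigma: float = 0.7  # lognormal scale of subject age around the group median
    sex_prob: float = 0.5  # P(female)
    platform_prob: float = 0.5  # P(EPIC)
    cellprop_alpha: dict = field(
        default_factory=lambda: {
            (g, v): _DEFAULT_CELL_ALPHA.copy() for g in GROUPS for v in ("pre", "post")
        }
    )
    subject_sd: float = 0.30  # random-intercept SD, M-units
    residual_sd: float = 0.10  # iid residual SD, M-units
    spatial_sd: float = 0.05  # SD of the spatially correlated noise, M-units
    spatial_decay: float = 0.01  # per-bp decay of within-cluster correlation
    n_missing_ancestry: int = 2  # subjects with ancestry PCs nulled out
    seed: int = 0

    def validate(self):
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValidationError("group sizes must be positive")
        for key, alpha in self.cellprop_alpha.items():
            a = np.asarray(alpha, dtype=float)
            if len(a) != len(CELL_TYPES) or np.any(a <= 0):
                raise ValidationError(f"Dirichlet parameters for {key} must be {len(CELL_TYPES)} positive reals")
        for sd in (self.subject_sd, self.residual_sd, self.spatial_sd):
            if sd <= 0:
                raise ValidationError("all standard deviations must be > 0")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class PlantedRegion:
    region_id: str
    chrom: str
    start_pos: int  # 1-based inclusive probe span
    end_pos: int
    probe_ids: list
    effects: dict  # group -> visit slope (delta) or mean offset (mu), M-units


@dataclass
class LinkedGene:
    gene_id: str
    chrom: str
    tss: int
    region_id: str
    target_spearman: float


@dataclass
class LinkedMetabolite:
    met_id: str
    panel: str
    region_id: str
    target_beta: float


@dataclass
class GroundTruth:
    delta_regions: list = field(default_factory=list)
    mu_regions: list = field(default_factory=list)
    linked_genes: list = field(default_factory=list)
    linked_metabolites: list = field(default_factory=list)
    null_probes: set = field(default_factory=set)

    def region(self, region_id: str) -> PlantedRegion:
        for r in self.delta_regions + self.mu_regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def validate(self, cis_window: int = 500_000):
        spans = {}
        for r in self.delta_regions + self.mu_regions:
            spans.setdefault(r.chrom, []).append((r.start_pos, r.end_pos, r.region_id))
        for chrom, lst in spans.items():
            lst.sort()
            for (s1, e1, i1), (s2, e2, i2) in zip(lst, lst[1:]):
                if s2 <= e1:
                    raise ValidationError(f"planted regions overlap: {i1} and {i2}")
        for g in self.linked_genes:
            r = self.region(g.region_id)
            mid = (r.start_pos + r.end_pos) // 2
            if abs(g.tss - mid) > cis_window:
                raise ValidationError(f"linked gene {g.gene_id} TSS outside cis window")


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(n_chrom: int = 2, clusters_per_chrom: int = 10,
                      probes_per_cluster_range: tuple = (4, 10),
                      intra_cluster_spacing_range: tuple = (20, 120),
                      seed: int = 0, *,
                      inter_cluster_gap_range: tuple = (2000, 8000),
                      frac_near_snp: float = 0.02,
                      frac_low_beta_range: float = 0.05,
                      n_sex_probes: int = 0) -> pd.DataFrame:
    """Probe manifest with clustered CpGs plus isolated singletons.

    Intra-cluster spacings must stay below 500 bp (so clusters can seed
    regions) and inter-cluster gaps above 500 bp (so clusters cannot merge).
    A singleton probe is dropped into each inter-cluster gap.  Optional
    ``n_sex_probes`` appends non-autosomal probes (chrX) for filter tests.
    """
    k_lo, k_hi = probes_per_cluster_range
    s_lo, s_hi = intra_cluster_spacing_range
    g_lo, g_hi = inter_cluster_gap_range
    if n_chrom <= 0 or clusters_per_chrom <= 0 or k_lo <= 0:
        raise ValidationError("counts must be positive")
    if k_hi < k_lo or s_hi < s_lo:
        raise ValidationError("ranges must be nonempty")
    if s_hi >= 500:
        raise ValidationError("intra-cluster spacing must stay below 500 bp")
    if g_lo <= 500:
        raise ValidationError("inter-cluster gaps must exceed 500 bp")

    rng = _rng(seed, 1)
    rows = []
    counter = 0

    def new_probe(chrom, pos, cluster, autosomal=True):
        nonlocal counter
        counter += 1
        rows.append({
            "probe_id": f"cg{counter:07d}", "chrom": chrom, "pos": int(pos),
            "cluster": cluster, "autosomal": autosomal, "near_snp": False,
            "beta_range_450k": float(rng.uniform(0.05, 0.60)),
            "beta_range_epic": float(rng.uniform(0.05, 0.60)),
        })

    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        cursor = int(rng.integers(10_000, 50_000))
        for j in range(clusters_per_chrom):
            k = int(rng.integers(k_lo, k_hi + 1))
            spacings = rng.integers(s_lo, s_hi + 1, size=max(k - 1, 0))
            pos = cursor + np.concatenate([[0], np.cumsum(spacings)]).astype(int)
            cname = f"{chrom}_c{j:03d}"
            for p in pos:
                new_probe(chrom, p, cname)
            cursor = int(pos[-1] + rng.integers(g_lo, g_hi + 1))
            # isolated singleton between clusters
            new_probe(chrom, cursor, f"{chrom}_s{j:03d}")
            cursor += int(rng.integers(g_lo, g_hi + 1))
    for i in range(n_sex_probes):
        new_probe("chrX", 10_000 + 1000 * i, f"chrX_s{i:03d}", autosomal=False)

    man = pd.DataFrame(rows)
    n = len(man)
    near = rng.random(n) < frac_near_snp
    man.loc[near, "near_snp"] = True
    low = rng.random(n) < frac_low_beta_range
    man.loc[low, "beta_range_450k"] = rng.uniform(0.002, 0.029, size=int(low.sum()))
    man.loc[low, "beta_range_epic"] = rng.uniform(0.002, 0.029, size=int(low.sum()))
    return man.reset_index(drop=True)


# ---------------------------------------------------------------------------
# samples


def generate_samples(design: CohortDesign) -> pd.DataFrame:
    """Sample sheet: two rows (pre, post) per subject, deterministic per seed."""
    design.validate()
    rng = _rng(design.seed, 2)
    rows = []
    sidx = 0
    for group in GROUPS:
        for _ in range(design.n_per_group[group]):
            sidx += 1
            subject = f"S{sidx:04d}"
            sex = "F" if rng.random() < design.sex_prob else "M"
            platform = "EPIC" if rng.random() < design.platform_prob else "450K"
            z_age = rng.standard_normal()
            age_pre = design.age_median[(group, "pre")] * np.exp(design.age_sigma * z_age)
            gap_med = max(
                design.age_median[(group, "post")] - design.age_median[(group, "pre")], 0.25
            )
            age_post = age_pre + gap_med * np.exp(0.3 * rng.standard_normal())
            pc1, pc2 = rng.standard_normal(2)
            for visit, age in (("pre", age_pre), ("post", age_post)):
                props = rng.dirichlet(np.asarray(design.cellprop_alpha[(group, visit)], dtype=float))
                row = {
                    "sample_id": f"{subject}_{visit}", "subject_id": subject,
                    "group": group, "visit": visit, "age": float(age), "sex": sex,
                    "platform": platform, "pc1": float(pc1), "pc2": float(pc2),
                }
                row.update({ct: float(p) for ct, p in zip(CELL_TYPES, props)})
                rows.append(row)
    samples = pd.DataFrame(rows).set_index("sample_id")
    if design.n_missing_ancestry > 0:
        subjects = samples["subject_id"].unique()
        drop = rng.choice(subjects, size=min(design.n_missing_ancestry, len(subjects)),
                          replace=False)
        samples.loc[samples["subject_id"].isin(drop), ["pc1", "pc2"]] = np.nan
    return samples


# ---------------------------------------------------------------------------
# ground-truth planting


def plant_ground_truth(manifest: pd.DataFrame, *,
                       n_delta_regions: int = 1, n_mu_regions: int = 1,
                       delta_slopes: dict | None = None,
                       mu_offsets: dict | None = None,
                       min_region_probes: int = 6,
                       gene_targets=(0.55,), metabolite_targets=(0.4,),
                       metabolite_panel: str = "Lipid",
                       seed: int = 0) -> GroundTruth:
    """Choose non-overlapping probe clusters to carry planted effects.

    Default effect scales follow the M-unit magnitudes seen in blood EWAS
    regions (slopes of a few hundredths, offsets of a few tenths).
    """
    delta_slopes = delta_slopes or {"reverter": 0.06, "progressor": 0.04, "maintainer": -0.08}
    mu_offsets = mu_offsets or {"maintainer": 0.0, "reverter": 0.37, "progressor": 0.46}
    rng = _rng(seed, 3)
    sizes = manifest.groupby("cluster")["probe_id"].count()
    eligible = sizes[sizes >= min_region_probes].index.to_numpy()
    need = n_delta_regions + n_mu_regions
    if len(eligible) < need:
        raise ValidationError(
            f"need {need} clusters with >= {min_region_probes} probes, found {len(eligible)}"
        )
    chosen = rng.choice(eligible, size=need, replace=False)

    def region_from_cluster(cluster, region_id, effects):
        sub = manifest[manifest["cluster"] == cluster].sort_values("pos")
        return PlantedRegion(
            region_id=region_id, chrom=str(sub["chrom"].iloc[0]),
            start_pos=int(sub["pos"].min()), end_pos=int(sub["pos"].max()),
            probe_ids=list(sub["probe_id"]), effects=dict(effects),
        )

    truth = GroundTruth()
    for i in range(n_delta_regions):
        truth.delta_regions.append(
            region_from_cluster(chosen[i], f"delta_{i + 1}", delta_slopes)
        )
    for i in range(n_mu_regions):
        truth.mu_regions.append(
            region_from_cluster(chosen[n_delta_regions + i], f"mu_{i + 1}", mu_offsets)
        )

    for i, target in enumerate(gene_targets):
        if not -1.0 < target < 1.0:
            raise ValidationError("target correlation must be in (-1, 1)")
        region = truth.delta_regions[i % max(len(truth.delta_regions), 1)]
        mid = (region.start_pos + region.end_pos) // 2
        tss = int(mid + rng.integers(-200_000, 200_000))
        truth.linked_genes.append(
            LinkedGene(f"GENE{i + 1:03d}", region.chrom, max(tss, 1),
                       region.region_id, float(target))
        )
    for i, target in enumerate(metabolite_targets):
        if not -1.0 < target < 1.0:
            raise ValidationError("target beta must be in (-1, 1)")
        region = truth.delta_regions[i % max(len(truth.delta_regions), 1)]
        truth.linked_metabolites.append(
            LinkedMetabolite(f"MET{i + 1:03d}", metabolite_panel,
                             region.region_id, float(target))
        )
    planted = {pid for r in truth.delta_regions + truth.mu_regions for pid in r.probe_ids}
    truth.null_probes = set(manifest["probe_id"]) - planted
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# methylation matrix


@dataclass
class MethylationDataset:
    """Aligned M-value matrix (probes x samples) with manifest and sample sheet."""

    values: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame


def generate_methylation(manifest: pd.DataFrame, samples: pd.DataFrame,
                         truth: GroundTruth, design: CohortDesign) -> MethylationDataset:
    """M-value matrix under the additive signal model (see module docstring)."""
    design.validate()
    probe_index = {pid: i for i, pid in enumerate(manifest["probe_id"])}
    for r in truth.delta_regions + truth.mu_regions:
        for pid in r.probe_ids:
            if pid not in probe_index:
                raise KeyError(f"planted probe {pid} not in manifest")

    rng = _rng(design.seed, 4)
    n_probes, n_samples = len(manifest), len(samples)

    baseline = rng.normal(0.0, 1.5, size=n_probes)
    coef_age = rng.normal(0.0, 0.004, size=n_probes)
    coef_sex = rng.normal(0.0, 0.05, size=n_probes)
    coef_platform = rng.normal(0.0, 0.05, size=n_probes)
    coef_cells = rng.normal(0.0, 0.4, size=(n_probes, len(CELL_TYPES)))

    age = samples["age"].to_numpy(dtype=float)
    female = (samples["sex"] == "F").to_numpy(dtype=float)
    epic = (samples["platform"] == "EPIC").to_numpy(dtype=float)
    cells = samples[list(CELL_TYPES)].to_numpy(dtype=float)
    # centre cell proportions on the prior mean so the baseline stays interpretable
    cells = cells - _DEFAULT_CELL_ALPHA / _DEFAULT_CELL_ALPHA.sum()

    M = (
        baseline[:, None]
        + coef_age[:, None] * (age - age.mean())[None, :]
        + coef_sex[:, None] * female[None, :]
        + coef_platform[:, None] * epic[None, :]
        + coef_cells @ cells.T
    )

    # per-probe subject random intercepts (matching the per-probe mixed model)
    subj_codes, subj_uniques = pd.factorize(samples["subject_id"])
    subj_effect = rng.normal(0.0, design.subject_sd, size=(n_probes, len(subj_uniques)))
    M += subj_effect[:, subj_codes]

    is_post = (samples["visit"] == "post").to_numpy(dtype=float)
    group = samples["group"].to_numpy()
    for r in truth.delta_regions:
        ridx = [probe_index[pid] for pid in r.probe_ids]
        slope = np.array([r.effects.get(g, 0.0) for g in group])
        M[np.ix_(ridx, range(n_samples))] += (slope * is_post)[None, :]
    for r in truth.mu_regions:
        ridx = [probe_index[pid] for pid in r.probe_ids]
        offset = np.array([r.effects.get(g, 0.0) for g in group])
        M[np.ix_(ridx, range(n_samples))] += offset[None, :]

    # spatially correlated noise within clusters
    for _, sub in manifest.groupby("cluster", sort=True):
        idx = sub.index.to_numpy()
        k = len(idx)
        eps = rng.standard_normal((k, n_samples))
        if k > 1 and np.isfinite(design.spatial_decay):
            d = np.abs(sub["pos"].to_numpy()[:, None] - sub["pos"].to_numpy()[None, :])
            cov = np.exp(-design.spatial_decay * d)
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(k))
            eps = L @ eps
        M[idx, :] += design.spatial_sd * eps

    M += rng.normal(0.0, design.residual_sd, size=(n_probes, n_samples))

    values = pd.DataFrame(M, index=pd.Index(manifest["probe_id"], name="probe_id"),
                          columns=samples.index)
    return MethylationDataset(values=values, manifest=manifest.copy(), samples=samples.copy())


# ---------------------------------------------------------------------------
# linked omics


@dataclass
class ExpressionData:
    values: pd.DataFrame  # genes x subjects (post visit)
    tss: pd.DataFrame  # gene_id, chrom, tss


@dataclass
class MetaboliteData:
    values: pd.DataFrame  # metabolites x samples (both visits)
    panels: pd.Series  # metabolite -> panel


def _regional_signal(methylation: MethylationDataset, region: PlantedRegion,
                     mode: str) -> pd.Series:
    """Standardised per-subject regional summary (mean over probes of delta or mean)."""
    vals = methylation.values.loc[region.probe_ids]
    samples = methylation.samples
    pre_ids = samples.index[samples["visit"] == "pre"]
    post_ids = samples.index[samples["visit"] == "post"]
    pre = vals[pre_ids].mean(axis=0)
    post = vals[post_ids].mean(axis=0)
    pre.index = samples.loc[pre_ids, "subject_id"]
    post.index = samples.loc[post_ids, "subject_id"]
    sig = post - pre if mode == "delta" else (post + pre) / 2.0
    return (sig - sig.mean()) / sig.std(ddof=1)


def generate_linked_omics(truth: GroundTruth, samples: pd.DataFrame,
                          methylation: MethylationDataset, seed: int = 0, *,
                          n_genes: int = 40, n_mets_per_panel: dict | None = None,
                          expression_subjects=None, metabolite_subjects=None):
    """Expression (post visit) and metabolite (both visits) matrices.

    Linked features follow their planted region's subject-level contrast
    (delta signal for delta regions, pre/post average for mu regions) at the
    stated target Spearman correlation / standardised beta; all other
    features are pure noise.  Targets are hit on the Pearson scale via the
    bivariate-normal identity r = 2 sin(pi * rho_s / 6).
    """
    rng = _rng(seed, 5)
    n_mets_per_panel = n_mets_per_panel or {"HILIC": 15, "Lipid": 30, "GCTOF": 15}
    subjects = list(pd.unique(samples["subject_id"]))
    expr_subjects = list(expression_subjects) if expression_subjects is not None else subjects
    met_subjects = list(metabolite_subjects) if metabolite_subjects is not None else subjects

    # --- expression ---
    gene_rows, tss_rows = [], []
    linked_by_gene = {g.gene_id: g for g in truth.linked_genes}
    chroms = methylation.manifest["chrom"].unique()
    gene_ids = list(linked_by_gene) + [f"GN{i:04d}" for i in range(n_genes - len(linked_by_gene))]
    for gid in gene_ids:
        if gid in linked_by_gene:
            link = linked_by_gene[gid]
            region = truth.region(link.region_id)
            mode = "delta" if any(r.region_id == link.region_id for r in truth.delta_regions) else "mean"
            s = _regional_signal(methylation, region, mode).reindex(expr_subjects)
            if not -1.0 < link.target_spearman < 1.0:
                raise ValidationError("target correlation must be in (-1, 1)")
            r = 2.0 * np.sin(np.pi * link.target_spearman / 6.0)
            noise = rng.standard_normal(len(expr_subjects))
            expr = r * s.to_numpy() + np.sqrt(max(1.0 - r * r, 0.0)) * noise
            tss_rows.append({"gene_id": gid, "chrom": link.chrom, "tss": link.tss})
        else:
            expr = rng.standard_normal(len(expr_subjects))
            man = methylation.manifest
            chrom = str(rng.choice(chroms))
            span = man.loc[man["chrom"] == chrom, "pos"]
            tss = int(rng.integers(max(int(span.min()) - 100_000, 1),
                                   int(span.max()) + 100_000))
            tss_rows.append({"gene_id": gid, "chrom": chrom, "tss": tss})
        gene_rows.append(8.0 + 2.0 * expr)
    expression = ExpressionData(
        values=pd.DataFrame(gene_rows, index=pd.Index(gene_ids, name="gene_id"),
                            columns=expr_subjects),
        tss=pd.DataFrame(tss_rows),
    )

    # --- metabolites ---
    met_sample_ids = [sid for sid in samples.index
                      if samples.loc[sid, "subject_id"] in set(met_subjects)]
    met_samples = samples.loc[met_sample_ids]
    linked_by_met = {m.met_id: m for m in truth.linked_metabolites}
    met_ids, panels = [], []
    for panel, count in n_mets_per_panel.items():
        linked_here = [m for m in truth.linked_metabolites if m.panel == panel]
        met_ids += [m.met_id for m in linked_here]
        panels += [panel] * len(linked_here)
        extra = max(count - len(linked_here), 0)
        met_ids += [f"{panel}_{i:03d}" for i in range(extra)]
        panels += [panel] * extra

    pre_ids = met_samples.index[met_samples["visit"] == "pre"]
    post_ids = met_samples.index[met_samples["visit"] == "post"]
    pre_subj = met_samples.loc[pre_ids, "subject_id"]
    post_subj = met_samples.loc[post_ids, "subject_id"]
    rows = []
    for mid in met_ids:
        base = pd.Series(100.0 + rng.standard_normal(len(pre_ids)), index=pre_subj)
        if mid in linked_by_met:
            link = linked_by_met[mid]
            if not -1.0 < link.target_beta < 1.0:
                raise ValidationError("target beta must be in (-1, 1)")
            region = truth.region(link.region_id)
            d = _regional_signal(methylation, region, "delta").reindex(base.index)
            b = link.target_beta
            delta = b * d.to_numpy() + np.sqrt(1.0 - b * b) * rng.standard_normal(len(base))
        else:
            delta = rng.standard_normal(len(base))
        post_level = base + pd.Series(delta, index=base.index)
        row = pd.Series(index=met_samples.index, dtype=float)
        row.loc[pre_ids] = base.to_numpy()
        row.loc[post_ids] = post_level.reindex(post_subj).to_numpy()
        rows.append(row)
    metabolites = MetaboliteData(
        values=pd.DataFrame(rows, index=pd.Index(met_ids, name="metabolite_id")),
        panels=pd.Series(panels, index=met_ids, name="panel"),
    )
    return expression, metabolites


def truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serialisable view of a ground-truth record."""
    return {
        "delta_regions": [asdict(r) for r in truth.delta_regions],
        "mu_regions": [asdict(r) for r in truth.mu_regions],
        "linked_genes": [asdict(g) for g in truth.linked_genes],
        "linked_metabolites": [asdict(m) for m in truth.linked_metabolites],
        "null_probes": sorted(truth.null_probes),
    }


def truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        delta_regions=[PlantedRegion(**r) for r in d.get("delta_regions", [])],
        mu_regions=[PlantedRegion(**r) for r in d.get("mu_regions", [])],
        linked_genes=[LinkedGene(**g) for g in d.get("linked_genes", [])],
        linked_metabolites=[LinkedMetabolite(**m) for m in d.get("linked_metabolites", [])],
        null_probes=set(d.get("null_probes", [])),
    )
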