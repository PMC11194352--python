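import warnings

import pandas as pd
import pytest

from longmeth.simulate import (
    CohortDesign,
    GroundTruth,
    generate_manifest,
    generate_methylation,
    generate_samples,
    plant_ground_truth,
)


@pytest.fixture(scope="session")
def default_design():
    return CohortDesign(seed=5)


@pytest.fixture(scope="session")
def small_manifest():
    return generate_manifest(n_chrom=1, clusters_per_chrom=4,
                             probes_per_cluster_range=(6, 8), seed=5)


@pytest.fixture(scope="session")
def samples(default_design):
    return generate_samples(default_design)


@pytest.fixture(scope="session")
def planted_cohort(default_design, small_manifest, samples):
    """Small cohort with one planted delta region and one planted mu region."""
    truth = plant_ground_truth(
        small_manifest, seed=5, n_delta_regions=1, n_mu_regions=1,
        min_region_probes=6,
        delta_slopes={"reverter": 0.06, "progressor": 0.0, "maintainer": -0.08},
        mu_offsets={"maintainer": 0.0, "reverter": 0.37, "progressor": 0.46},
    )
    dataset = generate_methylation(small_manifest, samples, truth, default_design)
    return dataset, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Medium cohort with no planted effects (null simulation)."""
    design = CohortDesign(seed=17)
    man = generate_manifest(n_chrom=2, clusters_per_chrom=20, seed=17)
    s = generate_samples(design)
    truth = GroundTruth(null_probes=set(man["probe_id"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = generate_methylation(man, s, truth, design)
    return ds


@pytest.fixture()
def toy_manifest():
    """Hand-built manifest exercising every probe-filter rule."""
    return pd.DataFrame({
        "probe_id": ["a", "b", "c", "d"],
        "chrom": ["chr1", "chr1", "chr1", "chrX"],
        "pos": [100, 200, 300, 400],
        "autosomal": [True, True, True, False],
        "near_snp": [False, False, True, False],
        "beta_range_450k": [0.02, 0.02, 0.40, 0.50],
        "beta_range_epic": [0.05, 0.02, 0.40, 0.50],
    })
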