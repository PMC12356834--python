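import numpy as np
import pytest

from rareburden import (
    read_annotations,
    read_samples,
    read_vcf,
)
from rareburden.synthetic import (
    ArtifactSpec,
    RiskGeneSpec,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config():
    """Two-cohort desk-scale study with one spiked risk gene, a pinch of
    multi-allelic sites and two injected duplicate samples."""
    return SimulationConfig(
        seed=42,
        strata_spec=[("SG", 120, 140), ("HK", 120, 140)],
        n_genes=40,
        n_common_variants=400,
        risk_genes=[RiskGeneSpec("RISKA", control_carrier_freq=0.02,
                                 odds_ratio=3.0)],
        multiallelic_frac=0.05,
        n_duplicate_samples=2,
        artifact_spec=ArtifactSpec(base_missingness=0.003),
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    paths = simulate_study(small_config, str(out))
    variants, gm = read_vcf(paths["vcf"])
    samples = read_samples(paths["samples"])
    annotations = read_annotations(paths["annotations"],
                                   set(gm.variant_ids))
    return {
        "paths": paths,
        "variants": variants,
        "gm": gm,
        "samples": samples,
        "annotations": annotations,
        "config": small_config,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
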