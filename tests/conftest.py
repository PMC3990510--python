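import numpy as np
import pytest

from gxediet.harmonize import harmonize_study
from gxediet.synthetic import default_consortium, generate_consortium
from gxediet.types import GeneratorConfig, StudySpec


@pytest.fixture(scope="session")
def small_consortium():
    """Ten-study consortium at 40% scale with the planted interaction."""
    cfg = default_consortium(n_snps=44, seed=20_240_301, scale=0.4)
    return cfg, generate_consortium(cfg)


@pytest.fixture(scope="session")
def harmonized_consortium(small_consortium):
    cfg, studies = small_consortium
    for ds, _ in studies:
        harmonize_study(ds)
    return cfg, studies


@pytest.fixture(scope="session")
def null_pair():
    """Two null studies (no planted effects), modest size, 30 SNPs."""
    specs = [
        StudySpec(
            f"null_{i}", 400, 400,
            exposure_means={"processed_meat": 0.55},
            exposure_sds={"processed_meat": 0.4},
        )
        for i in range(2)
    ]
    cfg = GeneratorConfig(
        studies=specs, exposures=("processed_meat",), n_snps=30,
        imputed_fraction=0.25, seed=77,
    )
    studies = generate_consortium(cfg)
    for ds, _ in studies:
        harmonize_study(ds)
    return cfg, studies


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
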