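import numpy as np
import pytest

from pleioscan.pipeline import run_pipeline, simulate_bundle
from pleioscan.simulate import default_config


@pytest.fixture(scope="session")
def default_fixture():
    """The default 6-disease / 3,000-SNP / 60-gene study with planted genes."""
    cfg = default_config(seed=0)
    bundle, truth = simulate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def pipeline_results(default_fixture):
    """Full pipeline run on the default fixture (computed once per session)."""
    cfg, bundle, _ = default_fixture
    return run_pipeline(bundle, seed=0,
                        excluded_region=cfg.mhc_like_region)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
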