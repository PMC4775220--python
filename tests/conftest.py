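import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ripcall as rc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_model():
    return rc.make_genome_model(5, 100_000, seed=7)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the default study conditions.

    2 RIP + 2 IgG replicates, 20 planted sites of width 600 at 8x
    enrichment on a 40-gene chromosome; shared by the end-to-end tests.
    """
    from ripcall.pipeline import PipelineConfig, SimulateConfig, run_pipeline

    cfg = PipelineConfig(seed=42)
    cfg.simulate = SimulateConfig()
    return run_pipeline(cfg, tmp_path_factory.mktemp("default_run"))


def gaussian_bump_track(length, centers, height=50.0, sd=300.0, baseline=0.0):
    x = np.arange(length, dtype=float)
    cov = np.full(length, baseline)
    for c in centers:
        cov += height * np.exp(-((x - c) ** 2) / (2 * sd**2))
    return cov
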