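"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# single-CPU runs: first-call imports can blow the default 200ms deadline
settings.register_profile(
    "cystodx", deadline=None, suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("cystodx")

from cystodx.config import RunConfig
from cystodx.fixtures import FixtureConfig, generate_dataset

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def dataset_manifest(fixture_dir):
    """Desk-scale study set: 100 images/class, 10% exposure outliers."""
    cfg = FixtureConfig(n_per_class=100, outlier_fraction=0.1, seed=PIPELINE_SEED)
    return generate_dataset(cfg, fixture_dir / "main")


@pytest.fixture(scope="session")
def small_manifest(fixture_dir):
    """Small clean set for fast unit-level training checks."""
    cfg = FixtureConfig(n_per_class=30, outlier_fraction=0.0, seed=3)
    return generate_dataset(cfg, fixture_dir / "small")


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def pipeline_result(dataset_manifest, run_config, tmp_path_factory):
    """The full pipeline (rejection -> three branches -> vote -> metrics),
    trained once and shared by the end-to-end and saliency tests."""
    from cystodx.pipeline import run_all

    out = tmp_path_factory.mktemp("pipeline")
    return run_all(run_config, out, manifest=dataset_manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
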