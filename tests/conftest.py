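"""Shared fixtures: small phantom, jaw model, and one full pipeline run.

The expensive artifacts (the phantom mesh, the jaw model, and a complete
pipeline run with a sensitivity variant) are session-scoped and shared by
the FE, aggregation and pipeline tests.
"""

import numpy as np
import pytest

from craniostrain.fe_solver import MaterialTable
from craniostrain.jaw_mda import make_jaw_model
from craniostrain.phantom_geometry import PhantomParams, make_cranium_phantom
from craniostrain.pipeline_cli import RunConfig, run_pipeline


SMALL_PARAMS = dict(n_cheek_teeth=2, height=14.0)


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(**SMALL_PARAMS)


@pytest.fixture(scope="session")
def phantom_small(small_params):
    return make_cranium_phantom(small_params)


@pytest.fixture(scope="session")
def phantom_default():
    return make_cranium_phantom(PhantomParams())


@pytest.fixture(scope="session")
def jaw_model_default():
    return make_jaw_model(PhantomParams())


@pytest.fixture(scope="session")
def jaw_model_small(small_params):
    return make_jaw_model(small_params)


@pytest.fixture(scope="session")
def materials():
    return MaterialTable()


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, small_params):
    """One full pipeline run (6 regimes) with the soft-tissue sensitivity
    variant, on the small two-cheek-tooth phantom."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(
        phantom=small_params,
        sensitivity={"multipliers": {"pdl": 0.1, "suture": 0.1}, "near_distance": 4.0},
        output_dir=str(out),
    )
    report = run_pipeline(cfg)
    return cfg, report


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
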