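import pytest

import mortlag as ml
from mortlag.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def expected_surfaces():
    """Default 4-country scenario, expected-count mode, with planted truth."""
    scenario = ml.default_scenario(seed=0)
    mortality, cause, truth = ml.generate_surface(scenario, mode="expected")
    return scenario, mortality, cause, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full expected-mode pipeline run shared across tests."""
    base = tmp_path_factory.mktemp("pipeline")
    scenario = ml.default_scenario(seed=0)
    scenario.to_yaml(base / "scenario.yaml")
    cfg = RunConfig(scenario=str(base / "scenario.yaml"),
                    outdir=str(base / "out"), seed=0)
    return cfg, run_pipeline(cfg)
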