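"""Session fixtures: one moderately sized cohort with generating effects,
run through the full pipeline once and reused across test modules."""

from __future__ import annotations

from dataclasses import replace

import pytest

from pseudom6a import SimulationConfig, generate_cohort, run_pipeline

#: study-scale cohort used by the directional tests: cohort size near the
#: 223-pair study, population size scaled to keep the suite fast
SESSION_CFG = SimulationConfig(n_pairs=200, n_samples=200, seed=11)


@pytest.fixture(scope="session")
def cohort_cfg() -> SimulationConfig:
    return replace(SESSION_CFG)


@pytest.fixture(scope="session")
def cohort(cohort_cfg):
    return generate_cohort(replace(cohort_cfg))


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("pipeline_run")


@pytest.fixture(scope="session")
def report(cohort_cfg, run_dir):
    return run_pipeline(replace(cohort_cfg), run_dir)
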