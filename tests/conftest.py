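"""Shared fixtures: the default synthetic dataset and one pipeline run.

Both are session-scoped; nearly every integration test reads from them
instead of regenerating, which keeps the suite fast and the study
conditions identical everywhere.
"""

import pytest

from circheart.pipeline import PipelineParams, run_stages
from circheart.simulate import SimConfig, make_fixture


@pytest.fixture(scope="session")
def fix():
    """Default synthetic fixture (seed 1): genome, truth tables, reads."""
    return make_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def result(fix):
    """Full pipeline run on the default fixture."""
    return run_stages(fix.genome, fix.reads, fix.config.groups,
                      fix.truth.mirnas, fix.truth.mirna_targets,
                      PipelineParams(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(fix, tmp_path_factory):
    """The fixture written to disk once."""
    from circheart.simulate import write_fixture
    d = tmp_path_factory.mktemp("fixture")
    return write_fixture(fix, d)
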