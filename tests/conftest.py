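import pytest

from pedcnvseg.fixture import (
    build_fixture,
    gene_models,
    literature_regions,
)
from pedcnvseg.pipeline import run_pipeline


@pytest.fixture(scope="session")
def fixture_data():
    return build_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_data):
    return run_pipeline(
        fixture_data.peds,
        fixture_data.calls,
        fixture_data.qc_metrics,
        fixture_data.control_table,
        fixture_data.dgv_table,
        fixture_data.config,
        literature_regions(),
        gene_models(),
    )
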