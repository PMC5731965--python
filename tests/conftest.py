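import pytest

from genemeta import AnalysisConfig, load_bundled_table2, run_analysis


@pytest.fixture(scope="session")
def table2():
    """The packaged 12-study ALDH2 rs671 / gastric-cancer collection."""
    return load_bundled_table2()


@pytest.fixture(scope="session")
def full_analysis(table2):
    """Full five-model analysis with country and control-source subgroups."""
    config = AnalysisConfig(group_by=("country", "control_source"))
    return run_analysis(table2, config)
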