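import pytest

from spliceframe.model import FilterConfig
from spliceframe.pipeline import PipelineConfig, run_pipeline
from spliceframe.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_small(tmp_path_factory):
    """Compact planted dataset: 4 events per type plus filter-fail cases."""
    out = tmp_path_factory.mktemp("fixture_small")
    return generate_fixture(FixtureSpec(seed=20, events_per_type=4), out)


@pytest.fixture(scope="session")
def fixture_full(tmp_path_factory):
    """Full planted dataset: 60 events covering all six types, both strands."""
    out = tmp_path_factory.mktemp("fixture_full")
    return generate_fixture(FixtureSpec(seed=7, events_per_type=10), out)


def _run(fixture, out_dir, **kwargs):
    config = PipelineConfig(
        events=fixture.paths["events"],
        counts=fixture.paths["counts"],
        genome=fixture.paths["genome"],
        annotation=fixture.paths["annotation"],
        proteins=fixture.paths["proteins"],
        domains=fixture.paths["domains"],
        out_dir=out_dir,
        filters=FilterConfig(),
        **kwargs,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def pipeline_small(fixture_small, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_small")
    return _run(fixture_small, out, translate_all=True, figures_top=2)


@pytest.fixture(scope="session")
def pipeline_full(fixture_full, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_full")
    return _run(fixture_full, out, translate_all=True)


@pytest.fixture()
def run_fixture_pipeline():
    return _run
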