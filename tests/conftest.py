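import pathlib

import pytest

from geoweave import pipeline
from geoweave.fixtures import SyntheticConfig, generate, write_bundle
from geoweave.rdf_core import parse_ntriples


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle, seed 1."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """One full uplift→enrich→downlift run over the session bundle."""
    out = tmp_path_factory.mktemp("run")
    stats = pipeline.run_all(bundle_dir, out)
    return out, stats


@pytest.fixture(scope="session")
def enriched_graph(pipeline_run):
    out, _ = pipeline_run
    return parse_ntriples((out / "graph_enriched.nt").read_text(encoding="utf-8"))
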