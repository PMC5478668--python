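import pytest

from fadskit.fa import PathwayGraph, default_pathway_graph, parse_fa_shorthand


@pytest.fixture(scope="session")
def graph():
    return default_pathway_graph()


@pytest.fixture(scope="session")
def c24_route():
    """The linear yeast C24 assay route: 22:5n-3 -> 24:5n-3 -> 24:6n-3."""
    g = PathwayGraph()
    g.add_edge(parse_fa_shorthand("22:5n-3"), parse_fa_shorthand("24:5n-3"))
    g.add_edge(parse_fa_shorthand("24:5n-3"), parse_fa_shorthand("24:6n-3"))
    return g


@pytest.fixture
def fa():
    return parse_fa_shorthand
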