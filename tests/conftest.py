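import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def diamond_ontology() -> nx.DiGraph:
    """Hand-built 6-term DAG (edges child->parent).

        R           level 0 (root)
       / \\
      A   B         level 1
       \\ / \\
        C   E       level 2  (C has parents A and B: a diamond)
        |
        D           level 3
    """
    g = nx.DiGraph()
    for term, level in [("R", 0), ("A", 1), ("B", 1), ("C", 2), ("E", 2), ("D", 3)]:
        g.add_node(term, name=f"term {term}", level=level)
    g.add_edges_from([("A", "R"), ("B", "R"), ("C", "A"), ("C", "B"), ("E", "B"), ("D", "C")])
    return g


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One shared demo pipeline run for tests that inspect its outputs."""
    from acidscreen import demo

    out = tmp_path_factory.mktemp("demo") / "run"
    return demo(seed=11, out_dir=out)
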