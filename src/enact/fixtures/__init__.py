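"""Named benchmark graphs shipped as diffable edge-list files.

* ``two-cell``: two vertices, single edge 1->2 (the minimal feed-forward
  system used for fold analysis).
* ``three-cycle``: the cyclic graph 1->2->3->1 (SNIC benchmark).
* ``kirk-silber``: four vertices with one branching vertex (2 -> 3 and
  2 -> 4), the canonical test for input-selected branching and
  double-activation states.
* ``ten-node``: a fixed randomly generated admissible, strongly connected
  ten-vertex graph (regenerable with :func:`ten_node_graph`).
"""

from importlib import resources

from ..graphs import DiGraph, random_admissible_graph, _parse_edge_list

__all__ = ["fixture_graph", "fixture_names", "ten_node_graph", "TEN_NODE_SEED", "TEN_NODE_EDGE_PROB"]

#: generator settings used to produce the shipped ten-node fixture
TEN_NODE_SEED = 2023
TEN_NODE_EDGE_PROB = 0.2

_FILES = {
    "two-cell": "two_cell.tsv",
    "three-cycle": "three_cycle.tsv",
    "kirk-silber": "kirk_silber.tsv",
    "ten-node": "ten_node.tsv",
}


def fixture_names() -> list[str]:
    return sorted(_FILES)


def fixture_graph(name: str) -> DiGraph:
    """Load one of the named fixture graphs."""
    key = name.replace("_", "-").lower()
    if key not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {fixture_names()}")
    text = resources.files(__package__).joinpath(_FILES[key]).read_text()
    return _parse_edge_list(text, f"fixture:{key}")


def ten_node_graph() -> DiGraph:
    """Regenerate the ten-node fixture from its recorded generator settings."""
    return random_admissible_graph(
        10, TEN_NODE_EDGE_PROB, seed=TEN_NODE_SEED, require_no_sink_subgraph=True
    )
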