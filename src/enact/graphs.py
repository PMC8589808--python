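"""Directed graphs and the admissibility conditions of the construction.

A directed graph ``G`` on ``n`` vertices is *admissible* for realisation as an
excitable network attractor when it contains

* no one-loops  (``a_ii = 0`` for all ``i``),
* no two-loops  (``a_ij * a_ji = 0`` for all ``i, j``), and
* no Delta-cliques (``a_ij * a_ik * a_jk = 0`` for all ``i, j, k``),

where ``a`` is the binary adjacency matrix with ``a_ij = 1`` meaning a directed
edge from vertex ``i`` to vertex ``j``.  Vertices are labelled ``1..n`` in all
reports and file formats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DiGraph",
    "ViolationReport",
    "GraphFormatError",
    "GenerationFailure",
    "validate_graph",
    "random_admissible_graph",
    "load_graph",
    "save_graph",
]

#: rejection-sampling budget for random_admissible_graph
GENERATION_BUDGET = 10_000


class GraphFormatError(ValueError):
    """Malformed graph input (file or adjacency array)."""


class GenerationFailure(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class DiGraph:
    """A directed graph held as a binary adjacency matrix.

    ``adjacency[i-1, j-1] == 1`` iff there is an edge ``i -> j`` (1-based
    vertex labels).
    """

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] == 0:
            raise GraphFormatError(f"adjacency must be square and non-empty, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise GraphFormatError("adjacency entries must be exactly 0 or 1")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as 1-based (source, destination) pairs."""
        return [(int(i) + 1, int(j) + 1) for i, j in zip(*np.nonzero(self.adjacency))]

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i - 1, j - 1])

    def out_degree(self, k: int) -> int:
        """Number of outgoing edges of vertex ``k`` (1-based)."""
        return int(self.adjacency[k - 1].sum())

    def in_degree(self, k: int) -> int:
        return int(self.adjacency[:, k - 1].sum())

    def successors(self, k: int) -> list[int]:
        return [int(j) + 1 for j in np.nonzero(self.adjacency[k - 1])[0]]

    def predecessors(self, k: int) -> list[int]:
        return [int(i) + 1 for i in np.nonzero(self.adjacency[:, k - 1])[0]]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(1, self.n + 1))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(cls, n: int, edges) -> "DiGraph":
        a = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            if not (1 <= i <= n and 1 <= j <= n):
                raise GraphFormatError(f"edge ({i},{j}) outside vertex range 1..{n}")
            a[i - 1, j - 1] = 1
        return cls(a)


@dataclass(frozen=True)
class ViolationReport:
    """Certificate of every admissibility violation found in a graph."""

    one_loops: list[int] = field(default_factory=list)
    two_loops: list[frozenset[int]] = field(default_factory=list)
    delta_cliques: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def admissible(self) -> bool:
        return not (self.one_loops or self.two_loops or self.delta_cliques)


def validate_graph(graph: DiGraph) -> ViolationReport:
    """Check the three admissibility conditions, listing every violation.

    One-loops are reported as vertices, two-loops as unordered pairs, and
    Delta-cliques as ordered triples ``(i, j, k)`` with edges ``i->j``,
    ``i->k`` and ``j->k``; triples are not collapsed under relabelling, so
    the report is a direct certificate.
    """
    a = graph.adjacency
    n = graph.n
    one_loops = [int(i) + 1 for i in np.nonzero(np.diag(a))[0]]
    two_loops = [
        frozenset((i + 1, j + 1))
        for i in range(n)
        for j in range(i + 1, n)
        if a[i, j] and a[j, i]
    ]
    delta_cliques = [
        (i + 1, j + 1, k + 1)
        for i, j, k in itertools.product(range(n), repeat=3)
        if a[i, j] and a[i, k] and a[j, k]
    ]
    return ViolationReport(one_loops, two_loops, delta_cliques)


def _is_admissible_fast(a: np.ndarray) -> bool:
    # vectorised yes/no check used inside rejection sampling
    if np.diag(a).any():
        return False
    if (a & a.T).any():
        return False
    # Delta-clique exists iff some i->k edge has a length-2 path i->j->k
    return not ((a.astype(np.int32) @ a) * a).any()


def random_admissible_graph(
    n: int,
    edge_prob: float,
    seed: int,
    require_no_sink_subgraph: bool = False,
) -> DiGraph:
    """Rejection-sample an admissible random digraph.

    Each attempt draws every ordered pair ``i != j`` independently with
    probability ``edge_prob`` and discards the sample if it violates
    admissibility.  When ``require_no_sink_subgraph`` is set (a walk must
    never get stuck in a subgraph, read here as strong connectivity), each
    attempt is instead seeded with a uniformly random Hamiltonian cycle --
    itself admissible and strongly connected for ``n >= 3`` -- and the extra
    pairs are drawn independently as before; admissibility of the combined
    graph is still re-checked and violating samples discarded.  At admissible
    edge densities an unconstrained sparse digraph essentially never has
    every vertex reachable from every other, so conditioning by rejection
    alone is not viable.  Deterministic for a fixed ``seed``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not 0 < edge_prob <= 1:
        raise ValueError(f"edge_prob must lie in (0,1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    off_diag = ~np.eye(n, dtype=bool)
    for _ in range(GENERATION_BUDGET):
        a = ((rng.random((n, n)) < edge_prob) & off_diag).astype(np.int8)
        if require_no_sink_subgraph:
            perm = rng.permutation(n)
            a[perm, np.roll(perm, -1)] = 1
        if not _is_admissible_fast(a):
            continue
        g = DiGraph(a)
        if require_no_sink_subgraph and not nx.is_strongly_connected(g.to_networkx()):
            continue
        return g
    raise GenerationFailure(
        f"no admissible graph found in {GENERATION_BUDGET} attempts "
        f"(n={n}, edge_prob={edge_prob}); the request is too dense or too sparse"
    )


# ---------------------------------------------------------------------------
# I/O: edge-list TSV, adjacency CSV, DOT


def _parse_edge_list(text: str, path: str) -> DiGraph:
    edges = []
    n_declared = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            # optional "# n=<count>" directive preserves trailing isolated vertices
            if line.replace(" ", "").startswith("#n="):
                n_declared = int(line.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphFormatError(f"{path}:{lineno}: expected 'src<TAB>dst', got {line!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{lineno}: non-integer vertex label") from exc
        if i < 1 or j < 1:
            raise GraphFormatError(f"{path}:{lineno}: vertex labels must be 1-based positive")
        edges.append((i, j))
    if not edges:
        raise GraphFormatError(f"{path}: no edges found (empty graph cannot be inferred)")
    n = max(max(i, j) for i, j in edges)
    if n_declared is not None:
        if n_declared < n:
            raise GraphFormatError(f"{path}: declared n={n_declared} smaller than largest label {n}")
        n = n_declared
    return DiGraph.from_edges(n, edges)


def _parse_adjacency_csv(text: str, path: str) -> DiGraph:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([int(tok) for tok in line.split(",")])
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{lineno}: non-integer adjacency entry") from exc
    if not rows:
        raise GraphFormatError(f"{path}: empty adjacency file")
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise GraphFormatError(f"{path}: adjacency must be square ({n} rows)")
    return DiGraph(np.array(rows))


def _parse_dot(text: str, path: str) -> DiGraph:
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip().rstrip(";")
        if "->" not in line:
            continue
        lhs, rhs = line.split("->", 1)
        rhs = rhs.split("[", 1)[0]
        try:
            edges.append((int(lhs.strip()), int(rhs.strip())))
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{lineno}: could not parse DOT edge {line!r}") from exc
    if not edges:
        raise GraphFormatError(f"{path}: no edges found in DOT source")
    n = max(max(i, j) for i, j in edges)
    return DiGraph.from_edges(n, edges)


_PARSERS = {
    "edge-list": _parse_edge_list,
    "adjacency-csv": _parse_adjacency_csv,
    "dot": _parse_dot,
}

_SUFFIX_FORMATS = {".tsv": "edge-list", ".txt": "edge-list", ".csv": "adjacency-csv", ".dot": "dot"}


def load_graph(path, format: str | None = None) -> DiGraph:
    """Load a graph from edge-list TSV, adjacency CSV, or DOT.

    When ``format`` is omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMATS.get(path.suffix)
        if format is None:
            raise GraphFormatError(f"cannot infer format from suffix of {path}")
    if format not in _PARSERS:
        raise GraphFormatError(f"unknown format {format!r}; choose from {sorted(_PARSERS)}")
    return _PARSERS[format](path.read_text(), str(path))


def save_graph(graph: DiGraph, path, format: str | None = None) -> None:
    """Write a graph; the write/load round trip is the identity on adjacency."""
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMATS.get(path.suffix)
        if format is None:
            raise GraphFormatError(f"cannot infer format from suffix of {path}")
    if format == "edge-list":
        text = f"# n={graph.n}\n" + "".join(f"{i}\t{j}\n" for i, j in graph.edges())
    elif format == "adjacency-csv":
        text = "".join(",".join(str(int(v)) for v in row) + "\n" for row in graph.adjacency)
    elif format == "dot":
        lines = ["digraph G {"]
        lines += [f"  {k};" for k in range(1, graph.n + 1)]
        lines += [f"  {i} -> {j};" for i, j in graph.edges()]
        lines.append("}")
        text = "\n".join(lines) + "\n"
    else:
        raise GraphFormatError(f"unknown format {format!r}")
    path.write_text(text)
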