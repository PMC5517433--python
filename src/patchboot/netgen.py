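"""Synthetic simple graphs with a prescribed degree sequence.

The generator follows the classical two-stage recipe: the pairing
(configuration) model matches degree stubs uniformly at random, producing a
multigraph, and a degree-preserving rewiring stage removes self-loops and
parallel edges with double-edge swaps.  The resulting graph has *exactly* the
prescribed degree sequence.  Edge lists are read and written as plain text,
one ``u v`` pair per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SimpleGraph",
    "pair_stubs",
    "rewire_to_simple",
    "generate_graph",
    "read_edgelist",
    "write_edgelist",
    "RewiringError",
]


class RewiringError(RuntimeError):
    """Raised when the swap budget is exhausted before the graph is simple."""

    def __init__(self, message: str, remaining_defects: int):
        super().__init__(message)
        self.remaining_defects = remaining_defects


@dataclass
class SimpleGraph:
    """Undirected simple graph on dense 0-based vertex labels.

    ``adjacency[v]`` is the set of neighbours of ``v``; the structure is kept
    symmetric and loop-free by construction.  ``labels`` optionally maps the
    internal labels back to external ones (as read from an edge list).
    """

    adjacency: list[set[int]]
    labels: list | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.adjacency)

    @property
    def num_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def neighbors(self, v: int) -> set[int]:
        return self.adjacency[v]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Canonical edges (u, v) with u < v, sorted."""
        for u in range(self.n):
            for v in sorted(self.adjacency[u]):
                if u < v:
                    yield (u, v)

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]], labels=None) -> "SimpleGraph":
        adj: list[set[int]] = [set() for _ in range(n)]
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u} not allowed in a simple graph")
            adj[u].add(v)
            adj[v].add(u)
        return cls(adj, labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g


def pair_stubs(degree_seq: Sequence[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    """Configuration-model stub matching.

    Each vertex ``v`` contributes ``degree_seq[v]`` stubs; a uniformly random
    perfect matching of the stubs yields the edge multiset, which may contain
    self-loops and parallel edges.
    """
    seq = np.asarray(degree_seq, dtype=np.int64)
    if np.any(seq < 0):
        raise ValueError("degrees must be non-negative")
    total = int(seq.sum())
    if total % 2 != 0:
        raise ValueError("sum of degrees must be even for stub pairing")
    stubs = np.repeat(np.arange(seq.size), seq)
    rng.shuffle(stubs)
    return list(zip(stubs[0::2].tolist(), stubs[1::2].tolist()))


def _canon(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


def rewire_to_simple(
    edges: Sequence[tuple[int, int]],
    degree_seq: Sequence[int],
    rng: np.random.Generator,
    max_sweeps: int = 100,
) -> SimpleGraph:
    """Remove loops and parallel edges by degree-preserving double-edge swaps.

    A defective edge (a loop, or any copy of a repeated edge beyond the first)
    is paired with a uniformly chosen partner edge and the endpoints are
    swapped; the swap is accepted only if both replacement edges are new and
    loop-free, so the defect count never increases.  The attempt budget is
    ``max_sweeps * |E|``.
    """
    seq = np.asarray(degree_seq, dtype=np.int64)
    if not nx.is_graphical(seq.tolist()):
        raise ValueError("degree sequence is not graphical (Erdős–Gallai)")
    edge_list = [tuple(e) for e in edges]
    counts: dict[tuple[int, int], int] = {}
    for e in edge_list:
        key = _canon(*e)
        counts[key] = counts.get(key, 0) + 1

    def defect_indices() -> list[int]:
        seen: dict[tuple[int, int], int] = {}
        out = []
        for i, e in enumerate(edge_list):
            key = _canon(*e)
            seen[key] = seen.get(key, 0) + 1
            if key[0] == key[1] or seen[key] > 1:
                out.append(i)
        return out

    defects = defect_indices()
    budget = max_sweeps * max(1, len(edge_list))
    attempts = 0
    while defects:
        if attempts >= budget:
            raise RewiringError(
                f"rewiring did not converge within {budget} attempts; "
                f"{len(defects)} defective edges remain",
                remaining_defects=len(defects),
            )
        attempts += 1
        i = defects[rng.integers(len(defects))]
        j = int(rng.integers(len(edge_list)))
        if i == j:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if rng.integers(2):
            x, y = y, x
        # proposed replacements: (u, x) and (v, y)
        a, b = _canon(u, x), _canon(v, y)
        if u == x or v == y or a == b or counts.get(a, 0) > 0 or counts.get(b, 0) > 0:
            continue
        for key in (_canon(u, v), _canon(x, y)):
            counts[key] -= 1
            if counts[key] == 0:
                del counts[key]
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        edge_list[i] = (u, x)
        edge_list[j] = (v, y)
        defects = defect_indices()

    graph = SimpleGraph.from_edges(seq.size, edge_list)
    if not np.array_equal(graph.degrees, seq):  # pragma: no cover - invariant
        raise AssertionError("rewiring failed to preserve the degree sequence")
    return graph


def generate_graph(model, n: int, rng: np.random.Generator) -> SimpleGraph:
    """Sample a degree sequence from ``model`` and realise it as a simple graph."""
    seq = model.sample_degrees(n, rng, even_sum=True)
    edges = pair_stubs(seq, rng)
    return rewire_to_simple(edges, seq, rng)


def read_edgelist(path) -> SimpleGraph:
    """Read a plain-text edge list (two integer labels per line).

    Blank lines and ``#`` comments are ignored; duplicate and reversed
    duplicate lines collapse to one undirected edge; self-loops are rejected.
    Arbitrary integer labels are mapped to dense 0-based labels, with the
    original labels retained on the returned graph.
    """
    edges: set[tuple[int, int]] = set()
    seen_labels: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two labels, got {text!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label in {text!r}") from exc
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative label in {text!r}")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} not allowed")
            seen_labels.update((u, v))
            edges.add(_canon(u, v))
    labels = sorted(seen_labels)
    index = {lab: i for i, lab in enumerate(labels)}
    mapped = [(index[u], index[v]) for u, v in edges]
    return SimpleGraph.from_edges(len(labels), mapped, labels=labels)


def write_edgelist(graph: SimpleGraph, path, sidecar: bool = False) -> None:
    """Write the canonical edge list (``u v`` per line, u < v, sorted).

    Internal dense labels are written; with ``sidecar=True`` a JSON file with
    order, size and the external-label mapping is placed next to the output.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u} {v}\n")
    if sidecar:
        meta = {"n": graph.n, "num_edges": graph.num_edges}
        if graph.labels is not None:
            meta["labels"] = list(graph.labels)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
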