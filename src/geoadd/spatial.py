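"""Adjacency graphs and the algebra of the spatial priors.

Region effects carry either an intrinsic CAR (Besag / Markov random field)
prior, whose precision is (1/tau2) * (diag(degree) - adjacency), or an
i.i.d. Normal(0, tau2) "unstructured" prior. The ICAR prior is improper
(its precision annihilates the constant vector on each connected component),
so fitted spatial blocks are centred to sum to zero; a disconnected graph is
rejected rather than silently centred per component.

Adjacency files use a plain-text ``.gra`` dialect::

    <number of regions>
    <label of region 0>
    <number of neighbours of region 0>
    <space-separated 0-based neighbour indices>
    ... (repeated per region)

Lines starting with ``#`` are comments and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .design import PenaltyMatrix

__all__ = [
    "AdjacencyGraph",
    "GraParseError",
    "read_gra",
    "write_gra",
    "icar_precision",
]


class GraParseError(ValueError):
    """Raised when a ``.gra`` file violates the documented dialect."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected region adjacency: ordered labels plus neighbour index sets."""

    labels: tuple[str, ...]
    neighbours: tuple[frozenset[int], ...]

    def __post_init__(self):
        n = len(self.labels)
        if len(self.neighbours) != n:
            raise ValueError("labels and neighbour sets differ in length")
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        for i, nbrs in enumerate(self.neighbours):
            for j in nbrs:
                if not 0 <= j < n:
                    raise ValueError(f"region {i} lists out-of-range neighbour {j}")
                if j == i:
                    raise ValueError(f"region {self.labels[i]} lists itself as neighbour")
                if i not in self.neighbours[j]:
                    raise ValueError(
                        "asymmetric adjacency: "
                        f"{self.labels[i]} lists {self.labels[j]} but not vice versa"
                    )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def degree(self) -> np.ndarray:
        return np.array([len(s) for s in self.neighbours], dtype=float)

    def edges(self) -> list[tuple[int, int]]:
        """Each undirected edge once, as (i, j) with i < j."""
        return [(i, j) for i, s in enumerate(self.neighbours) for j in sorted(s) if i < j]

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_regions, self.n_regions))
        for i, j in self.edges():
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.edges())
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def is_connected(self) -> bool:
        return len(self.connected_components()) == 1

    def require_connected(self) -> None:
        comps = self.connected_components()
        if len(comps) > 1:
            names = ["{" + ", ".join(self.labels[i] for i in sorted(c)) + "}" for c in comps]
            raise ValueError(
                f"adjacency graph has {len(comps)} connected components: "
                + ", ".join(names)
            )

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None


def read_gra(path) -> AdjacencyGraph:
    """Parse an adjacency file in the documented ``.gra`` dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()
    lines: list[tuple[int, str]] = []
    for no, line in enumerate(raw, start=1):
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            lines.append((no, stripped))
    if not lines:
        raise GraParseError(f"{path}: empty file")
    pos = 0

    def take(what: str) -> tuple[int, str]:
        nonlocal pos
        if pos >= len(lines):
            last = lines[-1][0]
            raise GraParseError(f"{path}: unexpected end of file after line {last}: expected {what}")
        item = lines[pos]
        pos += 1
        return item

    no, count_line = take("region count")
    try:
        n = int(count_line)
    except ValueError:
        raise GraParseError(f"{path}:{no}: region count is not an integer: {count_line!r}")
    if n <= 0:
        raise GraParseError(f"{path}:{no}: region count must be positive")

    labels: list[str] = []
    neighbours: list[frozenset[int]] = []
    for r in range(n):
        _, label = take(f"label of region {r}")
        no_k, k_line = take(f"neighbour count of region {r}")
        try:
            k = int(k_line)
        except ValueError:
            raise GraParseError(f"{path}:{no_k}: neighbour count is not an integer: {k_line!r}")
        if k < 0:
            raise GraParseError(f"{path}:{no_k}: negative neighbour count")
        if k == 0:
            idx: list[int] = []
        else:
            no_i, idx_line = take(f"neighbour indices of region {r}")
            try:
                idx = [int(tok) for tok in idx_line.split()]
            except ValueError:
                raise GraParseError(f"{path}:{no_i}: non-integer neighbour index: {idx_line!r}")
            if len(idx) != k:
                raise GraParseError(
                    f"{path}:{no_i}: region {label!r} declares {k} neighbours but lists {len(idx)}"
                )
            for j in idx:
                if not 0 <= j < n:
                    raise GraParseError(f"{path}:{no_i}: neighbour index {j} out of range 0..{n - 1}")
        labels.append(label)
        neighbours.append(frozenset(idx))
    if pos != len(lines):
        extra_no = lines[pos][0]
        raise GraParseError(f"{path}:{extra_no}: trailing content after {n} region blocks")
    try:
        return AdjacencyGraph(tuple(labels), tuple(neighbours))
    except ValueError as exc:
        raise GraParseError(f"{path}: {exc}") from exc


def write_gra(graph: AdjacencyGraph, path, header: str | None = None) -> None:
    """Serialize a graph in the ``.gra`` dialect (round-trips with read_gra)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"{graph.n_regions}\n")
        for i, label in enumerate(graph.labels):
            nbrs = sorted(graph.neighbours[i])
            fh.write(f"{label}\n{len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(str(j) for j in nbrs) + "\n")


def icar_precision(graph: AdjacencyGraph) -> PenaltyMatrix:
    """ICAR precision structure K = diag(degree) - adjacency.

    K is symmetric positive semidefinite with rank = n_regions minus the
    number of connected components; its null space is spanned by the
    per-component constant vectors, which is why ICAR blocks are centred.
    """
    k = np.diag(graph.degree()) - graph.adjacency_matrix()
    n_comp = len(graph.connected_components())
    return PenaltyMatrix(matrix=k, rank=graph.n_regions - n_comp, null_space_dim=n_comp)
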