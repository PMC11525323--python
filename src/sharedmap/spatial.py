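"""Adjacency structure and intrinsic-CAR (ICAR) mathematics.

Areal models of the Besag convolution family penalise squared differences
of a latent field across pairs of contiguous areas.  Everything those
models need from the map — who neighbours whom, connected components,
the pairwise-difference quadratic form, the improper Gaussian log density —
lives here.  Contiguity can be built programmatically on a regular lattice
(rook or queen rule) or read from a GAL neighbour-list file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "AdjacencyGraph",
    "build_lattice_adjacency",
    "read_adjacency_gal",
    "write_adjacency_gal",
    "connected_components",
    "icar_pairwise_ss",
    "icar_logdensity",
]


class GALParseError(ValueError):
    """Raised when a GAL neighbour file is malformed or asymmetric."""


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour structure over ``n_areas`` areal units.

    Parameters
    ----------
    n_areas
        Number of areal units.
    area_ids
        Unique string labels, one per area, in storage order.
    neighbors
        ``neighbors[i]`` lists the 0-based indices adjacent to area ``i``.
        Symmetry and absence of self-loops are validated on construction.
    """

    n_areas: int
    area_ids: list[str]
    neighbors: list[np.ndarray]
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)
    _labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_areas <= 0:
            raise ValueError("n_areas must be positive")
        if len(self.area_ids) != self.n_areas:
            raise ValueError("area_ids length must equal n_areas")
        if len(set(self.area_ids)) != self.n_areas:
            raise ValueError("area_ids must be unique")
        if len(self.neighbors) != self.n_areas:
            raise ValueError("neighbors length must equal n_areas")
        self.neighbors = [np.asarray(sorted(nb), dtype=np.int64) for nb in self.neighbors]
        nbsets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nb in enumerate(nbsets):
            if i in nb:
                raise ValueError(f"self-loop at area index {i}")
            for j in nb:
                if not (0 <= j < self.n_areas):
                    raise ValueError(f"neighbor index {j} of area {i} out of range")
                if i not in nbsets[j]:
                    raise ValueError(f"asymmetric adjacency: {i} lists {j} but not vice versa")

    # -- derived structure ------------------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """Array of shape (n_edges, 2): each undirected edge once, i < j."""
        if self._edges is None:
            pairs = [
                (i, int(j)) for i, nb in enumerate(self.neighbors) for j in nb if i < j
            ]
            self._edges = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return self._edges

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray([len(nb) for nb in self.neighbors], dtype=np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Binary symmetric adjacency as CSR (for vectorised neighbour sums)."""
        e = self.edges
        if e.size == 0:
            return sp.csr_matrix((self.n_areas, self.n_areas))
        data = np.ones(2 * e.shape[0])
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A (the ICAR structure matrix)."""
        lap = np.diag(self.degrees.astype(float))
        for i, j in self.edges:
            lap[i, j] -= 1.0
            lap[j, i] -= 1.0
        return lap

    def component_labels(self) -> np.ndarray:
        if self._labels is None:
            labels = np.full(self.n_areas, -1, dtype=np.int64)
            comp = 0
            for i in range(self.n_areas):
                if labels[i] >= 0:
                    continue
                stack = [i]
                labels[i] = comp
                while stack:
                    v = stack.pop()
                    for w in self.neighbors[v]:
                        if labels[w] < 0:
                            labels[w] = comp
                            stack.append(int(w))
                comp += 1
            self._labels = labels
        return self._labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels().max()) + 1


def build_lattice_adjacency(nrows: int, ncols: int, rule: str = "rook") -> AdjacencyGraph:
    """Contiguity graph of an ``nrows`` x ``ncols`` grid in row-major order.

    ``rule='rook'`` links horizontal/vertical neighbours; ``'queen'`` also
    links diagonals.  A regular lattice stands in for census-tract
    contiguity when simulating areal data.
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if rule not in ("rook", "queen"):
        raise ValueError(f"rule must be 'rook' or 'queen', got {rule!r}")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if rule == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    n = nrows * ncols
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    neighbors[i].append(rr * ncols + cc)
    ids = [f"r{r}c{c}" for r in range(nrows) for c in range(ncols)]
    return AdjacencyGraph(n, ids, [np.asarray(nb) for nb in neighbors])


def graph_from_id_lists(area_ids: Sequence[str], neighbor_ids: dict[str, Iterable[str]]) -> AdjacencyGraph:
    """Build a graph from id-labelled neighbour lists (validates symmetry)."""
    index = {a: i for i, a in enumerate(area_ids)}
    neighbors = []
    for a in area_ids:
        nb = []
        for b in neighbor_ids.get(a, ()):  # unknown ids surface as KeyError below
            if b not in index:
                raise KeyError(f"unknown neighbour id {b!r} for area {a!r}")
            nb.append(index[b])
        neighbors.append(np.asarray(nb, dtype=np.int64))
    return AdjacencyGraph(len(area_ids), list(area_ids), neighbors)


def read_adjacency_gal(path: str | Path) -> AdjacencyGraph:
    """Read a GAL neighbour-list file.

    Dialect: first non-comment line is the integer number of areas; then for
    each area a header line ``<id> <k>`` followed by one line of ``k``
    whitespace-separated neighbour ids.  Lines starting with ``#`` and blank
    lines are ignored.  Symmetry of the listing is verified, not assumed.
    """
    path = Path(path)
    numbered = [
        (no, ln.strip())
        for no, ln in enumerate(path.read_text().splitlines(), start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not numbered:
        raise GALParseError(f"{path}: empty GAL file")
    lines = iter(numbered)
    no, first = next(lines)
    try:
        n = int(first.split()[0])
    except ValueError as exc:
        raise GALParseError(f"{path}:{no}: expected area count, got {first!r}") from exc
    ids: list[str] = []
    raw: dict[str, list[str]] = {}
    for _ in range(n):
        try:
            no, header = next(lines)
        except StopIteration:
            raise GALParseError(f"{path}: truncated file, expected {n} area records")
        parts = header.split()
        if len(parts) != 2:
            raise GALParseError(f"{path}:{no}: expected '<id> <k>' header, got {header!r}")
        aid, k_str = parts
        try:
            k = int(k_str)
        except ValueError as exc:
            raise GALParseError(f"{path}:{no}: neighbour count not an integer: {k_str!r}") from exc
        if aid in raw:
            raise GALParseError(f"{path}:{no}: duplicate area id {aid!r}")
        if k > 0:
            try:
                no2, nbline = next(lines)
            except StopIteration:
                raise GALParseError(f"{path}: truncated neighbour list for {aid!r}")
            nbs = nbline.split()
            if len(nbs) != k:
                raise GALParseError(
                    f"{path}:{no2}: area {aid!r} declares {k} neighbours, line has {len(nbs)}"
                )
        else:
            nbs = []
        ids.append(aid)
        raw[aid] = nbs
    index = {a: i for i, a in enumerate(ids)}
    neighbors = []
    for aid in ids:
        nb = []
        for b in raw[aid]:
            if b not in index:
                raise GALParseError(f"{path}: area {aid!r} lists unknown neighbour {b!r}")
            nb.append(index[b])
        neighbors.append(np.asarray(nb, dtype=np.int64))
    for i, nb in enumerate(neighbors):
        for j in nb:
            if i not in neighbors[j]:
                raise GALParseError(
                    f"{path}: asymmetric listing: {ids[i]!r} lists {ids[int(j)]!r} "
                    f"but not vice versa"
                )
    return AdjacencyGraph(n, ids, neighbors)


def write_adjacency_gal(graph: AdjacencyGraph, path: str | Path) -> None:
    """Write a graph in the GAL dialect read by :func:`read_adjacency_gal`."""
    out = [str(graph.n_areas)]
    for i, aid in enumerate(graph.area_ids):
        nb = graph.neighbors[i]
        out.append(f"{aid} {len(nb)}")
        if len(nb):
            out.append(" ".join(graph.area_ids[int(j)] for j in nb))
    Path(path).write_text("\n".join(out) + "\n")


def connected_components(graph: AdjacencyGraph) -> tuple[np.ndarray, int]:
    """Per-area component label (0-based) and the number of components."""
    labels = graph.component_labels()
    return labels, graph.n_components


def icar_pairwise_ss(x: np.ndarray, graph: AdjacencyGraph) -> float:
    """Sum over unordered neighbour pairs {i,j} of (x_i - x_j)^2.

    This quadratic form x' L x (L the graph Laplacian) is the kernel of the
    intrinsic CAR prior on spatially structured effects.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_areas,):
        raise ValueError(f"x has shape {x.shape}, expected ({graph.n_areas},)")
    e = graph.edges
    if e.size == 0:
        return 0.0
    d = x[e[:, 0]] - x[e[:, 1]]
    return float(d @ d)


def check_centered(x: np.ndarray, graph: AdjacencyGraph, tol: float = 1e-8) -> bool:
    """True iff x sums to zero within every connected component (|sum| <= tol)."""
    x = np.asarray(x, dtype=float)
    labels = graph.component_labels()
    sums = np.bincount(labels, weights=x, minlength=graph.n_components)
    return bool(np.all(np.abs(sums) <= tol))


def icar_logdensity(x: np.ndarray, graph: AdjacencyGraph, tau: float) -> float:
    """Log density of the intrinsic CAR prior, up to a constant in (x, tau).

    Returns ``((n - c)/2) log tau - (tau/2) sum_{i~j} (x_i - x_j)^2`` where
    ``n`` is the number of areas and ``c`` the number of connected
    components (the rank deficiency of the Laplacian).  The prior is
    improper; it is identified by requiring x to sum to zero within each
    component, which is enforced as a precondition.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_areas,):
        raise ValueError(f"x has shape {x.shape}, expected ({graph.n_areas},)")
    if not check_centered(x, graph):
        raise ValueError("x must sum to zero within each connected component")
    n, c = graph.n_areas, graph.n_components
    return 0.5 * (n - c) * np.log(tau) - 0.5 * tau * icar_pairwise_ss(x, graph)


def greedy_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition areas into independent sets (no two in a set are adjacent).

    Used by the sampler to vectorise single-site Metropolis updates of ICAR
    fields: within a colour class the full conditionals do not interact, so
    the sites can be proposed and accepted simultaneously.
    """
    colors = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
    ncol = max(colors.values()) + 1 if colors else 1
    classes = [[] for _ in range(ncol)]
    for node, col in colors.items():
        classes[col].append(node)
    return [np.asarray(sorted(c), dtype=np.int64) for c in classes if c]


def enumerate_labeled_graphs(n: int, connected_only: bool = True):
    """Yield every labelled simple graph on n nodes as an AdjacencyGraph.

    Exhaustive (2^(n(n-1)/2) graphs); intended for small-n oracle tests.
    """
    pairs = list(itertools.combinations(range(n), 2))
    ids = [str(i) for i in range(n)]
    for mask in range(1 << len(pairs)):
        neighbors: list[list[int]] = [[] for _ in range(n)]
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                neighbors[i].append(j)
                neighbors[j].append(i)
        g = AdjacencyGraph(n, ids, [np.asarray(nb, dtype=np.int64) for nb in neighbors])
        if connected_only and g.n_components != 1:
            continue
        yield g
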