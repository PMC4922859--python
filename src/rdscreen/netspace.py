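"""Enumeration and graph-filtering of candidate signalling networks.

A *network* is an unsigned set of ``k`` regulatory interactions (Jacobian
support cells) over ``N`` typed nodes.  Nodes are either diffusible
(secreted ligands, extracellular inhibitors) or non-diffusible
(cell-autonomous factors: receptors, kinases, transcription factors).
Edge ``(i, j)`` stands for the Jacobian cell ``J[i][j]``, i.e. node ``j``
regulates node ``i``; diagonal cells are self-regulation and count toward
``k``.

The screening pipeline uses three graph-level operations implemented here:

* exhaustive enumeration of all ``k``-subsets of allowed cells,
* the strong-connectivity filter (self-loops ignored), which subsumes the
  removal of isolated nodes and of pure read-out nodes,
* deduplication of isomorphic networks under node permutations that
  preserve the diffusible / non-diffusible classes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[int, int]

__all__ = [
    "NodeSpec",
    "NetworkGraph",
    "CanonicalKey",
    "make_nodes",
    "count_networks",
    "enumerate_networks",
    "passes_connectivity_filter",
    "class_preserving_permutations",
    "automorphisms",
    "canonical_key",
    "dedup_networks",
]


@dataclass(frozen=True, order=True)
class NodeSpec:
    """One node of a signalling network.

    Parameters
    ----------
    index : int
        Position of the node, ``0 .. N-1``.
    diffusible : bool
        True for secreted/diffusing reactants, False for cell-autonomous
        factors (diffusion coefficient identically zero).
    label : str, optional
        Short display name (e.g. ``"Nodal"``).
    """

    index: int
    diffusible: bool
    label: str | None = field(default=None, compare=False)


def make_nodes(diffusible_flags: Sequence[bool], labels: Sequence[str] | None = None) -> tuple[NodeSpec, ...]:
    """Build a node tuple from per-node diffusibility flags."""
    if labels is None:
        labels = [None] * len(diffusible_flags)
    if len(labels) != len(diffusible_flags):
        raise ValueError("labels and diffusible_flags must have equal length")
    return tuple(
        NodeSpec(i, bool(f), lab) for i, (f, lab) in enumerate(zip(diffusible_flags, labels))
    )


def _validate_nodes(nodes: Sequence[NodeSpec]) -> None:
    if [n.index for n in nodes] != list(range(len(nodes))):
        raise ValueError("node indices must be unique and contiguous starting at 0")


@dataclass(frozen=True)
class NetworkGraph:
    """Unsigned interaction structure: node types plus a set of edges.

    ``edges`` is a frozenset of ordered pairs ``(target, source)``; the
    pair corresponds to the Jacobian support cell ``J[target][source]``.
    """

    nodes: tuple[NodeSpec, ...]
    edges: frozenset[Edge]

    def __post_init__(self):
        _validate_nodes(self.nodes)
        n = len(self.nodes)
        for (i, j) in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge {(i, j)} outside node range 0..{n - 1}")

    # -- basic views ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def k(self) -> int:
        return len(self.edges)

    @property
    def diffusible_mask(self) -> np.ndarray:
        return np.array([n.diffusible for n in self.nodes], dtype=bool)

    def sorted_edges(self) -> tuple[Edge, ...]:
        """Edges in row-major order; the canonical edge ordering used for
        sign vectors throughout the package."""
        return tuple(sorted(self.edges))

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for (i, j) in self.edges:
            a[i, j] = True
        return a

    # -- serialisation -------------------------------------------------
    def to_edge_list_text(self) -> str:
        """One edge per line in ``i<-j`` form (j regulates i)."""
        return "\n".join(f"{i}<-{j}" for (i, j) in self.sorted_edges())

    @classmethod
    def from_edge_list_text(cls, text: str, nodes: Sequence[NodeSpec]) -> "NetworkGraph":
        edges = set()
        for ln, line in enumerate(text.strip().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            try:
                i, j = line.split("<-")
                edges.add((int(i), int(j)))
            except ValueError as exc:
                raise ValueError(f"malformed edge on line {ln}: {line!r}") from exc
        return cls(tuple(nodes), frozenset(edges))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.index, diffusible=n.diffusible, label=n.label or str(n.index))
        for (i, j) in self.sorted_edges():
            g.add_edge(j, i)  # networkx convention: source -> target
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        g = self.to_networkx()
        lines = ["digraph network {"]
        for n, data in g.nodes(data=True):
            shape = "ellipse" if data["diffusible"] else "box"
            lines.append(f'  {n} [label="{data["label"]}", shape={shape}];')
        for u, v in g.edges():
            lines.append(f"  {u} -> {v};")
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True, order=True)
class CanonicalKey:
    """Lexicographically minimal N*N adjacency bit string over all
    class-preserving node permutations."""

    key: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


# ---------------------------------------------------------------------------
# Step 1: enumeration
# ---------------------------------------------------------------------------

def count_networks(n_nodes: int, k: int) -> int:
    """Number of k-edge networks on ``n_nodes`` nodes: binomial(N*N, k).

    Self-regulation cells are eligible, so the pool of cells has size
    ``N*N`` and a completely connected network has ``k = N*N``.
    """
    n_cells = n_nodes * n_nodes
    if not 1 <= k <= n_cells:
        raise ValueError(f"k={k} out of range: must satisfy 1 <= k <= N*N = {n_cells}")
    return math.comb(n_cells, k)


def enumerate_networks(
    nodes: Sequence[NodeSpec],
    k: int,
    forced_edges: Iterable[Edge] = (),
    forbidden_edges: Iterable[Edge] = (),
) -> Iterator[NetworkGraph]:
    """Yield every k-edge network containing all forced edges exactly once.

    The order is deterministic: free cells are combined in row-major
    lexicographic order, so catalogs are reproducible run to run.
    Infeasible constraint sets produce an empty stream and a logged
    warning rather than an exception (an empty screen is a valid answer).
    """
    _validate_nodes(nodes)
    nodes = tuple(nodes)
    n = len(nodes)
    forced = sorted(set(map(tuple, forced_edges)))
    forbidden = set(map(tuple, forbidden_edges))
    if set(forced) & forbidden:
        raise ValueError("forced and forbidden edge sets must be disjoint")
    all_cells = [(i, j) for i in range(n) for j in range(n)]
    for e in itertools.chain(forced, forbidden):
        if e not in set(all_cells):
            raise ValueError(f"constraint edge {e} outside node range")
    free = [c for c in all_cells if c not in forbidden and c not in set(forced)]
    n_extra = k - len(forced)
    if n_extra < 0:
        logger.warning("infeasible enumeration: %d forced edges exceed k=%d", len(forced), k)
        return
    if n_extra > len(free):
        logger.warning(
            "infeasible enumeration: only %d allowed cells for %d additional edges",
            len(free), n_extra,
        )
        return
    for extra in itertools.combinations(free, n_extra):
        yield NetworkGraph(nodes, frozenset(forced) | frozenset(extra))


# ---------------------------------------------------------------------------
# Step 2: connectivity filter
# ---------------------------------------------------------------------------

def passes_connectivity_filter(net: NetworkGraph) -> bool:
    """True iff the digraph with self-loops removed is strongly connected.

    Strong connectivity over all N nodes implies there is no isolated node
    and no pure read-out node (a node whose only non-self edges are
    incoming), which is exactly the composite filter of the pipeline's
    second step.  Self-loops are ignored because self-regulation cannot
    connect distinct nodes.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from((j, i) for (i, j) in net.edges if i != j)
    return nx.is_strongly_connected(g)


# ---------------------------------------------------------------------------
# Step 3: isomorphism deduplication
# ---------------------------------------------------------------------------

def class_preserving_permutations(nodes: Sequence[NodeSpec]) -> list[tuple[int, ...]]:
    """All node permutations mapping diffusible nodes to diffusible nodes
    and non-diffusible to non-diffusible.  Brute force is fine: screens
    run at N <= 5, i.e. at most 120 candidate permutations."""
    flags = [n.diffusible for n in nodes]
    return [
        p
        for p in itertools.permutations(range(len(nodes)))
        if all(flags[p[i]] == flags[i] for i in range(len(nodes)))
    ]


def _apply_permutation(edges: frozenset[Edge], perm: Sequence[int]) -> frozenset[Edge]:
    return frozenset((perm[i], perm[j]) for (i, j) in edges)


def _bitstring(edges: frozenset[Edge], n: int) -> str:
    bits = ["0"] * (n * n)
    for (i, j) in edges:
        bits[i * n + j] = "1"
    return "".join(bits)


def canonical_key(net: NetworkGraph, permutations: Sequence[Sequence[int]] | None = None) -> CanonicalKey:
    """Minimal adjacency bit string over class-preserving permutations.

    ``permutations`` may restrict the group further, e.g. to permutations
    preserving a constraint structure in constrained screens.
    """
    if permutations is None:
        permutations = class_preserving_permutations(net.nodes)
    best = min(_bitstring(_apply_permutation(net.edges, p), net.n_nodes) for p in permutations)
    return CanonicalKey(best)


def automorphisms(net: NetworkGraph, permutations: Sequence[Sequence[int]] | None = None) -> list[tuple[int, ...]]:
    """Class-preserving permutations that map the edge set onto itself."""
    if permutations is None:
        permutations = class_preserving_permutations(net.nodes)
    return [tuple(p) for p in permutations if _apply_permutation(net.edges, p) == net.edges]


def dedup_networks(
    networks: Iterable[NetworkGraph],
    permutations: Sequence[Sequence[int]] | None = None,
) -> list[NetworkGraph]:
    """Keep one representative per isomorphism class, ordered by canonical
    key.  Idempotent: deduplicating a deduplicated list is a no-op."""
    reps: dict[CanonicalKey, NetworkGraph] = {}
    for net in networks:
        key = canonical_key(net, permutations)
        reps.setdefault(key, net)
    return [reps[k] for k in sorted(reps)]
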