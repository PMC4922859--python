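"""Feedback-cycle formalism for the characteristic polynomial.

Every coefficient ``a_m`` of the characteristic polynomial at ``q^2 = 0``
can be written as a signed sum over sets of vertex-disjoint feedback
cycles covering ``m`` nodes: for each m-node principal subset,
``det(J_S) = sum over cycle covers of (-1)^(m - #cycles) * prod(gains)``,
and ``a_m = (-1)^m * sum_S det(J_S)``.  This rewrites the pattern-forming
conditions in terms of network feedbacks instead of individual rates:
net-positive cycles are candidate destabilisers, net-negative cycles
candidate stabilisers, and cycles confined to non-diffusible nodes keep
contributing in the large-wave-number limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netspace import NetworkGraph

__all__ = ["Cycle", "CycleDecomposition", "find_cycles", "coeff_from_cycles",
           "decompose", "feedback_report", "FeedbackReport", "CycleReportEntry"]


@dataclass(frozen=True)
class Cycle:
    """A directed simple cycle; length 1 is a self-loop.

    ``nodes`` lists the cycle in edge order starting from its smallest
    node index (so each cycle is reported once up to rotation): the cycle
    walks ``nodes[0] -> nodes[1] -> ... -> nodes[0]``.
    """

    nodes: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.nodes)

    def edges(self) -> tuple[tuple[int, int], ...]:
        """Jacobian cells (target, source) traversed by the cycle."""
        ns = self.nodes
        return tuple((ns[(p + 1) % len(ns)], ns[p]) for p in range(len(ns)))

    def gain(self, J: np.ndarray) -> float:
        g = 1.0
        for (i, j) in self.edges():
            g *= J[i, j]
        return g

    def sign(self, signs: dict) -> int:
        s = 1
        for e in self.edges():
            s *= signs[e]
        return s


def _canonical_rotation(seq: tuple[int, ...]) -> tuple[int, ...]:
    i = seq.index(min(seq))
    return seq[i:] + seq[:i]


def find_cycles(net: NetworkGraph) -> list[Cycle]:
    """All simple directed cycles of the network, self-loops included."""
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_nodes))
    # networkx edge u -> v == our cell (v, u)
    g.add_edges_from((j, i) for (i, j) in net.edges)
    out = [Cycle(_canonical_rotation(tuple(c))) for c in nx.simple_cycles(g)]
    return sorted(out, key=lambda c: (c.length, c.nodes))


def _cycle_covers(nodes: tuple[int, ...], adj: np.ndarray):
    """All partitions of ``nodes`` into vertex-disjoint simple cycles with
    every traversed cell present in ``adj``; yields lists of node tuples."""
    if not nodes:
        yield []
        return
    first = nodes[0]
    rest = set(nodes[1:])
    # enumerate simple cycles through `first` using only `nodes`
    def walks(path, visited):
        last = path[-1]
        # close the cycle: edge (first <- last) means adj[first, last]
        if adj[first, last]:
            yield tuple(path)
        for nxt in rest - visited:
            if adj[nxt, last]:
                yield from walks(path + [nxt], visited | {nxt})

    for cyc in walks([first], set()):
        remaining = tuple(sorted(rest - set(cyc)))
        for tail in _cycle_covers(remaining, adj):
            yield [cyc] + tail


def coeff_from_cycles(J: np.ndarray, m: int) -> float:
    """Characteristic coefficient ``a_m`` assembled from cycle covers.

    Matches ``char_poly_coeffs(J).coeffs[m-1]`` exactly (to floating
    tolerance); the route through explicit cycles is the deliverable, not
    a faster determinant.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in 1..{n}")
    adj = J != 0
    total = 0.0
    for subset in itertools.combinations(range(n), m):
        for cover in _cycle_covers(subset, adj):
            term = (-1.0) ** (m - len(cover))
            for cyc in cover:
                for p in range(len(cyc)):
                    term *= J[cyc[(p + 1) % len(cyc)], cyc[p]]
            total += term
    return ((-1.0) ** m) * total


@dataclass
class CycleDecomposition:
    """Per-order lists of (cycle cover, combinatorial sign, gain product)."""

    n_nodes: int
    terms: dict  # m -> list[(tuple[Cycle,...], int, float)]

    def coefficient(self, m: int) -> float:
        return ((-1.0) ** m) * sum(s * g for (_, s, g) in self.terms.get(m, []))


def decompose(J: np.ndarray) -> CycleDecomposition:
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    adj = J != 0
    terms: dict[int, list] = {}
    for m in range(1, n + 1):
        bucket = []
        for subset in itertools.combinations(range(n), m):
            for cover in _cycle_covers(subset, adj):
                sign = (-1) ** (m - len(cover))
                gain = 1.0
                for cyc in cover:
                    for p in range(len(cyc)):
                        gain *= J[cyc[(p + 1) % len(cyc)], cyc[p]]
                bucket.append((tuple(Cycle(_canonical_rotation(c)) for c in cover), sign, gain))
        terms[m] = bucket
    return CycleDecomposition(n, terms)


# ---------------------------------------------------------------------------
# qualitative report
# ---------------------------------------------------------------------------

@dataclass
class CycleReportEntry:
    cycle: Cycle
    sign: int                     # product of edge signs
    label: str                    # "destabilizing" / "stabilizing"
    coefficient_orders: tuple[int, ...]
    diffusion_independent: bool   # confined to non-diffusible nodes


@dataclass
class FeedbackReport:
    entries: list[CycleReportEntry]

    def destabilizing(self) -> list[CycleReportEntry]:
        return [e for e in self.entries if e.label == "destabilizing"]

    def stabilizing(self) -> list[CycleReportEntry]:
        return [e for e in self.entries if e.label == "stabilizing"]

    def to_text(self) -> str:
        lines = []
        for e in self.entries:
            arrow = "->".join(map(str, e.cycle.nodes + (e.cycle.nodes[0],)))
            tags = [e.label, f"enters a_{{{','.join(map(str, e.coefficient_orders))}}}"]
            if e.diffusion_independent:
                tags.append("diffusion-independent")
            lines.append(f"cycle {arrow} [{'+' if e.sign > 0 else '-'}]: " + ", ".join(tags))
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        return [
            {
                "nodes": list(e.cycle.nodes),
                "sign": e.sign,
                "label": e.label,
                "coefficient_orders": list(e.coefficient_orders),
                "diffusion_independent": e.diffusion_independent,
            }
            for e in self.entries
        ]


def feedback_report(topology) -> FeedbackReport:
    """Sign-label every feedback cycle of a signed topology.

    Net-activating cycles are flagged as destabilising candidates and
    net-inhibiting ones as stabilising candidates; the authoritative
    statement is which coefficients ``a_m`` (hence which Routh-Hurwitz
    inequalities) each cycle enters, listed alongside.  Cycles confined
    to non-diffusible nodes are additionally flagged: their contribution
    survives the large-``q`` limit for any diffusion coefficients.
    """
    net = topology.network
    adj = net.adjacency()
    diffusible = net.diffusible_mask
    cycles = find_cycles(net)
    entries = []
    for cyc in cycles:
        sign = cyc.sign(topology.signs)
        orders = []
        for m in range(cyc.length, net.n_nodes + 1):
            # cycle enters a_m iff its vertex set extends to an m-node
            # cover by disjoint cycles on the remaining nodes
            found = False
            for subset in itertools.combinations(
                [v for v in range(net.n_nodes) if v not in cyc.nodes], m - cyc.length
            ):
                for cover in _cycle_covers(tuple(sorted(subset)), adj):
                    found = True
                    break
                if found:
                    break
            if found or m == cyc.length:
                orders.append(m)
        entries.append(
            CycleReportEntry(
                cycle=cyc,
                sign=sign,
                label="destabilizing" if sign > 0 else "stabilizing",
                coefficient_orders=tuple(orders),
                diffusion_independent=bool(all(not diffusible[v] for v in cyc.nodes)),
            )
        )
    return FeedbackReport(entries)
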