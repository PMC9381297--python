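"""Protein-protein interaction network handling and degree-based hub ranking.

The PPI graph is an undirected simple graph (no self-loops, no parallel
edges). Hub proteins are the top-k nodes by degree; ties are broken
lexicographically so rankings are reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from diseasome.datasets import normalize_symbol
from diseasome.errors import InputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Thin wrapper over an undirected simple networkx graph."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node=None):
        if node is not None:
            return self.graph.degree(node)
        return dict(self.graph.degree())

    def to_graphml(self, path, node_attrs: dict | None = None) -> None:
        g = self.graph.copy()
        if node_attrs:
            for node, attrs in node_attrs.items():
                if node in g:
                    g.nodes[node].update(attrs)
        nx.write_graphml(g, path)


@dataclass
class HubReport:
    """Ranked (protein, degree) list; degrees non-increasing down the list."""

    ranked: list
    k: int

    def proteins(self) -> list:
        return [p for p, _ in self.ranked]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tprotein\tdegree\n")
            for rank, (protein, degree) in enumerate(self.ranked, start=1):
                fh.write(f"{rank}\t{protein}\t{degree}\n")


def read_edge_list(path, score_threshold: float | None = None) -> PPINetwork:
    """Parse a TSV edge list ``protein_a<TAB>protein_b[<TAB>score]``.

    Duplicate edges (in either orientation) are collapsed, self-loops
    dropped with a logged count, and an optional score column filtered at
    ``score_threshold`` (edges without a score always pass).
    """
    g = nx.Graph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'protein_a<TAB>protein_b'")
            a, b = normalize_symbol(parts[0]), normalize_symbol(parts[1])
            if lineno == 1 and {a, b} & {"PROTEIN_A", "PROTEIN_B"}:
                continue  # optional header
            if not a or not b:
                raise InputError(f"{path}:{lineno}: empty protein identifier")
            if len(parts) >= 3 and score_threshold is not None:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
                if score < score_threshold:
                    continue
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        logger.info("%s: dropped %d self-loops", path, n_self)
    return PPINetwork(g)


def induced_subnetwork(net: PPINetwork, genes) -> PPINetwork:
    """Restrict the network to the given gene set (both edge ends retained)."""
    keep = {normalize_symbol(g) for g in genes}
    sub = net.graph.subgraph(keep & set(net.graph.nodes)).copy()
    return PPINetwork(sub)


def top_hubs(net: PPINetwork, k: int = 10, include_ties: bool = False) -> HubReport:
    """Rank nodes by degree descending and return the top k as hubs.

    Ties at the k-th position are cut lexicographically unless
    ``include_ties`` is set, in which case every node tied with the k-th
    degree is kept.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    degrees = dict(net.graph.degree())
    if not degrees:
        logger.warning("top_hubs on an empty network")
        return HubReport([], k)
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) <= k:
        return HubReport(ranked, k)
    if include_ties:
        cutoff = ranked[k - 1][1]
        ranked = [rv for rv in ranked if rv[1] >= cutoff]
    else:
        ranked = ranked[:k]
    return HubReport(ranked, k)
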