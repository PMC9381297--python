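"""Gene-disease bipartite network ("diseasome") construction and scoring.

Two diseases are linked when their dysregulated gene sets intersect. For
disease pair (i, j) with dysregulated sets G_i and G_j the shared-gene count
is n_ij = |G_i ∩ G_j| and the edge-prediction score is the Jaccard
coefficient E(i, j) = |G_i ∩ G_j| / |G_i ∪ G_j|. Overlaps are computed
per direction (up-only, down-only) and combined, because cross-disease
comparisons are conventionally reported split by direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from diseasome.datasets import normalize_symbol
from diseasome.errors import ValidationError

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "combined")


@dataclass(frozen=True)
class DiseaseGeneSets:
    """Up- and down-regulated gene symbols for one disease.

    ``conflicted`` records genes excluded during a multi-cohort combination
    because they were called up in one cohort and down in another.
    """

    disease_id: str
    up_genes: frozenset
    down_genes: frozenset
    conflicted: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(map(normalize_symbol, self.up_genes)))
        object.__setattr__(self, "down_genes", frozenset(map(normalize_symbol, self.down_genes)))
        object.__setattr__(self, "conflicted", frozenset(map(normalize_symbol, self.conflicted)))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValidationError(
                f"{self.disease_id}: genes in both up and down sets: {sorted(overlap)[:5]}"
            )

    @property
    def all_genes(self) -> frozenset:
        return self.up_genes | self.down_genes

    def genes(self, direction: str) -> frozenset:
        if direction == "up":
            return self.up_genes
        if direction == "down":
            return self.down_genes
        if direction == "combined":
            return self.all_genes
        raise ValidationError(f"direction must be one of {DIRECTIONS}")


def shared_gene_count(sets_i, sets_j) -> int:
    """Number of genes dysregulated in both diseases: |G_i ∩ G_j|."""
    return len(frozenset(sets_i) & frozenset(sets_j))


def jaccard_score(sets_i, sets_j) -> float:
    """Jaccard edge-prediction score |G_i ∩ G_j| / |G_i ∪ G_j|.

    Undefined (NaN, with a warning) when both sets are empty.
    """
    a, b = frozenset(sets_i), frozenset(sets_j)
    union = a | b
    if not union:
        logger.warning("jaccard_score of two empty sets is undefined")
        return math.nan
    return len(a & b) / len(union)


@dataclass
class DiseasomeNetwork:
    """Bipartite gene-disease graph plus pairwise disease overlap statistics.

    ``bipartite_edges`` is a list of (disease_id, gene, direction) triples;
    ``pair_stats`` maps (disease_i, disease_j, direction) — pair sorted
    lexicographically, direction in up/down/combined — to
    ``{"n_shared": int, "jaccard": float}``. A pair appears only if its
    combined shared count is at least one.
    """

    focal_id: str
    disease_nodes: list
    gene_nodes: list
    bipartite_edges: list
    pair_stats: dict = field(default_factory=dict)

    def graph(self, direction: str | None = None) -> nx.Graph:
        """Bipartite networkx graph; restrict to one direction if given."""
        g = nx.Graph()
        for d in self.disease_nodes:
            g.add_node(d, type="disease")
        for disease, gene, edge_dir in self.bipartite_edges:
            if direction is not None and edge_dir != direction:
                continue
            if gene not in g:
                g.add_node(gene, type="gene")
            g.add_edge(disease, gene, direction=edge_dir)
        return g

    def pair_stats_frame(self) -> pd.DataFrame:
        rows = [
            {
                "disease_i": i,
                "disease_j": j,
                "direction": d,
                "n_shared": s["n_shared"],
                "jaccard": s["jaccard"],
            }
            for (i, j, d), s in sorted(self.pair_stats.items())
        ]
        return pd.DataFrame(rows, columns=["disease_i", "disease_j", "direction", "n_shared", "jaccard"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)

    def to_sif(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for disease, gene, direction in sorted(self.bipartite_edges):
                fh.write(f"{disease}\t{direction}\t{gene}\n")


def combine_focal_datasets(sets_list, combined_id: str) -> DiseaseGeneSets:
    """Merge several cohorts of the same disease into one gene-set pair.

    Up-sets and down-sets are unioned per direction. A gene called up in one
    cohort and down in another carries no consistent direction: it is removed
    from both sets and reported in ``conflicted`` so the exclusion is
    auditable.
    """
    sets_list = list(sets_list)
    if not sets_list:
        raise ValidationError("combine_focal_datasets needs >=1 input set")
    up = frozenset().union(*(s.up_genes for s in sets_list))
    down = frozenset().union(*(s.down_genes for s in sets_list))
    conflicted = up & down
    if conflicted:
        logger.warning(
            "%s: %d direction-conflicted genes excluded: %s",
            combined_id, len(conflicted), sorted(conflicted)[:10],
        )
    return DiseaseGeneSets(combined_id, up - conflicted, down - conflicted, conflicted)


def build_diseasome(focal: DiseaseGeneSets, risk_factors) -> DiseasomeNetwork:
    """Build the gene-disease bipartite network around a focal disease.

    Gene nodes are the genes the focal disease shares with at least one risk
    factor, connected per direction to every disease carrying them (the up-
    and down-subgraphs are recoverable via the edge ``direction`` attribute).
    Pairwise overlap counts and Jaccard scores are recorded for every disease
    pair that shares at least one dysregulated gene.
    """
    risk_factors = list(risk_factors)
    if not risk_factors:
        raise ValidationError("need at least one risk factor")
    if not focal.all_genes:
        raise ValidationError("focal disease has no dysregulated genes")
    ids = [focal.disease_id] + [r.disease_id for r in risk_factors]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate disease ids: {ids}")

    all_sets = [focal] + risk_factors
    edges = []
    gene_nodes = set()
    for direction in ("up", "down"):
        focal_genes = focal.genes(direction)
        shared_with_any = set()
        for rf in risk_factors:
            shared_with_any |= focal_genes & rf.genes(direction)
        for gene in shared_with_any:
            gene_nodes.add(gene)
            for ds in all_sets:
                if gene in ds.genes(direction):
                    edges.append((ds.disease_id, gene, direction))

    pair_stats = {}
    for idx, si in enumerate(all_sets):
        for sj in all_sets[idx + 1:]:
            key_i, key_j = sorted([si.disease_id, sj.disease_id])
            if shared_gene_count(si.all_genes, sj.all_genes) < 1:
                continue
            for direction in DIRECTIONS:
                gi, gj = si.genes(direction), sj.genes(direction)
                n = shared_gene_count(gi, gj)
                pair_stats[(key_i, key_j, direction)] = {
                    "n_shared": n,
                    "jaccard": jaccard_score(gi, gj) if (gi or gj) else math.nan,
                }
    return DiseasomeNetwork(
        focal_id=focal.disease_id,
        disease_nodes=ids,
        gene_nodes=sorted(gene_nodes),
        bipartite_edges=sorted(edges),
        pair_stats=pair_stats,
    )


def membership_patterns(network: DiseasomeNetwork, min_diseases: int = 3):
    """Genes linked to at least ``min_diseases`` diseases in the network.

    Returns (gene, direction, sorted disease list) tuples ordered by degree
    descending, then gene symbol — the multi-disease shared genes that make
    a risk factor's link to the focal disease most credible.
    """
    by_gene_dir: dict = {}
    for disease, gene, direction in network.bipartite_edges:
        by_gene_dir.setdefault((gene, direction), set()).add(disease)
    rows = [
        (gene, direction, sorted(diseases))
        for (gene, direction), diseases in by_gene_dir.items()
        if len(diseases) >= min_diseases
    ]
    rows.sort(key=lambda r: (-len(r[2]), r[0], r[1]))
    return rows
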