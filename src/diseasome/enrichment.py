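"""Local over-representation analysis against GMT gene-set libraries.

For a query gene list and a term with gene set T inside a background
universe of size M, the enrichment p-value is the upper hypergeometric tail

    p = P(X >= |query ∩ T|),   X ~ Hypergeom(M, |T|, |query ∩ universe|),

equivalent to a one-sided Fisher exact test. The default background is the
union of all genes in the library (the convention of web enrichment tools);
a measured-gene universe can be supplied instead. BH adjustment runs across
all terms of a library; the default significance rule is raw p <= 0.05 with
the adjusted p always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from diseasome.datasets import normalize_symbol
from diseasome.errors import InputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets plus the background universe."""

    library_id: str
    terms: dict  # term_id -> (description, frozenset of genes)
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        terms = {}
        for term, (desc, genes) in self.terms.items():
            genes = frozenset(normalize_symbol(g) for g in genes)
            if not genes:
                raise ValidationError(f"{self.library_id}: term {term!r} has no genes")
            terms[term] = (desc, genes)
        self.terms = terms
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
        else:
            self.universe = frozenset(normalize_symbol(g) for g in self.universe)
            stray = {t for t, (_, g) in terms.items() if not g <= self.universe}
            if stray:
                raise ValidationError(
                    f"{self.library_id}: terms with genes outside the universe: {sorted(stray)[:5]}"
                )

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.terms):
                desc, genes = self.terms[term]
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


@dataclass
class EnrichmentTable:
    """Per-term enrichment results, sorted by p ascending."""

    library_id: str
    query_size: int
    universe_size: int
    table: pd.DataFrame

    def significant_terms(self) -> list:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["genes"] = out["overlap_genes"].map(lambda gs: ",".join(sorted(gs)))
        out = out[["overlap_count", "term_size", "p_value", "p_adjusted", "significant", "genes"]]
        out = out.rename(
            columns={"overlap_count": "overlap", "p_value": "p", "p_adjusted": "p_adj"}
        )
        out.to_csv(path, sep="\t", index_label="term")


def read_gmt(path, library_id: str | None = None) -> GeneSetLibrary:
    """Parse a standard GMT file: ``term<TAB>description<TAB>gene1...``.

    Duplicate genes within a term count once; empty terms are dropped with
    a warning.
    """
    terms = {}
    n_empty = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term, desc = parts[0], parts[1]
            genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
            if not genes:
                n_empty += 1
                continue
            terms[term] = (desc, genes)
    if n_empty:
        logger.warning("%s: dropped %d empty terms", path, n_empty)
    return GeneSetLibrary(library_id or str(path), terms)


def hypergeom_tail(universe_size: int, term_size: int, query_size: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe_size, term_size, query_size)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def enrich(
    query,
    lib: GeneSetLibrary,
    background=None,
    p_threshold: float = 0.05,
    p_criterion: str = "raw",
) -> EnrichmentTable:
    """Hypergeometric over-representation of ``query`` against every term.

    ``background``, when given, replaces the library universe; query and
    terms are both intersected with it before testing. An empty
    query-universe intersection yields an empty table with a warning.
    """
    from diseasome.deg import benjamini_hochberg

    if p_criterion not in ("raw", "adjusted"):
        raise ValidationError("p_criterion must be 'raw' or 'adjusted'")
    query = frozenset(normalize_symbol(g) for g in query)
    universe = lib.universe if background is None else frozenset(
        normalize_symbol(g) for g in background
    )
    if background is not None and not universe:
        raise ValidationError("background universe is empty")
    query_in = query & universe
    columns = ["overlap_genes", "overlap_count", "term_size", "p_value", "p_adjusted", "significant"]
    if not query_in:
        logger.warning("%s: query has no genes in the universe", lib.library_id)
        return EnrichmentTable(lib.library_id, 0, len(universe), pd.DataFrame(columns=columns))

    rows = []
    for term in sorted(lib.terms):
        _, genes = lib.terms[term]
        genes_in = genes & universe
        if not genes_in:
            continue
        overlap = query_in & genes_in
        p = hypergeom_tail(len(universe), len(genes_in), len(query_in), len(overlap))
        rows.append((term, overlap, len(overlap), len(genes_in), p))
    index = [r[0] for r in rows]
    p_values = np.array([r[4] for r in rows])
    p_adj = benjamini_hochberg(p_values)
    p_crit = p_values if p_criterion == "raw" else p_adj
    table = pd.DataFrame(
        {
            "overlap_genes": [r[1] for r in rows],
            "overlap_count": [r[2] for r in rows],
            "term_size": [r[3] for r in rows],
            "p_value": p_values,
            "p_adjusted": p_adj,
            "significant": p_crit <= p_threshold,
        },
        index=pd.Index(index, name="term"),
    ).sort_values(["p_value", "term_size"], kind="mergesort")
    return EnrichmentTable(lib.library_id, len(query_in), len(universe), table)


def validate_against_benchmarks(query, benchmark_libs, target_terms) -> pd.DataFrame:
    """Check whether target disease terms are enriched in benchmark libraries.

    Runs the enrichment per library and reports, for every requested target
    term, whether it is significant there, its p-value and overlap genes.
    Targets absent from a library are marked ``not_testable``.
    """
    query = frozenset(normalize_symbol(g) for g in query)
    rows = []
    if not query:
        logger.warning("empty query for benchmark validation")
    for lib in benchmark_libs:
        result = enrich(query, lib) if query else None
        for target in target_terms:
            if target not in lib.terms:
                rows.append(
                    {
                        "library": lib.library_id,
                        "target": target,
                        "status": "not_testable",
                        "p_value": np.nan,
                        "overlap_genes": "",
                    }
                )
                continue
            if result is None or target not in result.table.index:
                status, p, genes = "not_significant", np.nan, ""
            else:
                row = result.table.loc[target]
                status = "significant" if bool(row["significant"]) else "not_significant"
                p = float(row["p_value"])
                genes = ",".join(sorted(row["overlap_genes"]))
            rows.append(
                {
                    "library": lib.library_id,
                    "target": target,
                    "status": status,
                    "p_value": p,
                    "overlap_genes": genes,
                }
            )
    return pd.DataFrame(rows, columns=["library", "target", "status", "p_value", "overlap_genes"])
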