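"""Synthetic multi-cohort study generator with planted ground truth.

The generator emulates the statistical structure of a multi-disease
case/control microarray compendium on a shared gene universe:

* expression values are Gaussian on the log2 scale (baseline mean 7, noise
  sd 0.5 by default, matching typical log2 microarray intensities and the
  t-test's working assumptions);
* a planted (gene, disease, up) membership adds +effect_size (log2 units,
  default 2) to that gene's case samples, down subtracts it — so the
  planted log2 fold change equals the effect size in expectation and
  recovery targets are analytic;
* cross-disease overlap structure is planted explicitly (a shared core
  dysregulated in every disease plus private genes per disease);
* PPI graphs carry planted hubs whose degrees strictly exceed every
  non-hub degree;
* GMT libraries carry one planted term with a controlled overlap fraction
  with a query list.

Every generator is a pure function of its design and seed; per-disease
random substreams are derived from the root seed and the disease's
position, so adding a disease never reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diseasome.datasets import ExpressionDataset
from diseasome.enrichment import GeneSetLibrary
from diseasome.errors import ValidationError
from diseasome.network import DIRECTIONS, DiseaseGeneSets, jaccard_score, shared_gene_count
from diseasome.ppi import PPINetwork

PLANTED_TERM = "PLANTED_TERM"


def gene_universe(n_genes: int) -> list:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass
class SimulationDesign:
    """Layout of a synthetic multi-disease expression study.

    ``diseases`` lists (disease_id, n_case, n_control); ``planted_membership``
    maps gene symbol -> {disease_id: "up" | "down"}.
    """

    n_genes: int
    diseases: list
    planted_membership: dict
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        ids = [d[0] for d in self.diseases]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate disease ids: {ids}")
        for did, n_case, n_control in self.diseases:
            if n_case < 3 or n_control < 3:
                raise ValidationError(f"{did}: need n_case, n_control >= 3")
        universe = set(gene_universe(self.n_genes))
        for gene, members in self.planted_membership.items():
            if gene not in universe:
                raise ValidationError(f"planted gene {gene!r} outside the universe")
            for did, direction in members.items():
                if did not in ids:
                    raise ValidationError(f"planted disease {did!r} not in design")
                if direction not in ("up", "down"):
                    raise ValidationError(f"direction must be up/down, got {direction!r}")

    def true_sets(self) -> dict:
        """Planted per-disease up/down gene sets."""
        out = {}
        for did, _, _ in self.diseases:
            up = frozenset(
                g for g, m in self.planted_membership.items() if m.get(did) == "up"
            )
            down = frozenset(
                g for g, m in self.planted_membership.items() if m.get(did) == "down"
            )
            out[did] = DiseaseGeneSets(did, up, down)
        return out


@dataclass
class GroundTruth:
    """Planted structure a recovery analysis should reproduce."""

    true_sets: dict = field(default_factory=dict)  # disease -> DiseaseGeneSets
    pair_stats: dict = field(default_factory=dict)  # (d_i, d_j, direction) -> stats
    hubs: list = field(default_factory=list)
    enriched_terms: dict = field(default_factory=dict)  # library -> term


def _pair_stats(true_sets: dict) -> dict:
    stats = {}
    ids = sorted(true_sets)
    for i, di in enumerate(ids):
        for dj in ids[i + 1:]:
            for direction in DIRECTIONS:
                gi = true_sets[di].genes(direction)
                gj = true_sets[dj].genes(direction)
                stats[(di, dj, direction)] = {
                    "n_shared": shared_gene_count(gi, gj),
                    "jaccard": jaccard_score(gi, gj) if (gi or gj) else math.nan,
                }
    return stats


def simulate_expression(design: SimulationDesign):
    """Generate one case/control expression matrix per disease.

    Returns (datasets, ground_truth). Each value is drawn from
    Normal(baseline_mean, noise_sd); planted memberships shift the case
    group of that gene by +/- effect_size. Deterministic given the design
    seed; disease k uses the substream (seed, k).
    """
    genes = gene_universe(design.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    datasets = []
    for k, (did, n_case, n_control) in enumerate(design.diseases):
        rng = np.random.default_rng([design.seed, k])
        n = n_case + n_control
        values = rng.normal(design.baseline_mean, design.noise_sd, size=(design.n_genes, n))
        for gene, members in design.planted_membership.items():
            direction = members.get(did)
            if direction is None:
                continue
            shift = design.effect_size if direction == "up" else -design.effect_size
            values[gene_index[gene], :n_case] += shift
        samples = [f"{did}_case_{i+1}" for i in range(n_case)] + [
            f"{did}_ctrl_{i+1}" for i in range(n_control)
        ]
        groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
        frame = pd.DataFrame(values, index=genes, columns=samples)
        datasets.append(ExpressionDataset(did, frame, groups))
    true_sets = design.true_sets()
    return datasets, GroundTruth(true_sets=true_sets, pair_stats=_pair_stats(true_sets))


def planted_overlap_design(
    n_genes: int = 2000,
    disease_ids=("FOCAL", "RF1", "RF2", "RF3", "RF4"),
    n_case: int = 15,
    n_control: int = 15,
    n_core_up: int = 10,
    n_core_down: int = 10,
    n_private_up: int = 20,
    n_private_down: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    baseline_mean: float = 7.0,
    seed: int = 0,
) -> SimulationDesign:
    """Design with a shared dysregulated core plus private genes per disease.

    The core genes (n_core_up up, n_core_down down) are planted in *every*
    disease, so each disease pair truly shares core_up + core_down genes;
    each disease additionally gets its own private up/down genes. This is
    the canonical test bed for the cross-comparison stages: pairwise shared
    counts and Jaccard scores are known exactly by construction.
    """
    genes = gene_universe(n_genes)
    per_disease = n_private_up + n_private_down
    needed = n_core_up + n_core_down + len(disease_ids) * per_disease
    if needed > n_genes:
        raise ValidationError(f"need {needed} planted genes but universe has {n_genes}")
    rng = np.random.default_rng([seed, 982451653])  # layout substream
    chosen = list(rng.choice(n_genes, size=needed, replace=False))
    core_up = [genes[i] for i in chosen[:n_core_up]]
    core_down = [genes[i] for i in chosen[n_core_up:n_core_up + n_core_down]]
    membership: dict = {}
    for g in core_up:
        membership[g] = {did: "up" for did in disease_ids}
    for g in core_down:
        membership[g] = {did: "down" for did in disease_ids}
    offset = n_core_up + n_core_down
    for did in disease_ids:
        private = [genes[i] for i in chosen[offset:offset + per_disease]]
        offset += per_disease
        for g in private[:n_private_up]:
            membership.setdefault(g, {})[did] = "up"
        for g in private[n_private_up:]:
            membership.setdefault(g, {})[did] = "down"
    return SimulationDesign(
        n_genes=n_genes,
        diseases=[(did, n_case, n_control) for did in disease_ids],
        planted_membership=membership,
        effect_size=effect_size,
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
        seed=seed,
    )


def simulate_ppi(n_nodes: int, n_edges: int, planted_hubs, seed: int = 0, node_names=None):
    """Random simple graph with planted hubs that dominate the degree ranking.

    ``planted_hubs`` is a list of (node_name, min_degree) pairs. Each hub is
    wired to at least its requested degree; filler edges among non-hubs are
    capped strictly below the smallest hub degree, so the top-|hubs| degree
    ranking recovers exactly the planted set. Non-hub nodes take names from
    ``node_names`` when given (e.g., real gene symbols), otherwise P0001....
    Deterministic given the seed.
    """
    planted_hubs = list(planted_hubs)
    hub_names = [h for h, _ in planted_hubs]
    if len(set(hub_names)) != len(hub_names):
        raise ValidationError("duplicate hub names")
    if n_nodes < len(hub_names) + 2:
        raise ValidationError("need at least two non-hub nodes")
    min_degrees = [d for _, d in planted_hubs]
    if planted_hubs:
        if min(min_degrees) < 1:
            raise ValidationError("hub min_degree must be >= 1")
        if max(min_degrees) >= n_nodes:
            raise ValidationError("hub min_degree must be < n_nodes")
        if sum(min_degrees) > 2 * n_edges:
            raise ValidationError("sum of hub degrees exceeds the edge budget")
    rng = np.random.default_rng([seed, 15485863])
    n_non_hubs = n_nodes - len(hub_names)
    if node_names is not None:
        non_hubs = [n for n in node_names if n not in set(hub_names)][:n_non_hubs]
        if len(non_hubs) < n_non_hubs:
            raise ValidationError("node_names does not cover the non-hub nodes")
    else:
        width = max(4, len(str(n_nodes)))
        fillers = [f"P{i:0{width}d}" for i in range(1, n_non_hubs + 1)]
        non_hubs = [f for f in fillers if f not in set(hub_names)]

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(hub_names)
    g.add_nodes_from(non_hubs)

    # round-robin hub attachment over a shuffled non-hub order keeps the
    # attachment load even, so non-hub degrees stay well below hub degrees
    order = list(non_hubs)
    rng.shuffle(order)
    cursor = 0
    for hub, min_degree in planted_hubs:
        if min_degree > len(non_hubs):
            raise ValidationError(f"hub {hub}: min_degree exceeds non-hub count")
        for _ in range(min_degree):
            g.add_edge(hub, order[cursor % len(order)])
            cursor += 1
    if planted_hubs:
        attach_load = max(dict(g.degree(non_hubs)).values())
        cap = min(dict(g.degree(hub_names)).values()) - 1
        if attach_load > cap:
            raise ValidationError("hub degrees too small to dominate non-hub degrees")
    else:
        cap = n_nodes  # unconstrained

    attempts = 0
    while g.number_of_edges() < n_edges and attempts < 50 * n_edges:
        attempts += 1
        a, b = rng.choice(len(non_hubs), size=2, replace=False)
        u, v = non_hubs[a], non_hubs[b]
        if g.has_edge(u, v):
            continue
        if g.degree(u) >= cap or g.degree(v) >= cap:
            continue
        g.add_edge(u, v)
    return PPINetwork(g), GroundTruth(hubs=sorted(hub_names))


def simulate_gmt(
    n_terms: int,
    term_size_range,
    universe,
    planted_term_overlap_fraction: float,
    query,
    seed: int = 0,
):
    """GMT library with one planted term enriched for the query.

    The planted term contains ceil(fraction * |query|) query genes plus
    random fillers drawn outside the query; the other n_terms - 1 terms are
    uniform draws from the universe with sizes in ``term_size_range``.
    """
    universe = sorted({str(g).upper() for g in universe})
    query = sorted({str(g).upper() for g in query})
    if not set(query) <= set(universe):
        raise ValidationError("query must be contained in the universe")
    if not 0 < planted_term_overlap_fraction <= 1:
        raise ValidationError("overlap fraction must be in (0, 1]")
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValidationError("term size exceeds universe size")
    if lo < 1 or lo > hi:
        raise ValidationError("invalid term size range")
    rng = np.random.default_rng([seed, 32452843])
    n_overlap = math.ceil(planted_term_overlap_fraction * len(query))
    overlap = list(rng.choice(query, size=n_overlap, replace=False))
    size = int(rng.integers(lo, hi + 1))
    size = max(size, n_overlap)
    outside = sorted(set(universe) - set(query))
    n_fill = min(size - n_overlap, len(outside))
    fillers = list(rng.choice(outside, size=n_fill, replace=False)) if n_fill else []
    terms = {PLANTED_TERM: ("planted enriched term", frozenset(overlap) | frozenset(fillers))}
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"TERM_{t:04d}"] = (f"random term {t}", frozenset(members))
    lib = GeneSetLibrary(f"synthetic_gmt_seed{seed}", terms, frozenset(universe))
    return lib, GroundTruth(enriched_terms={lib.library_id: PLANTED_TERM})


def write_fixtures(out_dir, seed: int = 0, n_genes: int = 500):
    """Materialise a small demo study (text files) under ``out_dir``.

    Two focal cohorts plus two risk factors on a 500-gene universe, a PPI
    edge list with planted hubs among the shared core genes, a pathway GMT
    with a planted term, a benchmark GMT whose risk-factor terms contain
    the shared genes, and a ready-to-run pipeline config.
    """
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = planted_overlap_design(
        n_genes=n_genes,
        disease_ids=("FOCAL1", "FOCAL2", "RF1", "RF2"),
        n_case=8,
        n_control=8,
        n_core_up=6,
        n_core_down=6,
        n_private_up=10,
        n_private_down=10,
        seed=seed,
    )
    datasets, truth = simulate_expression(design)
    paths = {}
    for ds in datasets:
        mpath = out / f"{ds.disease_id}_expr.tsv"
        gpath = out / f"{ds.disease_id}_groups.tsv"
        ds.values.round(5).to_csv(mpath, sep="\t", index_label="gene_id")
        with open(gpath, "w", encoding="utf-8") as fh:
            for s in ds.sample_ids:
                fh.write(f"{s}\t{ds.groups[s]}\n")
        paths[ds.disease_id] = (mpath, gpath)

    # PPI over the shared core genes so restriction to shared DEGs keeps it
    core = sorted(
        truth.true_sets["FOCAL1"].all_genes & truth.true_sets["RF1"].all_genes
    )
    hubs = [(g, 6) for g in core[:3]]
    ppi, ppi_truth = simulate_ppi(
        n_nodes=len(core), n_edges=28, planted_hubs=hubs, seed=seed, node_names=core[3:]
    )
    ppi_path = out / "ppi_edges.tsv"
    with open(ppi_path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{u}\t{v}\n")

    universe = gene_universe(n_genes)
    query = sorted(truth.true_sets["FOCAL1"].all_genes)
    pathways, _ = simulate_gmt(
        n_terms=40,
        term_size_range=(10, 30),
        universe=universe,
        planted_term_overlap_fraction=0.8,
        query=query,
        seed=seed,
    )
    pathway_path = out / "pathways.gmt"
    pathways.to_gmt(pathway_path)

    # benchmark library: one disease term per risk factor holding most of the
    # genes that risk factor shares with the focal core
    rng = np.random.default_rng([seed, 49979687])
    bench_terms = {}
    for rf in ("RF1", "RF2"):
        shared = sorted(truth.true_sets[rf].all_genes & truth.true_sets["FOCAL1"].all_genes)
        fill = list(rng.choice(sorted(set(universe) - set(shared)), size=10, replace=False))
        bench_terms[rf] = (f"benchmark disease term for {rf}", frozenset(shared) | frozenset(fill))
    for t in range(8):
        members = rng.choice(universe, size=15, replace=False)
        bench_terms[f"OTHER_{t}"] = (f"unrelated disease {t}", frozenset(members))
    bench = GeneSetLibrary("benchmark", bench_terms, frozenset(universe))
    bench_path = out / "benchmark.gmt"
    bench.to_gmt(bench_path)

    config = {
        "focal": {
            "combined_id": "FOCAL",
            "cohorts": [
                {"id": did, "matrix": str(paths[did][0]), "groups": str(paths[did][1])}
                for did in ("FOCAL1", "FOCAL2")
            ],
        },
        "risk_factors": [
            {"id": did, "matrix": str(paths[did][0]), "groups": str(paths[did][1])}
            for did in ("RF1", "RF2")
        ],
        "preprocess": {"log2_policy": "never", "zscore_ddof": 1},
        "deg": {"p_threshold": 0.05, "logfc_threshold": 1.0, "p_criterion": "raw"},
        "enrichment": {"p_threshold": 0.05, "p_criterion": "raw"},
        "ppi_edge_list": str(ppi_path),
        "libraries": {
            "pathways": [str(pathway_path)],
            "benchmarks": [str(bench_path)],
        },
        "benchmark_targets": ["RF1", "RF2"],
        "hub_k": 3,
        "min_shared_diseases": 2,
        "output_dir": str(out / "results"),
        "seed": seed,
    }
    config_path = out / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return {
        "config": config_path,
        "design": design,
        "truth": truth,
        "ppi_truth": ppi_truth,
        "ppi": ppi_path,
    }
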