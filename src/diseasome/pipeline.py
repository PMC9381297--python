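"""Configuration-driven orchestration of the full analysis.

Stage order: preprocess -> per-disease DEG calling -> focal-cohort
combination -> diseasome construction -> PPI hub ranking -> enrichment
(pathways / ontologies) -> benchmark validation. Stages whose inputs are
absent from the config (no PPI file, no GMT libraries) are skipped with a
notice in the manifest. All outputs are plain-text tables and GraphML; a
run is fully deterministic given its config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from diseasome.datasets import read_expression
from diseasome.deg import DEGConfig, call_degs, deg_sets
from diseasome.enrichment import read_gmt, enrich, validate_against_benchmarks
from diseasome.errors import InputError, ValidationError
from diseasome.network import build_diseasome, combine_focal_datasets, membership_patterns
from diseasome.ppi import induced_subnetwork, read_edge_list, top_hubs
from diseasome.preprocess import PreprocessConfig, preprocess, zscore_rows

logger = logging.getLogger(__name__)

STAGES = (
    "preprocess",
    "deg",
    "combine_focal",
    "diseasome",
    "ppi_hubs",
    "enrichment",
    "validation",
)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    focal_combined_id: str
    focal_cohorts: list  # [{id, matrix, groups}]
    risk_factors: list  # [{id, matrix, groups}]
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    enrichment_p_threshold: float = 0.05
    enrichment_p_criterion: str = "raw"
    ppi_edge_list: str | None = None
    ppi_score_threshold: float | None = None
    libraries: dict = field(default_factory=dict)  # kind -> [gmt paths]
    benchmark_targets: list = field(default_factory=list)
    hub_k: int = 10
    min_shared_diseases: int = 3
    output_dir: str = "diseasome_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.focal_cohorts:
            raise ValidationError("need >=1 focal cohort")
        if not self.risk_factors:
            raise ValidationError("need >=1 risk factor")
        ids = [c["id"] for c in self.focal_cohorts] + [r["id"] for r in self.risk_factors]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate disease ids: {ids}")
        for entry in self.focal_cohorts + self.risk_factors:
            for key in ("matrix", "groups"):
                if not Path(entry[key]).exists():
                    raise InputError(f"{entry['id']}: missing file {entry[key]}")
        if self.ppi_edge_list and not Path(self.ppi_edge_list).exists():
            raise InputError(f"missing PPI edge list {self.ppi_edge_list}")
        for kind, paths in self.libraries.items():
            for p in paths:
                if not Path(p).exists():
                    raise InputError(f"missing {kind} library {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        focal = raw["focal"]
        enr = raw.get("enrichment", {})
        return cls(
            focal_combined_id=focal.get("combined_id", "FOCAL"),
            focal_cohorts=focal["cohorts"],
            risk_factors=raw["risk_factors"],
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            deg=DEGConfig(**raw.get("deg", {})),
            enrichment_p_threshold=enr.get("p_threshold", 0.05),
            enrichment_p_criterion=enr.get("p_criterion", "raw"),
            ppi_edge_list=raw.get("ppi_edge_list"),
            ppi_score_threshold=raw.get("ppi_score_threshold"),
            libraries=raw.get("libraries", {}),
            benchmark_targets=raw.get("benchmark_targets", []),
            hub_k=raw.get("hub_k", 10),
            min_shared_diseases=raw.get("min_shared_diseases", 3),
            output_dir=raw.get("output_dir", "diseasome_out"),
            seed=raw.get("seed", 0),
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "focal": {"combined_id": self.focal_combined_id, "cohorts": self.focal_cohorts},
            "risk_factors": self.risk_factors,
            "preprocess": asdict(self.preprocess),
            "deg": asdict(self.deg),
            "enrichment": {
                "p_threshold": self.enrichment_p_threshold,
                "p_criterion": self.enrichment_p_criterion,
            },
            "ppi_edge_list": self.ppi_edge_list,
            "ppi_score_threshold": self.ppi_score_threshold,
            "libraries": self.libraries,
            "benchmark_targets": self.benchmark_targets,
            "hub_k": self.hub_k,
            "min_shared_diseases": self.min_shared_diseases,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


def _line_count(path) -> int:
    with open(path, encoding="utf-8") as fh:
        return sum(1 for _ in fh)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every applicable stage and return the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "counts": {}}
    resolved = cfg.to_dict()
    config_text = yaml.safe_dump(resolved, sort_keys=True)
    (out / "resolved_config.yaml").write_text(config_text, encoding="utf-8")
    manifest["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()

    import diseasome

    manifest["versions"] = {"diseasome": diseasome.__version__, "pandas": pd.__version__}

    current = None
    try:
        # ---- preprocess + DEG per disease -------------------------------
        current = "preprocess"
        cohorts = []
        for entry in cfg.focal_cohorts + cfg.risk_factors:
            ds = read_expression(entry["matrix"], entry["groups"], entry["id"])
            manifest["counts"].setdefault("raw_genes", {})[entry["id"]] = ds.shape[0]
            ds = preprocess(ds, cfg.preprocess)
            z = zscore_rows(ds, cfg.preprocess.zscore_ddof)
            manifest["counts"].setdefault("zscored_genes", {})[entry["id"]] = z.shape[0]
            cohorts.append(ds)
        manifest["stages"]["preprocess"] = "completed"

        current = "deg"
        deg_dir = out / "deg"
        deg_dir.mkdir(exist_ok=True)
        sets_by_id = {}
        summary_rows = []
        for ds in cohorts:
            table = call_degs(ds, cfg.deg)
            path = deg_dir / f"{ds.disease_id}.tsv"
            table.to_tsv(path)
            manifest["outputs"][f"deg/{ds.disease_id}"] = str(path)
            gs = deg_sets(table)
            sets_by_id[ds.disease_id] = gs
            summary_rows.append(
                {
                    "disease": ds.disease_id,
                    "n_genes": ds.shape[0],
                    "n_up": len(gs.up_genes),
                    "n_down": len(gs.down_genes),
                    "n_degs": len(gs.up_genes) + len(gs.down_genes),
                }
            )
        manifest["stages"]["deg"] = "completed"

        current = "combine_focal"
        focal_ids = [c["id"] for c in cfg.focal_cohorts]
        focal = combine_focal_datasets(
            [sets_by_id[i] for i in focal_ids], cfg.focal_combined_id
        )
        focal_path = out / "focal_sets.tsv"
        with open(focal_path, "w", encoding="utf-8") as fh:
            fh.write("gene\tdirection\n")
            for g in sorted(focal.up_genes):
                fh.write(f"{g}\tup\n")
            for g in sorted(focal.down_genes):
                fh.write(f"{g}\tdown\n")
            for g in sorted(focal.conflicted):
                fh.write(f"{g}\tconflicted\n")
        manifest["outputs"]["focal_sets"] = str(focal_path)
        manifest["counts"]["focal_conflicted"] = len(focal.conflicted)
        summary_rows.append(
            {
                "disease": focal.disease_id,
                "n_genes": max(r["n_genes"] for r in summary_rows),
                "n_up": len(focal.up_genes),
                "n_down": len(focal.down_genes),
                "n_degs": len(focal.all_genes),
            }
        )
        manifest["stages"]["combine_focal"] = "completed"

        current = "diseasome"
        risk_sets = [sets_by_id[r["id"]] for r in cfg.risk_factors]
        net = build_diseasome(focal, risk_sets)
        net.to_graphml(out / "diseasome.graphml")
        net.to_sif(out / "diseasome.sif")
        pair_frame = net.pair_stats_frame()
        pair_frame.to_csv(out / "pair_stats.tsv", sep="\t", index=False)
        patterns = membership_patterns(net, cfg.min_shared_diseases)
        with open(out / "membership_patterns.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tdirection\tn_diseases\tdiseases\n")
            for gene, direction, diseases in patterns:
                fh.write(f"{gene}\t{direction}\t{len(diseases)}\t{','.join(diseases)}\n")
        for name in ("diseasome.graphml", "diseasome.sif", "pair_stats.tsv", "membership_patterns.tsv"):
            manifest["outputs"][name] = str(out / name)
        manifest["counts"]["shared_genes"] = len(net.gene_nodes)
        manifest["counts"]["bipartite_edges"] = len(net.bipartite_edges)
        manifest["stages"]["diseasome"] = "completed"
        shared_degs = set(net.gene_nodes)

        current = "ppi_hubs"
        if cfg.ppi_edge_list:
            ppi = read_edge_list(cfg.ppi_edge_list, cfg.ppi_score_threshold)
            sub = induced_subnetwork(ppi, shared_degs)
            report = top_hubs(sub, cfg.hub_k)
            report.to_tsv(out / "hubs.tsv")
            # annotate each protein with the risk factors whose shared-DEG
            # list contains it (cluster membership in the network export)
            annotations = {}
            for node in sub.nodes:
                members = [
                    rs.disease_id for rs in risk_sets if node in rs.all_genes
                ]
                annotations[node] = {"risk_factors": ",".join(sorted(members))}
            sub.to_graphml(out / "ppi_subnetwork.graphml", annotations)
            manifest["outputs"]["hubs"] = str(out / "hubs.tsv")
            manifest["outputs"]["ppi_subnetwork"] = str(out / "ppi_subnetwork.graphml")
            manifest["counts"]["ppi_nodes"] = len(sub.nodes)
            manifest["counts"]["ppi_edges"] = sub.n_edges
            manifest["stages"]["ppi_hubs"] = "completed"
        else:
            logger.info("no PPI edge list configured; skipping hub stage")
            manifest["stages"]["ppi_hubs"] = "skipped (no PPI edge list)"

        current = "enrichment"
        enrichable = {k: v for k, v in cfg.libraries.items() if k != "benchmarks" and v}
        if enrichable and shared_degs:
            for kind, paths in sorted(enrichable.items()):
                for p in paths:
                    lib = read_gmt(p)
                    result = enrich(
                        shared_degs,
                        lib,
                        p_threshold=cfg.enrichment_p_threshold,
                        p_criterion=cfg.enrichment_p_criterion,
                    )
                    name = f"enrich_{kind}_{Path(p).stem}.tsv"
                    result.to_tsv(out / name)
                    manifest["outputs"][name] = str(out / name)
                    manifest["counts"][f"significant_{kind}_{Path(p).stem}"] = len(
                        result.significant_terms()
                    )
            manifest["stages"]["enrichment"] = "completed"
        else:
            manifest["stages"]["enrichment"] = "skipped (no pathway/ontology libraries)"

        current = "validation"
        bench_paths = cfg.libraries.get("benchmarks", [])
        if bench_paths and cfg.benchmark_targets:
            libs = [read_gmt(p) for p in bench_paths]
            report = validate_against_benchmarks(shared_degs, libs, cfg.benchmark_targets)
            report.to_csv(out / "validation.tsv", sep="\t", index=False)
            manifest["outputs"]["validation"] = str(out / "validation.tsv")
            manifest["stages"]["validation"] = "completed"
        else:
            manifest["stages"]["validation"] = "skipped (no benchmark libraries/targets)"

        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest["outputs"]["summary"] = str(out / "summary.tsv")
        manifest["outputs"]["pair_stats"] = str(out / "pair_stats.tsv")
        manifest["counts"]["summary_rows"] = _line_count(out / "summary.tsv") - 1
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / f"{current}.txt").write_text(f"{type(exc).__name__}: {exc}\n")
        raise type(exc)(f"stage {current!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize(manifest: dict) -> dict:
    """Load the per-disease and per-pair summary tables of a completed run."""
    per_disease = pd.read_csv(manifest["outputs"]["summary"], sep="\t")
    pairs = pd.read_csv(manifest["outputs"]["pair_stats"], sep="\t")
    return {"per_disease": per_disease, "pairs": pairs}
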