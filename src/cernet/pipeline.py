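"""End-to-end orchestration: DE screen -> correlation -> database
cross-reference -> network assembly -> centrality/pivotal screen -> clinical
screen -> optional enrichment, with every intermediate written as TSV and a
JSON run manifest recording config, seed, versions and per-stage counts.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .correlate import all_pairs_correlation, clinical_screen
from .de import de_filter, differential_expression, sample_separation_report
from .enrich import overrepresentation
from .io import (
    ClinicalTable,
    ExpressionTable,
    InteractionTable,
    SampleGroups,
    read_clinical_table,
    read_expression_table,
    read_gmt,
    read_interaction_table,
    read_sample_groups,
    write_clinical_table,
    write_expression_table,
    write_interaction_table,
    write_network,
    write_sample_groups,
)
from .network import (
    assemble_network,
    centrality_table,
    cross_reference,
    pivotal_screen,
)
from .simulate import SimulationConfig, generate_dataset, truth_report

CLASS_PAIRS = (("lncRNA", "miRNA"), ("miRNA", "mRNA"), ("lncRNA", "mRNA"))


@dataclass
class PipelineConfig:
    """Inputs, thresholds and flags for one pipeline run."""

    out_dir: str = "cernet_run"
    # synthetic mode: generate inputs from this seed instead of reading paths
    synthetic: bool = True
    seed: int = 0
    # input paths (ignored in synthetic mode)
    lncrna_path: str | None = None
    mirna_path: str | None = None
    mrna_path: str | None = None
    groups_path: str | None = None
    interactions_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    # DE thresholds
    log2fc_min: float = 1.0
    p_max: float = 0.05
    q_max: float = 0.05
    pseudocount: float = 0.25
    # gene-gene correlation thresholds (|r| >= r_min_gene, inclusive)
    r_min_gene: float = 0.8
    p_max_corr: float = 0.05
    # clinical screen thresholds (|r| > r_min_clinical, strict)
    r_min_clinical: float = 0.8
    p_max_clinical: float = 0.05
    # network options
    sign_filter: bool = True
    k_pivotal: int = 10
    cases_only_correlation: bool = False

    def __post_init__(self) -> None:
        for name in ("p_max", "q_max", "p_max_corr", "p_max_clinical"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("r_min_gene", "r_min_clinical"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k_pivotal < 1:
            raise ValueError("k_pivotal must be >= 1")
        if not self.synthetic:
            for name in (
                "lncrna_path",
                "mirna_path",
                "mrna_path",
                "groups_path",
                "interactions_path",
            ):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} is required when synthetic=False")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    run_dir: Path
    manifest: dict
    de_records: pd.DataFrame
    de_passing: pd.DataFrame
    correlation_edges: pd.DataFrame
    network_edges: pd.DataFrame
    graph: nx.Graph
    centralities: pd.DataFrame
    pivotal: set[str]
    clinical_correlations: pd.DataFrame
    separation: dict
    enrichment: pd.DataFrame | None
    truth: object | None = None


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage, writing intermediates and a manifest to out_dir."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cernet",
        "versions": {
            "cernet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
        },
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    collected: list[str] = []

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts

    truth = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # 1. inputs
        if config.synthetic:
            dataset = generate_dataset(SimulationConfig(seed=config.seed))
            tables = dataset.tables
            groups = dataset.groups
            interactions = dataset.interactions
            clinical = dataset.clinical
            truth = dataset.truth
            for cls, table in tables.items():
                write_expression_table(table, run_dir / f"input_{cls}.tsv")
            write_sample_groups(groups, run_dir / "input_groups.tsv")
            write_interaction_table(interactions, run_dir / "input_interactions.tsv")
            write_clinical_table(clinical, run_dir / "input_clinical.tsv")
            truth_report(truth, run_dir / "ground_truth.tsv")
        else:
            tables = {
                "lncRNA": read_expression_table(config.lncrna_path, "lncRNA", "FPKM"),
                "miRNA": read_expression_table(config.mirna_path, "miRNA", "RPM"),
                "mRNA": read_expression_table(config.mrna_path, "mRNA", "FPKM"),
            }
            groups = read_sample_groups(config.groups_path)
            interactions = read_interaction_table(config.interactions_path)
            clinical = (
                read_clinical_table(config.clinical_path)
                if config.clinical_path
                else None
            )
        stage(
            "input",
            genes={cls: len(t.gene_ids) for cls, t in tables.items()},
            samples=len(next(iter(tables.values())).sample_ids),
            interactions=len(interactions),
        )

        # 2. differential expression
        de_frames = [
            differential_expression(tables[cls], groups, config.pseudocount)
            for cls in ("lncRNA", "miRNA", "mRNA")
        ]
        de_records = pd.concat(de_frames, ignore_index=True)
        de_passing, de_summary = de_filter(
            de_records, config.log2fc_min, config.p_max, config.q_max
        )
        for frame, cls in zip(de_frames, ("lncRNA", "miRNA", "mRNA")):
            _write(frame, run_dir / f"de_{cls}.tsv")
        _write(de_passing, run_dir / "de_passing.tsv")
        _write(de_summary, run_dir / "de_summary.tsv")
        stage("differential_expression", tested=len(de_records), passing=len(de_passing))

        # 3. sample separation on the DE signature
        de_tables = {
            cls: tables[cls].restrict_genes(
                de_passing.loc[de_passing["rna_class"] == cls, "gene_id"]
            )
            for cls in tables
        }
        separation = {}
        sep_rows = []
        for cls, table in de_tables.items():
            if len(table.gene_ids) == 0:
                continue
            rep = sample_separation_report({cls: table}, groups, config.pseudocount)
            separation.update(rep)
            sep_rows.append({"rna_class": cls, "ari": rep[cls].ari})
        _write(pd.DataFrame(sep_rows, columns=["rna_class", "ari"]),
               run_dir / "separation.tsv")
        stage("sample_separation", classes=len(sep_rows))

        # 4. pairwise correlation between DE genes of different classes
        if config.cases_only_correlation:
            case_ids = groups.case_ids
            corr_tables = {
                cls: ExpressionTable(
                    t.data[[s for s in t.sample_ids if s in case_ids]],
                    t.rna_class,
                    t.unit,
                )
                for cls, t in de_tables.items()
            }
        else:
            corr_tables = de_tables
        edge_frames = []
        for ca, cb in CLASS_PAIRS:
            if corr_tables[ca].gene_ids and corr_tables[cb].gene_ids:
                edge_frames.append(
                    all_pairs_correlation(
                        corr_tables[ca],
                        corr_tables[cb],
                        config.r_min_gene,
                        config.p_max_corr,
                    )
                )
        correlation_edges = (
            pd.concat(edge_frames, ignore_index=True)
            if edge_frames
            else pd.DataFrame(
                columns=["gene_a", "class_a", "gene_b", "class_b", "r", "p_value", "n_used"]
            )
        )
        _write(correlation_edges, run_dir / "correlation_edges.tsv")
        stage("correlation", edges=len(correlation_edges))

        # 5. cross-reference with the interaction database
        network_edges = cross_reference(correlation_edges, interactions)
        _write(network_edges, run_dir / "network_edges.tsv")
        stage("cross_reference", edges=len(network_edges))

        # 6. network assembly, centralities, pivotal screen
        graph = assemble_network(network_edges, de_records, config.sign_filter)
        write_network(graph, run_dir / "network.sif", "sif")
        write_network(graph, run_dir / "network.graphml", "graphml")
        centralities = centrality_table(graph)
        _write(centralities, run_dir / "centrality.tsv")
        pivotal = pivotal_screen(centralities, config.k_pivotal)
        _write(
            pd.DataFrame({"node": sorted(pivotal.members)}),
            run_dir / "pivotal.tsv",
        )
        venn_rows = [
            {"metric": metric, "nodes": ",".join(sorted(nodes))}
            for metric, nodes in pivotal.top_by_metric.items()
        ]
        _write(pd.DataFrame(venn_rows, columns=["metric", "nodes"]),
               run_dir / "venn.tsv")
        stage(
            "network",
            nodes=graph.number_of_nodes(),
            edges=graph.number_of_edges(),
            pivotal=len(pivotal.members),
        )

        # 7. clinical screen over network genes
        if clinical is not None and graph.number_of_nodes() > 0:
            clinical_corr = clinical_screen(
                graph.nodes,
                tables,
                clinical,
                config.r_min_clinical,
                config.p_max_clinical,
            )
        else:
            clinical_corr = pd.DataFrame(
                columns=["gene_id", "parameter", "r", "p_value", "n_used"]
            )
        _write(clinical_corr, run_dir / "clinical_correlations.tsv")
        stage("clinical_screen", correlations=len(clinical_corr))

        # 8. optional enrichment of network mRNAs
        enrichment = None
        if config.gmt_path:
            gene_sets = read_gmt(config.gmt_path)
            universe = [g for t in tables.values() for g in t.gene_ids]
            query = [
                v for v, d in graph.nodes(data=True) if d.get("rna_class") == "mRNA"
            ]
            if query:
                enrichment = overrepresentation(query, gene_sets, universe)
                _write(enrichment, run_dir / "enrichment.tsv")
            stage("enrichment", sets=len(gene_sets), query=len(query))
        else:
            stage("enrichment", skipped=True)

        collected = [str(w.message) for w in caught]

    if len(de_passing) == 0:
        collected.append("no genes passed the DE filter; downstream outputs are empty")
    manifest["warnings"] = collected
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        run_dir=run_dir,
        manifest=manifest,
        de_records=de_records,
        de_passing=de_passing,
        correlation_edges=correlation_edges,
        network_edges=network_edges,
        graph=graph,
        centralities=centralities,
        pivotal=pivotal.members,
        clinical_correlations=clinical_corr,
        separation=separation,
        enrichment=enrichment,
        truth=truth,
    )
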