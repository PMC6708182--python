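"""In-memory evaluation of the full inference chain against planted truth.

Runs generate -> DE screen -> correlation -> cross-reference -> assembly ->
centrality -> pivotal screen -> clinical screen for one or many seeds without
touching disk, and scores each stage against the generator's ground truth.
Used by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .correlate import all_pairs_correlation, clinical_screen
from .de import de_filter, differential_expression, sample_separation_report
from .io import pair_class_for
from .network import assemble_network, centrality_table, cross_reference, pivotal_screen
from .pipeline import CLASS_PAIRS
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset


@dataclass
class ChainScore:
    """Truth-referenced outcome of one simulated run."""

    seed: int
    n_planted: int
    n_planted_passing: int
    n_null: int
    n_null_passing: int
    edge_set_equal: bool
    hub_in_pivotal: bool
    ari: dict[str, float]
    clinical_recovered: bool
    n_network_nodes: int
    n_network_edges: int


def run_chain(
    config: SimulationConfig,
    log2fc_min: float = 1.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
    r_min: float = 0.8,
    p_max_corr: float = 0.05,
    k: int = 10,
    sign_filter: bool = True,
) -> tuple[SyntheticDataset, ChainScore]:
    """Run the full chain on one synthetic dataset and score it."""
    dataset = generate_dataset(config)
    truth = dataset.truth

    de_records = pd.concat(
        [
            differential_expression(table, dataset.groups)
            for table in dataset.tables.values()
        ],
        ignore_index=True,
    )
    passing, _ = de_filter(de_records, log2fc_min, p_max, q_max)
    passing_ids = set(passing["gene_id"])

    planted = set(truth.de_genes)
    all_ids = {g for t in dataset.tables.values() for g in t.gene_ids}
    nulls = all_ids - planted

    de_tables = {
        cls: table.restrict_genes(
            passing.loc[passing["rna_class"] == cls, "gene_id"]
        )
        for cls, table in dataset.tables.items()
    }
    frames = [
        all_pairs_correlation(de_tables[a], de_tables[b], r_min, p_max_corr)
        for a, b in CLASS_PAIRS
        if de_tables[a].gene_ids and de_tables[b].gene_ids
    ]
    corr_edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["gene_a", "class_a", "gene_b", "class_b", "r", "p_value", "n_used"]
        )
    )
    survived = cross_reference(corr_edges, dataset.interactions)
    graph = assemble_network(survived, de_records, sign_filter)
    pivotal = pivotal_screen(centrality_table(graph), k)

    surviving_set = {
        (frozenset({row.gene_a, row.gene_b}), pair_class_for(row.class_a, row.class_b))
        for row in survived.itertuples()
    }

    separation = sample_separation_report(
        {cls: t for cls, t in de_tables.items() if t.gene_ids}, dataset.groups
    )

    clinical_hits = clinical_screen(
        graph.nodes, dataset.tables, dataset.clinical
    )
    hit_pairs = set(zip(clinical_hits["gene_id"], clinical_hits["parameter"]))
    clinical_ok = all(
        (gene, param) in hit_pairs for gene, param, _ in truth.clinical
    ) if truth.clinical else True

    score = ChainScore(
        seed=config.seed,
        n_planted=len(planted),
        n_planted_passing=len(planted & passing_ids),
        n_null=len(nulls),
        n_null_passing=len(nulls & passing_ids),
        edge_set_equal=surviving_set == truth.edge_set,
        hub_in_pivotal=(truth.hub in pivotal.members) if truth.hub else False,
        ari={cls: rep.ari for cls, rep in separation.items()},
        clinical_recovered=clinical_ok,
        n_network_nodes=graph.number_of_nodes(),
        n_network_edges=graph.number_of_edges(),
    )
    return dataset, score


def recovery_rates(
    base_seed: int, n_seeds: int, config: SimulationConfig | None = None, **chain_kwargs
) -> dict:
    """Aggregate ChainScores over seeds base_seed .. base_seed + n_seeds - 1."""
    template = config if config is not None else SimulationConfig()
    scores = []
    for i in range(n_seeds):
        cfg = replace(template, seed=base_seed + i)
        _, score = run_chain(cfg, **chain_kwargs)
        scores.append(score)
    n_pl = sum(s.n_planted for s in scores)
    n_nu = sum(s.n_null for s in scores)
    return {
        "n_seeds": n_seeds,
        "planted_pass_rate": sum(s.n_planted_passing for s in scores) / max(n_pl, 1),
        "null_pass_rate": sum(s.n_null_passing for s in scores) / max(n_nu, 1),
        "edge_set_equal_rate": sum(s.edge_set_equal for s in scores) / n_seeds,
        "hub_pivotal_rate": sum(s.hub_in_pivotal for s in scores) / n_seeds,
        "ari_perfect_rate": sum(
            all(v == 1.0 for v in s.ari.values()) and bool(s.ari) for s in scores
        )
        / n_seeds,
        "clinical_recovery_rate": sum(s.clinical_recovered for s in scores) / n_seeds,
        "scores": scores,
    }
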