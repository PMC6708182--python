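"""Normalization, differential-expression filtering and sample-separation
reporting.

The differential test is a two-sided Welch t on log2(x + pseudocount) with
Benjamini-Hochberg adjustment within each RNA class; the fold change is the
log2 ratio of (pseudocounted) group means on the abundance scale. The
screening rule keeps genes with |log2 FC| >= 1, P <= 0.05 and FDR <= 0.05,
all boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable, SampleGroups

DE_COLUMNS = [
    "gene_id",
    "rna_class",
    "mean_case",
    "mean_control",
    "log2fc",
    "p_value",
    "q_value",
    "direction",
    "degenerate",
]


def fpkm(counts, transcript_length_bp, total_mapped):
    """Fragments per kilobase of exon per million mapped reads.

    ``counts * 1e9 / (transcript_length_bp * total_mapped)``; accepts scalars
    or arrays.
    """
    length = np.asarray(transcript_length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(length <= 0):
        raise ValueError("transcript length must be positive")
    if np.any(total <= 0):
        raise ValueError("total mapped reads must be positive")
    out = np.asarray(counts, dtype=float) * 1e9 / (length * total)
    return float(out) if out.ndim == 0 else out


def rpm(counts, total_mapped):
    """Reads per million mapped reads: ``counts * 1e6 / total_mapped``."""
    total = np.asarray(total_mapped, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total mapped reads must be positive")
    out = np.asarray(counts, dtype=float) * 1e6 / total
    return float(out) if out.ndim == 0 else out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    table: ExpressionTable, groups: SampleGroups, pseudocount: float = 0.25
) -> pd.DataFrame:
    """Per-gene Welch t test and fold change between case and control.

    Genes with zero within-group variance on the log scale are flagged
    ``degenerate``: their variance is floored at machine tolerance, so two
    identical groups give t = 0 and p = 1 rather than NaN.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    case_ids = [s for s in table.sample_ids if groups.mapping.get(s) == "case"]
    ctrl_ids = [s for s in table.sample_ids if groups.mapping.get(s) == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need >= 2 samples per group")
    case = table.data[case_ids].to_numpy()
    ctrl = table.data[ctrl_ids].to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]

    # written as a difference of logs so swapping the groups negates it exactly
    log2fc = np.log2(case.mean(axis=1) + pseudocount) - np.log2(
        ctrl.mean(axis=1) + pseudocount
    )

    lc = np.log2(case + pseudocount)
    lt = np.log2(ctrl + pseudocount)
    m1, m2 = lc.mean(axis=1), lt.mean(axis=1)
    v1, v2 = lc.var(axis=1, ddof=1), lt.var(axis=1, ddof=1)
    degenerate = (v1 <= 0) & (v2 <= 0)
    # variance floor keeps degenerate genes defined instead of NaN
    floor = np.finfo(float).eps
    v1f, v2f = np.maximum(v1, floor), np.maximum(v2, floor)
    se2 = v1f / n1 + v2f / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1f / n1) ** 2 / (n1 - 1) + (v2f / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "rna_class": table.rna_class,
            "mean_case": case.mean(axis=1),
            "mean_control": ctrl.mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "direction": np.where(log2fc > 0, "up", "down"),
            "degenerate": degenerate,
        },
        columns=DE_COLUMNS,
    )


def de_filter(
    records: pd.DataFrame,
    log2fc_min: float = 1.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the DE screen (inclusive boundaries) and summarize counts.

    Returns the passing records and an up/down count summary per RNA class.
    """
    if log2fc_min <= 0 or p_max < 0 or q_max < 0:
        raise ValueError("log2fc_min must be positive, p/q thresholds non-negative")
    if records.empty:
        passing = records.copy()
    else:
        mask = (
            (records["log2fc"].abs() >= log2fc_min)
            & (records["p_value"] <= p_max)
            & (records["q_value"] <= q_max)
        )
        passing = records[mask].copy()
    rows = []
    for cls in sorted(set(records["rna_class"])) if not records.empty else []:
        sub = passing[passing["rna_class"] == cls]
        rows.append(
            {
                "rna_class": cls,
                "n_up": int((sub["direction"] == "up").sum()),
                "n_down": int((sub["direction"] == "down").sum()),
                "n_total": len(sub),
            }
        )
    summary = pd.DataFrame(rows, columns=["rna_class", "n_up", "n_down", "n_total"])
    return passing, summary


@dataclass
class ClassSeparation:
    """Sample-separation diagnostics for one RNA class."""

    rna_class: str
    pc_coords: pd.DataFrame  # samples x (PC1, PC2)
    cluster_labels: pd.Series  # 2-cut average-linkage assignment
    ari: float  # agreement of the 2-cluster partition with the groups


def sample_separation_report(
    tables: dict[str, ExpressionTable],
    groups: SampleGroups,
    pseudocount: float = 0.25,
) -> dict[str, ClassSeparation]:
    """PCA coordinates and clustering agreement per RNA class.

    PCA is the singular value decomposition of the gene-centered log2 matrix;
    clustering is average linkage on the 1 - Pearson-r distance between
    samples, cut into two clusters, scored against the true groups with the
    adjusted Rand index.
    """
    out: dict[str, ClassSeparation] = {}
    for cls, table in tables.items():
        samples = table.sample_ids
        if len(samples) < 3:
            raise ValueError("need >= 3 samples for a separation report")
        labels = groups.labels_for(samples)
        x = np.log2(table.data.to_numpy() + pseudocount)
        centered = x - x.mean(axis=1, keepdims=True)

        # sample coordinates on the first two principal axes
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        k = min(2, len(s))
        coords = (vt[:k].T * s[:k])[:, :2]
        if coords.shape[1] < 2:
            coords = np.column_stack([coords, np.zeros(len(samples))])
        pc = pd.DataFrame(coords, index=samples, columns=["PC1", "PC2"])

        if x.shape[0] >= 2:
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(x.T)
            dist = 1.0 - corr
            np.fill_diagonal(dist, 0.0)
            dist = np.nan_to_num(dist, nan=1.0)
            condensed = squareform(np.maximum(dist, 0.0), checks=False)
        else:
            # a single gene carries no between-gene correlation structure;
            # fall back to absolute expression distance
            v = x[0]
            condensed = squareform(
                np.abs(v[:, None] - v[None, :]), checks=False
            )
        lab = fcluster(linkage(condensed, method="average"), 2, criterion="maxclust")
        ari = float(adjusted_rand_score(labels, lab))
        out[cls] = ClassSeparation(
            rna_class=cls,
            pc_coords=pc,
            cluster_labels=pd.Series(lab, index=samples, name="cluster"),
            ari=ari,
        )
    return out
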