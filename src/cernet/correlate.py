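"""Pearson correlation machinery for the gene-gene network stage and the
gene-clinical screen.

Expression vectors are log2(x + pseudocount) transformed before correlating
(the standard scale for co-expression of normalized abundances; it keeps
positive and negative associations symmetric, which the raw lognormal scale
does not). Significance of a sample correlation r at pairwise-complete size
n is the two-sided p of t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees
of freedom. The gene-gene stage keeps pairs with |r| >= r_min (inclusive,
configurable); the clinical screen uses the strict |r| > r_min rule.
Correlations are computed across all samples (cases and controls pooled)
unless the caller restricts the tables. No multiple-testing correction is
applied to either screen.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionTable

EDGE_COLUMNS = ["gene_a", "class_a", "gene_b", "class_b", "r", "p_value", "n_used"]
CLINICAL_COLUMNS = ["gene_id", "parameter", "r", "p_value", "n_used"]


class ConstantInputError(ValueError):
    """A vector with zero variance has no defined correlation."""


def pearson_r(x, y) -> float:
    """Sample Pearson correlation, pairwise-complete over missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector has undefined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a sample Pearson correlation at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(min(1.0, 2.0 * stats.t.sf(t, n - 2)))


def _aligned_matrices(table_a: ExpressionTable, table_b: ExpressionTable):
    shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError("tables share fewer than 3 samples")
    return (
        table_a.data[shared].to_numpy(),
        table_b.data[shared].to_numpy(),
        shared,
    )


def all_pairs_correlation(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    r_min: float = 0.8,
    p_max: float = 0.05,
    pseudocount: float = 0.25,
    log_scale: bool = True,
) -> pd.DataFrame:
    """All cross-table gene pairs with |r| >= r_min and p <= p_max.

    Constant genes are skipped with a warning; self-pairs are excluded when a
    table is correlated against itself.
    """
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie in (0, 1)")
    a, b, shared = _aligned_matrices(table_a, table_b)
    if log_scale:
        a = np.log2(a + pseudocount)
        b = np.log2(b + pseudocount)
    n = len(shared)

    def standardize(mat, table):
        sd = mat.std(axis=1)
        const = sd == 0
        if const.any():
            names = [g for g, c in zip(table.gene_ids, const) if c]
            warnings.warn(
                f"skipping {len(names)} constant gene(s) in {table.rna_class} "
                f"(first: {names[0]})",
                stacklevel=3,
            )
        sd = np.where(const, 1.0, sd)
        return (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None], const

    za, const_a = standardize(a, table_a)
    zb, const_b = standardize(b, table_b)
    r = (za @ zb.T) / n
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(t, n - 2))

    keep = (np.abs(r) >= r_min) & (p <= p_max)
    keep[const_a, :] = False
    keep[:, const_b] = False
    same = table_a.data.index.equals(table_b.data.index) and (
        table_a.rna_class == table_b.rna_class
    )
    rows = []
    genes_a, genes_b = table_a.gene_ids, table_b.gene_ids
    for i, j in np.argwhere(keep):
        if same and genes_a[i] == genes_b[j]:
            continue
        rows.append(
            {
                "gene_a": genes_a[i],
                "class_a": table_a.rna_class,
                "gene_b": genes_b[j],
                "class_b": table_b.rna_class,
                "r": r[i, j],
                "p_value": p[i, j],
                "n_used": n,
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def clinical_screen(
    network_genes,
    tables: dict[str, ExpressionTable],
    clinical: ClinicalTable,
    r_min: float = 0.8,
    p_max: float = 0.05,
    pseudocount: float = 0.25,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Gene x clinical-parameter correlations passing |r| > r_min and p <= p_max.

    Missing clinical values are handled pairwise-complete; a parameter with
    fewer than 3 non-missing samples shared with the expression data is
    skipped with a warning. Results are sorted by |r| descending.
    """
    network_genes = set(network_genes)
    rows = []
    for table in tables.values():
        genes = [g for g in table.gene_ids if g in network_genes]
        if not genes:
            continue
        shared = [s for s in table.sample_ids if s in set(clinical.sample_ids)]
        for param in clinical.parameters:
            values = clinical.data.loc[shared, param].to_numpy()
            ok = np.isfinite(values)
            if ok.sum() < 3:
                warnings.warn(
                    f"skipping clinical parameter {param!r}: "
                    f"fewer than 3 non-missing samples",
                    stacklevel=2,
                )
                continue
            for gene in genes:
                expr = table.data.loc[gene, shared].to_numpy()[ok]
                if log_scale:
                    expr = np.log2(expr + pseudocount)
                vals = values[ok]
                if np.ptp(expr) == 0 or np.ptp(vals) == 0:
                    continue
                r = pearson_r(expr, vals)
                p = pearson_p(r, len(vals))
                if abs(r) > r_min and p <= p_max:
                    rows.append(
                        {
                            "gene_id": gene,
                            "parameter": param,
                            "r": r,
                            "p_value": p,
                            "n_used": len(vals),
                        }
                    )
    out = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    if not out.empty:
        out = (
            out.reindex(out["r"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True)
        )
    return out
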