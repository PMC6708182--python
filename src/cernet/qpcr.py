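"""Relative quantification of qPCR cycle-threshold (CT) measurements by the
2^-ddCT method.

dCT = CT(target) - CT(reference gene); ddCT = dCT(sample) - dCT(calibrator);
relative expression = 2^-ddCT, assuming 100% amplification efficiency. For
cohort comparisons the calibrator is the control-group mean dCT, the per-gene
fold change is the geometric mean over case samples relative to control, and
the group difference is tested with a two-sided Welch t on dCT values.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "group", "gene", "reference_gene", "ct_target", "ct_reference"]
GROUPS = ("case", "control", "calibrator")
SUMMARY_COLUMNS = [
    "gene",
    "n_case",
    "n_control",
    "fold_change",
    "log2_fold_change",
    "p_value",
    "direction",
]


def read_ct_table(path) -> pd.DataFrame:
    """Read a CT table TSV and validate groups and CT ranges."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column {missing[0]!r}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(
            f"{Path(path).name}: unknown group {df['group'][bad].iloc[0]!r}"
        )
    for col in ("ct_target", "ct_reference"):
        values = pd.to_numeric(df[col], errors="coerce")
        out_of_range = ~((values > 0) & (values < 45))
        if out_of_range.any():
            row = int(np.argmax(out_of_range.to_numpy()))
            raise ValueError(
                f"{Path(path).name}: {col} out of (0, 45) at row {row + 2}"
            )
        df[col] = values
    return df[CT_COLUMNS + [c for c in df.columns if c not in CT_COLUMNS]]


def ddct_fold_change(
    ct_t: float, ct_r: float, ct_t_cal: float, ct_r_cal: float
) -> float:
    """2^-ddCT relative expression of a sample against a calibrator."""
    for v in (ct_t, ct_r, ct_t_cal, ct_r_cal):
        if not np.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_t - ct_r) - (ct_t_cal - ct_r_cal)
    return float(2.0 ** (-ddct))


def group_fold_change(records: pd.DataFrame, min_per_group: int = 3) -> pd.DataFrame:
    """Per-gene case-vs-control fold change with a Welch t p-value on dCT.

    The calibrator is the control-group mean dCT, so the reported fold change
    is the geometric-mean case expression relative to control. Genes with
    fewer than ``min_per_group`` records in either group are skipped with a
    warning.
    """
    df = records.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        case = sub.loc[sub["group"] == "case", "dct"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "dct"].to_numpy()
        if len(case) < min_per_group or len(ctrl) < min_per_group:
            warnings.warn(
                f"skipping gene {gene!r}: fewer than {min_per_group} records "
                "per group",
                stacklevel=2,
            )
            continue
        ddct = case.mean() - ctrl.mean()
        fold = float(2.0**-ddct)
        _, p = stats.ttest_ind(case, ctrl, equal_var=False)
        rows.append(
            {
                "gene": gene,
                "n_case": len(case),
                "n_control": len(ctrl),
                "fold_change": fold,
                "log2_fold_change": float(-ddct),
                "p_value": float(p),
                "direction": "up" if fold > 1 else "down",
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
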