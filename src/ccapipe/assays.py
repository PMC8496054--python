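"""Knockdown functional readouts.

Relative expression after siRNA silencing is quantified by the
2^-ddCt method: per condition the replicate-mean Ct of the target is
referenced to a housekeeping gene (dCt), the control condition's dCt is
subtracted (ddCt), and the fold change vs control is 2^-ddCt.
Viability/proliferation readings are normalized to the mean of the
scrambled-control wells.  Gene-by-condition matrices summarize a plate
for heatmap display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct", "normalize_assay", "condition_heatmap"]

_CT_COLUMNS = {"condition", "gene", "replicate", "ct"}


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_condition: str = "scrambled",
    base: float = 2.0,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Relative expression (fold of control) from a Ct table.

    ``ct_table`` is long-format with ``condition, gene, replicate, ct``.
    By default replicate Cts are averaged before differencing; with
    ``per_replicate`` the ddCt is formed per replicate (against the
    replicate-mean reference) and the per-replicate fold changes are
    averaged, which also yields a dispersion estimate on the fold scale.
    ``base`` allows amplification-efficiency corrections (default 2).

    Returns one row per (condition, gene) with ``delta_ct, ddct, rq``
    and the replicate SD of the target Ct.
    """
    missing = _CT_COLUMNS - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("non-positive Ct values")
    conditions = ct_table["condition"].unique()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    for cond in conditions:
        sub = ct_table[ct_table["condition"] == cond]
        if reference_gene not in set(sub["gene"]):
            raise ValueError(
                f"reference gene {reference_gene!r} missing in condition {cond!r}"
            )

    mean_ct = ct_table.groupby(["condition", "gene"])["ct"].mean()
    sd_ct = ct_table.groupby(["condition", "gene"])["ct"].std(ddof=1)
    ref_ct = mean_ct.xs(reference_gene, level="gene")

    rows = []
    targets = [g for g in ct_table["gene"].unique() if g != reference_gene]
    for gene in targets:
        dct_control = mean_ct[(control_condition, gene)] - ref_ct[control_condition]
        for cond in conditions:
            if (cond, gene) not in mean_ct.index:
                continue
            dct = mean_ct[(cond, gene)] - ref_ct[cond]
            ddct_val = dct - dct_control
            if per_replicate:
                sub = ct_table[(ct_table["condition"] == cond) & (ct_table["gene"] == gene)]
                rep_dct = sub["ct"].values - ref_ct[cond]
                rep_rq = base ** -(rep_dct - dct_control)
                rq, rq_sd = float(rep_rq.mean()), float(rep_rq.std(ddof=1))
            else:
                rq, rq_sd = float(base**-ddct_val), np.nan
            rows.append(
                {
                    "condition": cond,
                    "gene": gene,
                    "delta_ct": float(dct),
                    "ddct": float(ddct_val),
                    "rq": rq,
                    "rq_sd": rq_sd,
                    "ct_sd": float(sd_ct[(cond, gene)]),
                }
            )
    return pd.DataFrame(rows)


def normalize_assay(
    readings: pd.DataFrame,
    control_condition: str = "scrambled",
    value_column: str = "value",
) -> pd.DataFrame:
    """Normalize raw assay readings to the control-condition mean.

    Works per assay if an ``assay`` column is present (viability and
    proliferation plates can share a table).
    """
    if value_column not in readings.columns or "condition" not in readings.columns:
        raise ValueError(f"readings need 'condition' and {value_column!r} columns")
    group_cols = ["assay"] if "assay" in readings.columns else []
    out = readings.copy()

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        control = df.loc[df["condition"] == control_condition, value_column]
        if control.empty:
            raise ValueError(f"control condition {control_condition!r} has no readings")
        mean = control.mean()
        if mean == 0:
            raise ValueError("control mean is zero; normalization undefined")
        df = df.copy()
        df["normalized"] = df[value_column] / mean
        return df

    if group_cols:
        out = out.groupby(group_cols, group_keys=False)[out.columns].apply(_norm)
    else:
        out = _norm(out)
    return out.reset_index(drop=True)


def condition_heatmap(relative: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Gene-by-condition fold-change matrix for heatmap display.

    Rows are genes, columns conditions (input order preserved); a
    ``silencing`` annotation column marks combined vs single-siRNA
    conditions.  ``log2`` exports log2(RQ) instead of RQ.
    """
    if {"condition", "gene", "rq"} - set(relative.columns):
        raise ValueError("need columns condition, gene, rq")
    if relative.duplicated(subset=["condition", "gene"]).any():
        raise ValueError("duplicate (condition, gene) cells")
    genes = list(dict.fromkeys(relative["gene"]))
    conditions = list(dict.fromkeys(relative["condition"]))
    mat = relative.pivot(index="gene", columns="condition", values="rq")
    mat = mat.reindex(index=genes, columns=conditions)
    if mat.isna().any().any():
        raise ValueError("incomplete design: missing (gene, condition) cells")
    if log2:
        mat = np.log2(mat)
    mat.columns.name = None
    annotation = pd.Series(
        ["combined" if "+" in c else "single" for c in conditions],
        index=conditions,
        name="silencing",
    )
    mat.attrs["silencing"] = annotation
    return mat
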