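"""Threshold-based differential-expression classification.

Works downstream of an external differential-expression fit: genes arrive as
(gene, log2 fold change, p value) rows.  A gene is called up when
p < 0.01 and log2FC > 0.6 (about 1.5-fold), down when log2FC < -0.6, and
not significant otherwise.  Pathway-analysis input is the 100 smallest-p
genes under the same p cut-off.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "classify_deg",
    "log2fc_to_fold",
    "top_n_by_p",
    "volcano_table",
    "P_CUT_DEFAULT",
    "LFC_CUT_DEFAULT",
]

P_CUT_DEFAULT = 0.01
LFC_CUT_DEFAULT = 0.6

REQUIRED_COLS = ("gene", "log2fc", "p_value")


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    if table.gene.duplicated().any():
        raise ValueError("gene ids must be unique")
    p = table.p_value.dropna()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")


def classify_deg(
    table: pd.DataFrame,
    p_cut: float = P_CUT_DEFAULT,
    lfc_cut: float = LFC_CUT_DEFAULT,
    p_op: str = "lt",
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Label each gene ``up`` / ``down`` / ``ns``.

    ``up``: p passes the cut (default p < p_cut; ``p_op="ge"`` flips the
    comparison) and log2FC > lfc_cut; ``down`` likewise with
    log2FC < -lfc_cut.  Missing values label ``ns`` with a QC note.
    ``use_adjusted`` tests the ``p_adjusted`` column instead.
    """
    _validate(table)
    if p_op not in ("lt", "ge"):
        raise ValueError("p_op must be 'lt' or 'ge'")
    pcol = "p_adjusted" if use_adjusted else "p_value"
    if pcol not in table.columns:
        raise ValueError(f"column {pcol!r} not present")
    out = table.copy()
    p = out[pcol].to_numpy(dtype=float)
    lfc = out.log2fc.to_numpy(dtype=float)
    ok = np.isfinite(p) & np.isfinite(lfc)
    sig = (p < p_cut) if p_op == "lt" else (p >= p_cut)
    out["label"] = np.select(
        [ok & sig & (lfc > lfc_cut), ok & sig & (lfc < -lfc_cut)],
        ["up", "down"],
        default="ns",
    )
    out["qc_note"] = np.where(ok, "", "missing value")
    return out


def log2fc_to_fold(lfc: float) -> float:
    """Linear fold change 2**lfc (0.6 -> 1.5 at two significant figures)."""
    if not np.isfinite(lfc):
        raise ValueError("log2 fold change must be finite")
    return float(2.0**lfc)


def top_n_by_p(
    table: pd.DataFrame,
    n: int = 100,
    p_cut: float = P_CUT_DEFAULT,
) -> pd.DataFrame:
    """The ``n`` qualifying genes (p < p_cut) with the smallest p values.

    Ties break by |log2FC| descending, then gene id; fewer than ``n``
    qualifying genes returns them all with a warning.
    """
    _validate(table)
    if len(table) == 0:
        raise ValueError("gene table is empty")
    qual = table[table.p_value < p_cut].copy()
    if len(qual) < n:
        warnings.warn(
            f"only {len(qual)} genes pass p < {p_cut} (requested {n})", stacklevel=2
        )
    qual["_abs_lfc"] = qual.log2fc.abs()
    qual = qual.sort_values(
        ["p_value", "_abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return qual.head(n).reset_index(drop=True)


def volcano_table(
    classified: pd.DataFrame, p_cut: float = P_CUT_DEFAULT
) -> pd.DataFrame:
    """(log2FC, -log10 p, label) export for volcano plots."""
    out = classified[["gene", "log2fc", "p_value", "label"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out.p_value)
    out["p_cut_line"] = -np.log10(p_cut)
    return out
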