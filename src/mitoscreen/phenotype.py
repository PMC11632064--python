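"""Phenotype-switching readouts from differential-expression tables.

Melanoma cells move along a dedifferentiation axis spanning seven
transcriptional states (melanocytic through undifferentiated).  Given a
DE contrast (gene, log2 fold change, adjusted P), this module calls
significance at a fold-change/P threshold, scores per-state polarization
(the percentage of each state's marker genes called up or down), reports
a proliferative/invasive marker panel, and computes summed Spearman
correlations of query genes against an inflammation gene set in a tumor
expression matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen import spearman

__all__ = [
    "call_de",
    "polarization_score",
    "marker_panel_view",
    "inflammation_correlation_sum",
]


def call_de(
    table: pd.DataFrame,
    fc_threshold: float = 1.2,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Three-way up/down/not_significant call per gene.

    A gene is up when log2FC > log2(fc_threshold) and p_adj <
    padj_threshold; down symmetrically.  Defaults follow the common
    figure-legend convention (fold change > 1.2, p-adj < 0.05); a looser
    FDR < 0.1 screen is available by passing ``padj_threshold=0.1``.
    """
    if fc_threshold <= 1:
        raise ValueError(f"fc_threshold must be > 1, got {fc_threshold}")
    if not 0 < padj_threshold <= 1:
        raise ValueError(f"padj_threshold must be in (0,1], got {padj_threshold}")
    required = {"gene", "log2FoldChange", "padj"}
    if not required.issubset(table.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    bad = table["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj values must lie in [0,1]")
    out = table.copy()
    lfc_cut = np.log2(fc_threshold)
    sig = out["padj"] < padj_threshold
    out["call"] = "not_significant"
    out.loc[sig & (out["log2FoldChange"] > lfc_cut), "call"] = "up"
    out.loc[sig & (out["log2FoldChange"] < -lfc_cut), "call"] = "down"
    return out


def polarization_score(
    calls: pd.DataFrame, states: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-state percentage of marker genes called up / down.

    The denominator is the state's genes detected in the calls table
    (undetected genes carry no evidence either way).  A state with no
    detected gene is flagged not evaluable.
    """
    if "call" not in calls.columns:
        raise ValueError("run call_de first: calls table lacks a 'call' column")
    by_gene = calls.drop_duplicates("gene").set_index("gene")["call"]
    rows = []
    for state, members in states.items():
        members = list(dict.fromkeys(members))
        detected = [g for g in members if g in by_gene.index]
        n = len(detected)
        if n == 0:
            rows.append((state, 0, np.nan, np.nan, False))
            continue
        sub = by_gene.loc[detected]
        pct_up = 100.0 * (sub == "up").sum() / n
        pct_down = 100.0 * (sub == "down").sum() / n
        rows.append((state, n, pct_up, pct_down, True))
    return pd.DataFrame(
        rows, columns=["state", "n_detected", "percent_up", "percent_down", "evaluable"]
    ).set_index("state")


def marker_panel_view(
    calls: pd.DataFrame,
    proliferative_markers: list[str],
    invasive_markers: list[str],
) -> tuple[pd.DataFrame, str]:
    """Signed log2FC per phenotype-switching marker, plus a direction call.

    The summary is "dedifferentiation-consistent" when every detected
    invasive marker rises and every detected proliferative marker falls,
    "differentiation-consistent" for the mirror image, "mixed" otherwise
    and "empty" when no marker is detected.
    """
    by_gene = calls.drop_duplicates("gene").set_index("gene")
    rows = []
    for panel, markers in (
        ("proliferative", proliferative_markers),
        ("invasive", invasive_markers),
    ):
        for g in dict.fromkeys(markers):
            if g in by_gene.index:
                rec = by_gene.loc[g]
                rows.append(
                    (g, panel, float(rec["log2FoldChange"]),
                     rec.get("call", "not_significant"), True)
                )
            else:
                rows.append((g, panel, np.nan, "absent", False))
    view = pd.DataFrame(
        rows, columns=["gene", "panel", "log2FoldChange", "call", "present"]
    ).set_index("gene")
    present = view[view["present"]]
    if present.empty:
        return view, "empty"
    inv = present[present["panel"] == "invasive"]["log2FoldChange"]
    pro = present[present["panel"] == "proliferative"]["log2FoldChange"]
    if (inv > 0).all() and (pro < 0).all() and (len(inv) + len(pro)) > 0:
        summary = "dedifferentiation-consistent"
    elif (inv < 0).all() and (pro > 0).all() and (len(inv) + len(pro)) > 0:
        summary = "differentiation-consistent"
    else:
        summary = "mixed"
    return view, summary


def inflammation_correlation_sum(
    expression: pd.DataFrame,
    query_genes: list[str],
    inflammation_set: list[str],
    min_pairs: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed Spearman correlation of each query gene vs an inflammation set.

    ``expression`` is samples x genes (e.g. tumors).  For each query
    gene, every pairwise Spearman rho against the inflammation genes is
    computed (self-pairs excluded); insufficient-data pairs contribute 0
    to the sum and are counted.  Returns (pairwise rho matrix, summary
    with columns sum_rho, n_pairs_used, n_insufficient, present).
    """
    inflammation = [g for g in dict.fromkeys(inflammation_set) if g in expression.columns]
    pair_rows = {}
    summary_rows = []
    for q in dict.fromkeys(query_genes):
        if q not in expression.columns:
            summary_rows.append((q, np.nan, 0, 0, False))
            continue
        rhos = {}
        n_ins = 0
        total = 0.0
        used = 0
        for g in inflammation:
            if g == q:
                continue
            res = spearman(expression[q], expression[g], min_pairs=min_pairs)
            if res.insufficient:
                n_ins += 1
                rhos[g] = np.nan
            else:
                rhos[g] = res.rho
                total += res.rho
                used += 1
        pair_rows[q] = rhos
        summary_rows.append((q, total, used, n_ins, True))
    pairwise = pd.DataFrame(pair_rows).T
    pairwise.index.name = "query_gene"
    summary = pd.DataFrame(
        summary_rows,
        columns=["query_gene", "sum_rho", "n_pairs_used", "n_insufficient", "present"],
    ).set_index("query_gene")
    return pairwise, summary
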