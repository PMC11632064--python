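"""Mitochondrial annotation, essentiality classification, pathway tallies.

The screen's selected genes are intersected with a mitochondrial
membership table (MitoCarta-style), tallied by hierarchical pathway label
(MitoPathways-style, flat "A > B" strings), and classified by knockout
essentiality.  Annotation is consumed as input; membership is never
re-derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen import SelectionResult

__all__ = [
    "intersect_mitochondrial",
    "classify_essentiality",
    "pathway_tally",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "Unclassified"

_REQUIRED_COLUMNS = ("is_mitochondrial",)


def _check_annotation(annotation: pd.DataFrame) -> None:
    for col in _REQUIRED_COLUMNS:
        if col not in annotation.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    if annotation.index.has_duplicates:
        raise ValueError("annotation gene identifiers must be unique")


def intersect_mitochondrial(
    selection: SelectionResult,
    annotation: pd.DataFrame,
    allow_missing: bool = False,
) -> SelectionResult:
    """Restrict a selection to genes annotated as mitochondrial.

    Direction labels and per-gene evidence are preserved.  Selected genes
    absent from the annotation raise a structural error naming the
    offenders, unless ``allow_missing`` is set (they are then treated as
    non-mitochondrial).
    """
    _check_annotation(annotation)
    selected = selection.selected_genes
    missing = [g for g in selected if g not in annotation.index]
    if missing and not allow_missing:
        raise ValueError(
            f"{len(missing)} selected gene(s) lack annotation: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    mito = set(
        annotation.index[annotation["is_mitochondrial"].astype(bool)]
    )
    keep = lambda genes: sorted(g for g in genes if g in mito)  # noqa: E731
    kept = set(keep(selected))
    evidence = selection.evidence
    if len(evidence):
        evidence = evidence[evidence["gene"].isin(kept)].reset_index(drop=True)
    return SelectionResult(
        resistance_genes=keep(selection.resistance_genes),
        sensitizing_genes=keep(selection.sensitizing_genes),
        discordant_genes=keep(selection.discordant_genes),
        evidence=evidence,
        alpha=selection.alpha,
        min_evidence=selection.min_evidence,
    )


def classify_essentiality(
    knockout_scores: pd.DataFrame,
    common_essential_threshold: float = -1.0,
    nonessential_threshold: float = -0.5,
) -> pd.Series:
    """Label genes by the distribution of knockout fitness scores.

    ``knockout_scores`` is cell lines x genes (Chronos-like: more
    negative = stronger proliferation loss).  Per gene: common_essential
    when the median score is at or below ``common_essential_threshold``
    (the median of all common-essential gene scores sits near -1);
    nonessential when both the median and the lower quartile stay above
    ``nonessential_threshold`` (i.e. at least three quarters of lines are
    barely affected); selective otherwise (strong essentiality confined
    to a minority of lines); unknown when every score is missing.
    """
    labels = {}
    for gene in knockout_scores.columns:
        v = knockout_scores[gene].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            labels[gene] = "unknown"
            continue
        med = float(np.median(v))
        q1 = float(np.quantile(v, 0.25))
        if med <= common_essential_threshold:
            labels[gene] = "common_essential"
        elif med > nonessential_threshold and q1 > nonessential_threshold:
            labels[gene] = "nonessential"
        else:
            labels[gene] = "selective"
    return pd.Series(labels, name="essentiality_label")


def _split_labels(raw) -> list[str]:
    if isinstance(raw, str):
        return [s.strip() for s in raw.split("|") if s.strip()]
    if isinstance(raw, (list, tuple)):
        return [str(s) for s in raw if str(s)]
    return []


def pathway_tally(
    selection: SelectionResult, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway gene counts split by selection direction.

    A gene with k pathway labels contributes to k pathway rows; genes
    without any label are pooled under ``Unclassified``.  Returns
    (per-pathway counts, unduplicated per-direction totals); the totals
    count each gene once and sum to the selection size.
    """
    _check_annotation(annotation)
    directions = {
        "resistance": selection.resistance_genes,
        "sensitizing": selection.sensitizing_genes,
        "discordant": selection.discordant_genes,
    }
    counts: dict[str, dict[str, int]] = {}
    totals = {}
    for direction, genes in directions.items():
        totals[direction] = len(genes)
        for gene in genes:
            raw = (
                annotation.loc[gene, "pathway_labels"]
                if gene in annotation.index and "pathway_labels" in annotation.columns
                else ""
            )
            labels = _split_labels(raw) or [UNCLASSIFIED]
            for lab in labels:
                counts.setdefault(lab, {})[direction] = (
                    counts.get(lab, {}).get(direction, 0) + 1
                )
    tally = (
        pd.DataFrame(counts).T.reindex(columns=list(directions)).fillna(0).astype(int)
    )
    tally.index.name = "pathway"
    tally = tally.sort_index()
    total_df = pd.DataFrame(
        {"n_genes": pd.Series(totals)},
    )
    total_df.index.name = "direction"
    return tally, total_df
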