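"""Relative qPCR quantification: ddCt fold changes and mtDNA/gDNA ratio.

Cycle thresholds (Ct) are cycle numbers at which fluorescence crosses the
detection threshold; one extra cycle means half the starting template at
perfect amplification efficiency.  Technical replicate wells are averaged
per (sample, target) before any delta is taken.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_delta_ct", "mtdna_ratio"]

_CT_COLUMNS = {"sample", "condition", "target", "ct"}


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    if not _CT_COLUMNS.issubset(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(_CT_COLUMNS)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    # average technical replicates per (sample, condition, target)
    return (
        table.groupby(["sample", "condition", "target"], sort=False)["ct"]
        .mean()
        .reset_index()
    )


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Fold change of ``target`` per sample by the ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean
    dCt of the control-condition samples; fold = efficiency^(-ddCt).
    The control group's fold changes have geometric mean 1 by
    construction.  Samples missing either Ct are flagged and excluded.
    """
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    tab = _prepare(table)
    wide = tab.pivot_table(
        index=["sample", "condition"], columns="target", values="ct"
    )
    for t in (target, reference):
        if t not in wide.columns:
            raise ValueError(f"target {t!r} absent from the Ct table")
    wide = wide.reset_index()
    wide["excluded"] = wide[target].isna() | wide[reference].isna()
    wide["delta_ct"] = wide[target] - wide[reference]
    ctrl = wide[(wide["condition"] == control_condition) & ~wide["excluded"]]
    if ctrl.empty:
        raise ValueError(
            f"no usable sample in control condition {control_condition!r}"
        )
    ctrl_mean = ctrl["delta_ct"].mean()
    wide["delta_delta_ct"] = wide["delta_ct"] - ctrl_mean
    wide["fold_change"] = np.power(float(efficiency), -wide["delta_delta_ct"])
    return wide[
        ["sample", "condition", "delta_ct", "delta_delta_ct", "fold_change", "excluded"]
    ]


def mtdna_ratio(
    table: pd.DataFrame,
    mito_target: str,
    genomic_target: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Mitochondrial-to-genomic DNA copy ratio per sample.

    ratio = efficiency^(Ct_genomic - Ct_mito), assuming one template
    doubling per cycle at the default efficiency of 2.  Samples missing
    either target are excluded with a flag.
    """
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    tab = _prepare(table)
    wide = tab.pivot_table(
        index=["sample", "condition"], columns="target", values="ct"
    )
    for t in (mito_target, genomic_target):
        if t not in wide.columns:
            raise ValueError(f"target {t!r} absent from the Ct table")
    wide = wide.reset_index()
    wide["excluded"] = wide[mito_target].isna() | wide[genomic_target].isna()
    wide["mtdna_ratio"] = np.power(
        float(efficiency), wide[genomic_target] - wide[mito_target]
    )
    wide.loc[wide["excluded"], "mtdna_ratio"] = np.nan
    return wide[["sample", "condition", "mtdna_ratio", "excluded"]]
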