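"""Bioenergetic metrics from extracellular-flux traces.

The instrument records oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) per well across a
five-injection schedule: baseline, oligomycin (ATP-synthase block), FCCP
(uncoupler), rotenone + antimycin A (electron-transport block), and
monensin (maximal glycolytic drive).  Standard derived quantities:

* non-mitochondrial respiration = post-rot/AA OCR, subtracted from all
  OCR summaries;
* basal respiration = corrected baseline OCR;
* ATP-linked respiration = basal - corrected post-oligomycin OCR;
* proton leak = corrected post-oligomycin OCR;
* maximal respiration = corrected post-FCCP OCR;
* spare respiratory capacity = maximal - basal;
* coupling fraction = ATP-linked / basal;
* maximal ECAR = post-monensin ECAR (ECAR is not rot/AA-corrected);
* glycolytic reserve = maximal ECAR - basal ECAR;
* OCR/ECAR ratio = corrected basal OCR over basal ECAR.

All rates are divided by the well's cell count before aggregation; the
group value is the mean over its wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import FluxRun, FLUX_PHASES

__all__ = ["BioenergeticProfile", "compute_profile", "fold_induction"]

OCR_METRICS = (
    "basal_respiration",
    "atp_linked_respiration",
    "proton_leak",
    "maximal_respiration",
    "spare_capacity",
)
ECAR_METRICS = ("basal_ecar", "maximal_ecar", "glycolytic_reserve")
ALL_METRICS = OCR_METRICS + ("coupling_fraction",) + ECAR_METRICS + ("ocr_ecar_ratio",)


@dataclass
class BioenergeticProfile:
    """Per-group metric table plus optional percent-of-reference view.

    ``per_group`` rows are groups, columns the ten metrics (cell-count
    normalized).  ``per_well`` keeps the well-level values behind the
    group means.  ``percent_of_reference`` expresses OCR metrics as % of
    the reference group's basal respiration and ECAR metrics as % of its
    basal ECAR (the reference basal is 100 by construction); dimensionless
    ratios are excluded.  ``n_flagged_negative`` counts wells whose
    corrected OCR went negative (retained, but flagged).
    """

    per_group: pd.DataFrame
    per_well: pd.DataFrame
    percent_of_reference: pd.DataFrame | None
    reference_group: str | None
    n_flagged_negative: int


def _phase_summaries(run: FluxRun, how: str) -> pd.DataFrame:
    if how not in ("mean", "last"):
        raise ValueError(f"phase summary must be mean|last, got {how!r}")
    d = run.data
    missing = set(FLUX_PHASES) - set(d["phase"].unique())
    if missing:
        raise ValueError(f"flux run lacks phase(s): {sorted(missing)}")
    if how == "mean":
        agg = d.groupby(["well", "phase"])[["ocr", "ecar"]].mean()
    else:
        agg = (
            d.sort_values("cycle")
            .groupby(["well", "phase"])[["ocr", "ecar"]]
            .last()
        )
    return agg


def compute_profile(
    run: FluxRun,
    grouping: Mapping[str, str],
    reference_group: str | None = None,
    phase_summary: str = "mean",
) -> BioenergeticProfile:
    """Compute the full bioenergetic profile per group of wells.

    ``grouping`` maps every well to a group (e.g. cell line); a missing
    well is an error.  ``phase_summary`` picks how a phase's measurement
    cycles collapse to one number per well ("mean", the default, or
    "last").  With ``reference_group`` set, a percent-of-reference table
    is added with that group's basal OCR and basal ECAR pinned at 100%.
    """
    wells = run.wells
    unmapped = [w for w in wells if w not in grouping]
    if unmapped:
        raise ValueError(f"grouping lacks well(s): {unmapped}")
    summaries = _phase_summaries(run, phase_summary)

    rows = []
    n_flagged = 0
    for well in wells:
        s = summaries.loc[well]
        count = float(run.cell_counts.loc[well])
        nonmito = s.loc["rotenone_antimycin", "ocr"]
        basal = s.loc["baseline", "ocr"] - nonmito
        leak = s.loc["oligomycin", "ocr"] - nonmito
        maximal = s.loc["fccp", "ocr"] - nonmito
        if min(basal, leak, maximal) < 0:
            n_flagged += 1
        atp = basal - leak
        basal_ecar = s.loc["baseline", "ecar"]
        max_ecar = s.loc["monensin", "ecar"]
        rec = {
            "well": well,
            "group": grouping[well],
            "basal_respiration": basal / count,
            "atp_linked_respiration": atp / count,
            "proton_leak": leak / count,
            "maximal_respiration": maximal / count,
            "spare_capacity": (maximal - basal) / count,
            "coupling_fraction": atp / basal if basal != 0 else np.nan,
            "basal_ecar": basal_ecar / count,
            "maximal_ecar": max_ecar / count,
            "glycolytic_reserve": (max_ecar - basal_ecar) / count,
            "ocr_ecar_ratio": basal / basal_ecar if basal_ecar != 0 else np.nan,
        }
        rows.append(rec)
    per_well = pd.DataFrame(rows).set_index("well")
    per_group = per_well.groupby("group")[list(ALL_METRICS)].mean()

    percent = None
    if reference_group is not None:
        if reference_group not in per_group.index:
            raise ValueError(f"reference group {reference_group!r} not in grouping")
        ref_ocr = per_group.loc[reference_group, "basal_respiration"]
        ref_ecar = per_group.loc[reference_group, "basal_ecar"]
        percent = pd.DataFrame(index=per_group.index)
        for m in OCR_METRICS:
            percent[m] = 100.0 * per_group[m] / ref_ocr
        for m in ECAR_METRICS:
            percent[m] = 100.0 * per_group[m] / ref_ecar
    return BioenergeticProfile(
        per_group=per_group,
        per_well=per_well,
        percent_of_reference=percent,
        reference_group=reference_group,
        n_flagged_negative=n_flagged,
    )


def fold_induction(
    run: FluxRun,
    numerator_phase: str,
    denominator_phase: str,
    channel: str,
    grouping: Mapping[str, str],
    phase_summary: str = "mean",
) -> pd.DataFrame:
    """Group-mean per-well ratio between two phases of one channel.

    OCR ratios use rot/AA-corrected values (e.g. maximal FCCP induction
    relative to basal); ECAR ratios use raw values (e.g. monensin over
    baseline).  Wells with a zero denominator are excluded from the group
    mean and tallied in ``n_excluded``.
    """
    if channel not in ("ocr", "ecar"):
        raise ValueError(f"channel must be ocr|ecar, got {channel!r}")
    for ph in (numerator_phase, denominator_phase):
        if ph not in FLUX_PHASES:
            raise ValueError(f"unknown phase {ph!r}")
    summaries = _phase_summaries(run, phase_summary)
    rows = []
    for well in run.wells:
        if well not in grouping:
            raise ValueError(f"grouping lacks well {well!r}")
        s = summaries.loc[well]
        num = s.loc[numerator_phase, channel]
        den = s.loc[denominator_phase, channel]
        if channel == "ocr":
            nonmito = s.loc["rotenone_antimycin", "ocr"]
            num, den = num - nonmito, den - nonmito
        rows.append((well, grouping[well], num, den))
    df = pd.DataFrame(rows, columns=["well", "group", "num", "den"])
    df["ok"] = df["den"] != 0
    df.loc[df["ok"], "ratio"] = df.loc[df["ok"], "num"] / df.loc[df["ok"], "den"]
    out = df.groupby("group").agg(
        ratio=("ratio", "mean"),
        n_wells=("ok", "sum"),
        n_excluded=("ok", lambda s: int((~s).sum())),
    )
    return out
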