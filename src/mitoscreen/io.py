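"""Readers and writers for the pipeline's tabular dialect.

All tables are UTF-8, tab-separated, '.' decimal, header row mandatory.
Lines starting with '#' are metadata comments (the pipeline stamps each
output with its run-manifest hash this way) and are skipped on read, so
every table round-trips losslessly.  Gene sets use the GMT dialect (set
name, description, members).  The effect matrix carries a JSON sidecar
(<path>.meta.json) recording approach modalities and the score
orientation, which the loader asserts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .screen import EffectMatrix, ORIENTATION, SelectionResult
from .synthetic import FluxRun

__all__ = [
    "write_table",
    "read_table",
    "write_expression",
    "read_expression",
    "write_effects",
    "read_effects",
    "write_annotation",
    "read_annotation",
    "write_gmt",
    "read_gmt",
    "write_selection",
    "read_selection",
    "write_flux_run",
    "read_flux_run",
    "read_ct_table",
    "write_manifest",
]


def write_table(
    df: pd.DataFrame, path, index: bool = True, manifest_hash: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if manifest_hash:
            fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- expression / effects ---------------------------------------------------


def write_expression(expr: pd.DataFrame, path, manifest_hash=None) -> None:
    df = expr.copy()
    df.index.name = "cell_line"
    write_table(df, path, manifest_hash=manifest_hash)


def read_expression(path) -> pd.DataFrame:
    df = read_table(path)
    df.index.name = "cell_line"
    return df


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_effects(effects: EffectMatrix, path, manifest_hash=None) -> None:
    df = effects.values.copy()
    df.index.name = "cell_line"
    write_table(df, path, manifest_hash=manifest_hash)
    with open(_meta_path(path), "w") as fh:
        json.dump(
            {"orientation": effects.orientation, "modalities": effects.modalities},
            fh,
            indent=1,
            sort_keys=True,
        )


def read_effects(path) -> EffectMatrix:
    df = read_table(path)
    df.index.name = "cell_line"
    meta_path = _meta_path(path)
    modalities: dict[str, str] = {}
    orientation = ORIENTATION
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        orientation = meta.get("orientation", ORIENTATION)
        modalities = meta.get("modalities", {})
    if orientation != ORIENTATION:
        raise ValueError(
            f"effect matrix at {path} declares orientation {orientation!r}; "
            f"expected {ORIENTATION!r} (higher score = more resistant)"
        )
    return EffectMatrix(values=df, modalities=modalities, orientation=orientation)


# -- annotation -------------------------------------------------------------


def write_annotation(annotation: pd.DataFrame, path, manifest_hash=None) -> None:
    write_table(annotation, path, manifest_hash=manifest_hash)


def read_annotation(path) -> pd.DataFrame:
    df = read_table(path)
    if "is_mitochondrial" in df.columns:
        df["is_mitochondrial"] = df["is_mitochondrial"].astype(bool)
    if "pathway_labels" in df.columns:
        df["pathway_labels"] = df["pathway_labels"].fillna("")
    return df


# -- gene sets (GMT) --------------------------------------------------------


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = list(dict.fromkeys(p for p in parts[2:] if p))
    return sets


# -- selection --------------------------------------------------------------


def write_selection(sel: SelectionResult, path_prefix, manifest_hash=None) -> None:
    """Write <prefix>.genes.tsv (gene, direction), <prefix>.evidence.tsv
    and <prefix>.json (parameters + counts)."""
    rows = (
        [(g, "resistance") for g in sel.resistance_genes]
        + [(g, "sensitizing") for g in sel.sensitizing_genes]
        + [(g, "discordant") for g in sel.discordant_genes]
    )
    genes = pd.DataFrame(rows, columns=["gene", "direction"]).sort_values("gene")
    write_table(genes, f"{path_prefix}.genes.tsv", index=False, manifest_hash=manifest_hash)
    write_table(sel.evidence, f"{path_prefix}.evidence.tsv", index=False, manifest_hash=manifest_hash)
    payload = {
        "alpha": sel.alpha,
        "min_evidence": sel.min_evidence,
        "counts": sel.counts(),
    }
    if manifest_hash:
        payload["manifest"] = manifest_hash
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_selection(path_prefix) -> SelectionResult:
    genes = pd.read_csv(f"{path_prefix}.genes.tsv", sep="\t", comment="#")
    evidence = pd.read_csv(f"{path_prefix}.evidence.tsv", sep="\t", comment="#")
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    by_dir = {d: sorted(genes.loc[genes["direction"] == d, "gene"]) for d in
              ("resistance", "sensitizing", "discordant")}
    return SelectionResult(
        resistance_genes=by_dir["resistance"],
        sensitizing_genes=by_dir["sensitizing"],
        discordant_genes=by_dir["discordant"],
        evidence=evidence,
        alpha=meta["alpha"],
        min_evidence=meta["min_evidence"],
    )


# -- flux runs --------------------------------------------------------------


def write_flux_run(run: FluxRun, path, grouping=None) -> None:
    """Long-format CSV: well[,group],phase,cycle,ocr,ecar,cell_count."""
    df = run.data.copy()
    if grouping is not None:
        df.insert(1, "group", df["well"].map(grouping))
    df["cell_count"] = df["well"].map(run.cell_counts)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def read_flux_run(path) -> tuple[FluxRun, dict[str, str] | None]:
    df = pd.read_csv(path, comment="#")
    required = {"well", "phase", "cycle", "ocr", "ecar", "cell_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"flux CSV must have columns {sorted(required)}")
    counts = df.drop_duplicates("well").set_index("well")["cell_count"]
    grouping = None
    if "group" in df.columns:
        grouping = dict(df.drop_duplicates("well").set_index("well")["group"])
    run = FluxRun(
        data=df[["well", "phase", "cycle", "ocr", "ecar"]].copy(),
        cell_counts=counts,
    )
    return run, grouping


# -- qPCR -------------------------------------------------------------------


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "condition", "target", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


# -- manifest ---------------------------------------------------------------


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
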