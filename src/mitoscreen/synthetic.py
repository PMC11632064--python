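"""Synthetic panels with planted ground truth.

Generates the data structures the screen consumes — an expression panel
(cell lines x genes), a perturbation-effect panel (cell lines x
approaches), gene annotation, differential-expression tables, phenotype
state gene sets, extracellular-flux plate traces and qPCR Ct tables —
with full ground-truth records, so every downstream operation can be
exercised against a known answer.

Planted-signal mechanism
------------------------
All approaches targeting the same gene product are strongly correlated
with one another in real dependency panels, so effect scores share a
latent per-line dependency factor ``f``:

    effect_a = sqrt(b) * f + sqrt(1-b) * eps_a,   b = approach_correlation

A planted gene mixes the standardized mean of its signal approaches'
effect scores into its (Gaussian, log-scale) expression with a weight
solved so that the population Pearson correlation with each signal
approach equals ``rho_P = 2*sin(pi*rho_S/6)`` — the inverse of the
bivariate-normal relation rho_S = (6/pi)*arcsin(rho_P/2) — which makes
the population Spearman correlation equal the requested ``target_rho``
(positive for resistance genes, negative for sensitizing genes).  Null
genes are independent Gaussian noise, exchangeable with respect to every
effect column.  Missingness is applied completely at random, to the
effect panel only, mirroring cell lines absent from individual screens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .screen import EffectMatrix

__all__ = [
    "PanelTruth",
    "SyntheticPanel",
    "spearman_to_pearson",
    "generate_panel",
    "generate_state_sets",
    "generate_de_table",
    "FluxRun",
    "generate_flux_run",
    "generate_ct_table",
]

DEFAULT_APPROACH_CORRELATION = 0.45

#: MitoPathways-style hierarchical labels used for synthetic annotation.
MITO_PATHWAY_LABELS = (
    "Metabolism > Lipid metabolism",
    "Metabolism > Amino acid metabolism",
    "Metabolism > Carbohydrate metabolism",
    "Metabolism > Detoxification",
    "Mitochondrial central dogma > mtDNA replication",
    "Mitochondrial central dogma > Translation",
    "OXPHOS > Complex I",
    "Signaling > Apoptosis",
)

ESSENTIALITY_LABELS = ("common_essential", "selective", "nonessential")


@dataclass
class PanelTruth:
    """Ground truth of a generated panel."""

    planted_resistance: list[str]
    planted_sensitizing: list[str]
    target_rho: float
    approaches_with_signal: dict[str, list[str]]
    seed: int

    def __post_init__(self) -> None:
        if set(self.planted_resistance) & set(self.planted_sensitizing):
            raise ValueError("resistance and sensitizing plants must be disjoint")
        for g, apps in self.approaches_with_signal.items():
            if not apps:
                raise ValueError(f"planted gene {g} has an empty signal set")

    @property
    def planted(self) -> list[str]:
        return sorted(set(self.planted_resistance) | set(self.planted_sensitizing))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PanelTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticPanel:
    expression: pd.DataFrame
    effects: EffectMatrix
    annotation: pd.DataFrame
    truth: PanelTruth
    state_sets: dict[str, list[str]] = field(default_factory=dict)


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation yielding Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _check_fraction(name: str, value: float, closed_top: bool = False) -> None:
    top_ok = value <= 1 if closed_top else value < 1
    if not (0 <= value and top_ok):
        hi = "1]" if closed_top else "1)"
        raise ValueError(f"{name} must be in [0,{hi}, got {value}")


def generate_panel(
    n_lines: int = 40,
    n_genes: int = 500,
    n_resistance: int = 20,
    n_sensitizing: int = 20,
    target_rho: float = 0.6,
    n_approaches: int = 8,
    signal_approaches_per_gene: int = 4,
    missing_rate: float = 0.1,
    seed: int = 0,
    approach_correlation: float = DEFAULT_APPROACH_CORRELATION,
    n_extra_expression_lines: int = 0,
    n_extra_effect_lines: int = 0,
    mito_background_fraction: float = 0.1,
) -> SyntheticPanel:
    """Generate an expression + effect panel with planted signature genes.

    Defaults give the standard benchmark panel: 40 cell lines, 500 genes,
    20 resistance + 20 sensitizing genes planted at |Spearman| 0.6 on 4
    of 8 approaches each, 10% effect-score missingness.  Planted genes
    (and a ``mito_background_fraction`` of null genes) are tagged
    mitochondrial in the annotation table.  ``n_extra_*_lines`` add cell
    lines private to one panel, to exercise identifier harmonization.
    Identical seeds and parameters reproduce identical panels.
    """
    if n_lines < 3:
        raise ValueError("n_lines must be >= 3")
    if n_genes < 1 or n_approaches < 1:
        raise ValueError("n_genes and n_approaches must be positive")
    if n_resistance < 0 or n_sensitizing < 0:
        raise ValueError("planted gene counts must be non-negative")
    if n_resistance + n_sensitizing > n_genes:
        raise ValueError("more planted genes than genes in the panel")
    if not 0 < target_rho < 1:
        raise ValueError(f"target_rho must be in (0,1), got {target_rho}")
    if not 1 <= signal_approaches_per_gene <= n_approaches:
        raise ValueError("signal_approaches_per_gene must be in [1, n_approaches]")
    _check_fraction("missing_rate", missing_rate)
    _check_fraction("approach_correlation", approach_correlation, closed_top=False)

    k = signal_approaches_per_gene
    b = approach_correlation
    rho_p = spearman_to_pearson(target_rho)
    # corr(gene, signal effect) = w * sqrt(b + (1-b)/k); solve for w
    mix_var = b + (1.0 - b) / k
    w = rho_p / np.sqrt(mix_var)
    if w > 1.0:
        raise ValueError(
            f"target_rho={target_rho} with {k} signal approaches needs "
            f"approach_correlation >= {rho_p**2 - (1 - rho_p**2) / (k - 1):.3f}"
            if k > 1
            else f"target_rho={target_rho} is not reachable"
        )

    rng = np.random.default_rng(seed)
    lines = [f"LINE_{i:04d}" for i in range(n_lines + max(n_extra_expression_lines, 0) + max(n_extra_effect_lines, 0))]
    shared = lines[:n_lines]
    expr_lines = shared + lines[n_lines : n_lines + n_extra_expression_lines]
    eff_lines = shared + lines[
        n_lines + n_extra_expression_lines : n_lines
        + n_extra_expression_lines
        + n_extra_effect_lines
    ]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    approaches = _approach_names(n_approaches)

    n_eff = len(eff_lines)
    f = rng.standard_normal(n_eff)
    eps = rng.standard_normal((n_eff, n_approaches))
    eff_values = np.sqrt(b) * f[:, None] + np.sqrt(1.0 - b) * eps
    effects_df = pd.DataFrame(eff_values, index=eff_lines, columns=approaches)
    effects_df.index.name = "cell_line"

    planted_res = genes[:n_resistance]
    planted_sen = genes[n_resistance : n_resistance + n_sensitizing]
    signal_map: dict[str, list[str]] = {}

    n_expr = len(expr_lines)
    expr_values = rng.standard_normal((n_expr, n_genes))
    # effects restricted to the lines both panels share, standardized mean
    eff_shared = effects_df.loc[shared].to_numpy()
    for j, gene in enumerate(planted_res + planted_sen):
        sign = 1.0 if gene in planted_res else -1.0
        sig_idx = np.sort(rng.choice(n_approaches, size=k, replace=False))
        signal_map[gene] = [approaches[a] for a in sig_idx]
        m = eff_shared[:, sig_idx].mean(axis=1) / np.sqrt(mix_var)
        noise = rng.standard_normal(n_expr)
        col = np.sqrt(1.0 - w * w) * noise
        col[:n_lines] += sign * w * m
        # extra expression-only lines carry pure noise at unit variance
        if n_expr > n_lines:
            col[n_lines:] = noise[n_lines:]
        expr_values[:, j] = col
    # shift/scale to a log2-abundance-like range; rank structure unchanged
    expr_values = 6.0 + 1.5 * expr_values
    expression = pd.DataFrame(expr_values, index=expr_lines, columns=genes)
    expression.index.name = "cell_line"

    if missing_rate > 0:
        mask = rng.random(effects_df.shape) < missing_rate
        eff_masked = effects_df.to_numpy()
        eff_masked[mask] = np.nan
        effects_df = pd.DataFrame(
            eff_masked, index=effects_df.index, columns=approaches
        )

    modalities = {a: _modality_of(a) for a in approaches}
    effects = EffectMatrix(values=effects_df, modalities=modalities)

    truth = PanelTruth(
        planted_resistance=list(planted_res),
        planted_sensitizing=list(planted_sen),
        target_rho=float(target_rho),
        approaches_with_signal=signal_map,
        seed=int(seed),
    )
    annotation = _make_annotation(
        genes, truth, rng, mito_background_fraction
    )
    return SyntheticPanel(
        expression=expression, effects=effects, annotation=annotation, truth=truth
    )


def _approach_names(n: int) -> list[str]:
    base = ["CRISPR_chronos", "RNAi_demeter2"]
    drugs = [f"DRUG_{i:02d}" for i in range(max(n - 2, 0))]
    return (base + drugs)[:n]


def _modality_of(name: str) -> str:
    if name.startswith("CRISPR"):
        return "crispr"
    if name.startswith("RNAi"):
        return "rnai"
    return "drug"


def _make_annotation(
    genes: list[str],
    truth: PanelTruth,
    rng: np.random.Generator,
    mito_background_fraction: float,
) -> pd.DataFrame:
    _check_fraction("mito_background_fraction", mito_background_fraction, True)
    planted = set(truth.planted)
    is_mito = np.array([g in planted for g in genes])
    nulls = np.nonzero(~is_mito)[0]
    n_extra = int(round(mito_background_fraction * nulls.size))
    if n_extra:
        is_mito[rng.choice(nulls, size=n_extra, replace=False)] = True
    pathways = [
        "|".join(
            sorted(
                rng.choice(
                    MITO_PATHWAY_LABELS,
                    size=rng.integers(1, 3),
                    replace=False,
                )
            )
        )
        if mito
        else ""
        for mito, _ in zip(is_mito, genes)
    ]
    essentiality = rng.choice(ESSENTIALITY_LABELS, size=len(genes), p=[0.1, 0.2, 0.7])
    scores = np.where(
        essentiality == "common_essential",
        rng.normal(-1.5, 0.2, len(genes)),
        np.where(
            essentiality == "selective",
            rng.normal(-0.7, 0.15, len(genes)),
            rng.normal(-0.1, 0.1, len(genes)),
        ),
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "is_mitochondrial": is_mito,
            "pathway_labels": pathways,
            "essentiality_label": essentiality,
            "median_knockout_score": np.round(scores, 4),
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# Differential-expression tables with controlled per-state polarization


SEVEN_STATES = (
    "melanocytic",
    "transitory_melanocytic",
    "transitory",
    "transitory_neural_crest",
    "neural_crest_like",
    "antigen_presenting",
    "undifferentiated",
)


def generate_state_sets(
    genes_per_state: int = 20, states: tuple[str, ...] = SEVEN_STATES
) -> dict[str, list[str]]:
    """Disjoint placeholder gene sets for the seven phenotype states."""
    out = {}
    for i, st in enumerate(states):
        out[st] = [f"{st.upper()}_{j:03d}" for j in range(genes_per_state)]
    return out


def generate_de_table(
    state_sets: dict[str, list[str]],
    per_state_up_fraction: dict[str, float],
    per_state_down_fraction: dict[str, float],
    n_background: int = 100,
    seed: int = 0,
    fc_threshold: float = 1.2,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression table with exact per-state up/down counts.

    Within each state, ``round(fraction * n)`` genes are pushed past the
    (fc_threshold, padj_threshold) boundary in each direction; the rest,
    and ``n_background`` extra genes, stay non-significant.  States are
    assumed disjoint; a gene seen in an earlier state keeps its first
    assignment.
    """
    lfc_min = np.log2(fc_threshold)
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, float, float]] = []
    seen: set[str] = set()
    for state, members in state_sets.items():
        members = [g for g in dict.fromkeys(members) if g not in seen]
        seen.update(members)
        fu = per_state_up_fraction.get(state, 0.0)
        fd = per_state_down_fraction.get(state, 0.0)
        _check_fraction(f"up_fraction[{state}]", fu, closed_top=True)
        _check_fraction(f"down_fraction[{state}]", fd, closed_top=True)
        if fu + fd > 1:
            raise ValueError(f"up+down fractions exceed 1 for state {state}")
        n = len(members)
        n_up = int(round(fu * n))
        n_down = int(round(fd * n))
        if n_up + n_down > n:
            n_down = n - n_up
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            gene = members[idx]
            if pos < n_up:
                lfc = lfc_min + 0.1 + rng.uniform(0, 1.5)
                padj = rng.uniform(1e-8, padj_threshold * 0.5)
            elif pos < n_up + n_down:
                lfc = -(lfc_min + 0.1 + rng.uniform(0, 1.5))
                padj = rng.uniform(1e-8, padj_threshold * 0.5)
            else:
                lfc = rng.uniform(-0.8, 0.8) * lfc_min
                padj = rng.uniform(min(padj_threshold * 2, 1.0), 1.0)
            rows.append((gene, lfc, padj))
    for i in range(n_background):
        rows.append(
            (
                f"BG_{i:04d}",
                rng.uniform(-0.8, 0.8) * lfc_min,
                rng.uniform(min(padj_threshold * 2, 1.0), 1.0),
            )
        )
    return pd.DataFrame(rows, columns=["gene", "log2FoldChange", "padj"])


# ---------------------------------------------------------------------------
# Extracellular-flux plate traces


FLUX_PHASES = ("baseline", "oligomycin", "fccp", "rotenone_antimycin", "monensin")


@dataclass
class FluxRun:
    """A flux-analyzer run: long-format OCR/ECAR traces plus cell counts.

    ``data`` columns: well, phase, cycle, ocr, ecar.  Phases follow the
    five-injection schedule (baseline, oligomycin, FCCP,
    rotenone+antimycin A, monensin).
    """

    data: pd.DataFrame
    cell_counts: pd.Series
    phases: tuple[str, ...] = FLUX_PHASES

    def __post_init__(self) -> None:
        counts = self.data.groupby(["well", "phase"]).size()
        wells = self.data["well"].unique()
        for well in wells:
            for phase in self.phases:
                if (well, phase) not in counts.index:
                    raise ValueError(f"well {well} lacks phase {phase}")
        if (self.cell_counts <= 0).any():
            raise ValueError("cell counts must be positive")

    @property
    def wells(self) -> list[str]:
        return list(dict.fromkeys(self.data["well"]))


def generate_flux_run(
    basal_ocr: float = 100.0,
    oligo_ocr: float = 40.0,
    fccp_ocr: float = 180.0,
    rotaa_ocr: float = 20.0,
    basal_ecar: float = 50.0,
    monensin_ecar: float = 90.0,
    noise_sd: float = 0.0,
    n_wells: int = 6,
    seed: int = 0,
    cycles_per_phase: int = 3,
    cell_count: int = 1,
    oligo_ecar: float | None = None,
) -> FluxRun:
    """Synthetic five-phase flux run with per-well Gaussian noise.

    OCR inputs are phase plateaus in pmol O2/min; ECAR in mpH/min (the
    oligomycin/FCCP/rot+AA ECAR defaults to the basal plateau unless
    ``oligo_ecar`` is given; the monensin phase carries the maximal ECAR
    and the post-rot/AA OCR).  With ``noise_sd=0`` the bioenergetic
    metrics recover the inputs exactly.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if cell_count < 1:
        raise ValueError("cell_count must be positive")
    rng = np.random.default_rng(seed)
    ocr_levels = {
        "baseline": basal_ocr,
        "oligomycin": oligo_ocr,
        "fccp": fccp_ocr,
        "rotenone_antimycin": rotaa_ocr,
        "monensin": rotaa_ocr,
    }
    mid_ecar = basal_ecar if oligo_ecar is None else oligo_ecar
    ecar_levels = {
        "baseline": basal_ecar,
        "oligomycin": mid_ecar,
        "fccp": mid_ecar,
        "rotenone_antimycin": mid_ecar,
        "monensin": monensin_ecar,
    }
    rows = []
    for wi in range(n_wells):
        well = f"W{wi + 1:02d}"
        for phase in FLUX_PHASES:
            for cyc in range(cycles_per_phase):
                rows.append(
                    (
                        well,
                        phase,
                        cyc + 1,
                        ocr_levels[phase] + rng.normal(0, noise_sd),
                        ecar_levels[phase] + rng.normal(0, noise_sd),
                    )
                )
    data = pd.DataFrame(rows, columns=["well", "phase", "cycle", "ocr", "ecar"])
    counts = pd.Series(
        cell_count, index=pd.Index([f"W{w + 1:02d}" for w in range(n_wells)], name="well")
    )
    return FluxRun(data=data, cell_counts=counts)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_ct_table(
    fold_changes: dict[str, float],
    target: str = "GENE",
    reference: str = "TBP",
    control_condition: str = "control",
    base_target_ct: float = 25.0,
    base_reference_ct: float = 20.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table realizing given fold changes relative to a control.

    ``fold_changes`` maps condition -> intended fold (the control
    condition is forced to 1).  One sample per condition with
    ``replicates`` technical replicate wells per target.
    """
    rng = np.random.default_rng(seed)
    folds = dict(fold_changes)
    folds.setdefault(control_condition, 1.0)
    rows = []
    for cond, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"fold change must be positive, got {fold} for {cond}")
        sample = f"S_{cond}"
        target_ct = base_target_ct - np.log2(fold)
        for _ in range(replicates):
            rows.append(
                (sample, cond, target, target_ct + rng.normal(0, noise_sd))
            )
            rows.append(
                (sample, cond, reference, base_reference_ct + rng.normal(0, noise_sd))
            )
    return pd.DataFrame(rows, columns=["sample", "condition", "target", "ct"])
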