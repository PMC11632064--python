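"""Expression-dependency correlation screen.

Per-gene Spearman correlation of transcript abundance against the effect
scores of each perturbation approach (CRISPR knockout, RNAi knockdown,
inhibitor treatment), followed by an evidence-count selection rule: a gene
enters the signature when it correlates significantly (raw two-sided
P < alpha) with at least ``min_evidence`` approaches.  Genes whose
significant correlations all share a positive sign are "resistance"
transcripts (high expression, mild proliferation impact), all-negative
genes are "sensitizing", and sign conflicts are reported separately as
discordant rather than silently dropped.

Effect scores follow the DepMap polarity convention throughout: a higher
score means the perturbation impaired proliferation less, i.e. the cell
line is more resistant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectMatrix",
    "SpearmanResult",
    "SelectionResult",
    "spearman",
    "correlate_all",
    "select_signature",
]

ORIENTATION = "higher_is_resistant"

#: largest n for which exact permutation P values are offered; above this
#: the enumeration (n! orderings) is no longer tractable.
EXACT_PERM_MAX_N = 9


@dataclass
class EffectMatrix:
    """Cell-lines x approaches perturbation effect scores.

    ``values`` holds one column per approach (NaN = line absent from that
    screen); ``modalities`` tags each approach as crispr / rnai / drug;
    ``orientation`` records the score polarity and must equal
    ``"higher_is_resistant"`` (asserted by loaders).
    """

    values: pd.DataFrame
    modalities: dict[str, str] = field(default_factory=dict)
    orientation: str = ORIENTATION

    def __post_init__(self) -> None:
        if self.orientation != ORIENTATION:
            raise ValueError(
                f"effect matrix orientation must be {ORIENTATION!r}, "
                f"got {self.orientation!r}"
            )
        if self.values.columns.has_duplicates:
            raise ValueError("approach identifiers must be unique")
        if self.values.index.has_duplicates:
            raise ValueError("cell-line identifiers must be unique")

    @property
    def approaches(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n_pairs: int
    insufficient: bool = False


@dataclass
class SelectionResult:
    """Outcome of the evidence-count selection rule.

    The three gene sets are pairwise disjoint; ``evidence`` holds one row
    per significant (gene, approach) record of every selected gene.
    """

    resistance_genes: list[str]
    sensitizing_genes: list[str]
    discordant_genes: list[str]
    evidence: pd.DataFrame
    alpha: float
    min_evidence: int

    @property
    def selected_genes(self) -> list[str]:
        return sorted(
            set(self.resistance_genes)
            | set(self.sensitizing_genes)
            | set(self.discordant_genes)
        )

    def counts(self) -> dict[str, int]:
        return {
            "resistance": len(self.resistance_genes),
            "sensitizing": len(self.sensitizing_genes),
            "discordant": len(self.discordant_genes),
        }


def _validate_min_pairs(min_pairs: int) -> None:
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3 (Spearman undefined below)")


def spearman(
    x,
    y,
    min_pairs: int = 10,
    method: str = "t",
) -> SpearmanResult:
    """Spearman rank correlation with pairwise-complete handling.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    ``method="t"`` gives the two-sided P from the t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom; it is the
    default and appropriate for panels of tens to hundreds of cell lines.
    ``method="exact"`` enumerates all permutations of one rank vector
    (n <= 9) and is the small-sample reference.

    Pairs with a missing value in either vector are dropped.  Fewer than
    ``min_pairs`` complete pairs, or a constant vector, yields an
    insufficient-data flag instead of an exception.
    """
    _validate_min_pairs(min_pairs)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            if set(x.index) != set(y.index):
                raise ValueError("x and y do not share an index")
            y = y.reindex(x.index)
        xv = x.to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValueError(
                f"x and y have mismatched lengths ({xv.size} vs {yv.size})"
            )
    mask = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[mask], yv[mask]
    n = int(xv.size)
    if n < min_pairs or np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpearmanResult(np.nan, np.nan, n, insufficient=True)

    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    if method == "t":
        res = stats.spearmanr(xv, yv)
        return SpearmanResult(float(res.statistic), float(res.pvalue), n)
    if method == "exact":
        if n > EXACT_PERM_MAX_N:
            raise ValueError(
                f"exact permutation P limited to n <= {EXACT_PERM_MAX_N}, got {n}"
            )
        rho = _rank_pearson(rx, ry)
        return SpearmanResult(rho, _exact_perm_pvalue(rx, ry, rho), n)
    raise ValueError(f"unknown method {method!r}")


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def _exact_perm_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact P: fraction of the n! orderings of the y mid-ranks
    whose |rho| reaches |rho_obs| (within 1e-12, so rank ties do not leak
    spurious discreteness)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    num = ryc @ rxc
    den = np.sqrt((rxc @ rxc) * np.sum(ryc * ryc, axis=1))
    rho_all = num / den
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def _column_spearman_vs_vector(
    X: np.ndarray, y: np.ndarray, min_pairs: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spearman rho/P of every column of X (no NaNs) against y (no NaNs).

    Vectorized mid-rank Pearson with the t-approximation P; returns
    (rho, p, n_pairs, insufficient). Constant columns are flagged.
    """
    n = y.size
    n_genes = X.shape[1]
    rho = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    npairs = np.full(n_genes, n, dtype=int)
    insufficient = np.zeros(n_genes, dtype=bool)
    if n < min_pairs or np.ptp(y) == 0:
        insufficient[:] = True
        return rho, p, npairs, insufficient

    R = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    Rc = R - R.mean(axis=0)
    ryc = ry - ry.mean()
    ssx = np.sum(Rc * Rc, axis=0)
    const = ssx == 0
    insufficient |= const
    den = np.sqrt(ssx * (ryc @ ryc))
    den[const] = np.nan
    r = (Rc.T @ ryc) / den
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pv = np.where(np.abs(r) >= 1.0, 0.0, pv)
    rho[~const] = r[~const]
    p[~const] = pv[~const]
    return rho, p, npairs, insufficient


def correlate_all(
    expression: pd.DataFrame,
    effects: EffectMatrix | pd.DataFrame,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Correlate every gene against every approach, pairwise-complete.

    ``expression`` is cell lines x genes (log-scale abundance); the
    cell-line intersection with the effect matrix is recomputed per
    approach against that approach's missing pattern.  Returns a long
    table with one row per (gene, approach): columns gene, approach, rho,
    p_value, n_pairs, insufficient, ordered by gene then approach.
    """
    _validate_min_pairs(min_pairs)
    eff = effects.values if isinstance(effects, EffectMatrix) else effects
    if expression.index.has_duplicates or expression.columns.has_duplicates:
        raise ValueError("expression identifiers must be unique on both axes")
    common = expression.index.intersection(eff.index)
    if len(common) == 0:
        raise ValueError(
            "no shared cell lines between the expression panel "
            f"({len(expression.index)} lines) and the effect panel "
            f"({len(eff.index)} lines)"
        )
    if len(common) < min_pairs:
        raise ValueError(
            f"only {len(common)} shared cell lines; min_pairs={min_pairs}"
        )
    expr = expression.loc[common]
    eff = eff.loc[common]
    genes = list(expr.columns)
    blocks = []
    for approach in eff.columns:
        yfull = eff[approach].to_numpy(dtype=float)
        ymask = ~np.isnan(yfull)
        Xfull = expr.to_numpy(dtype=float)
        X = Xfull[ymask]
        y = yfull[ymask]
        gene_nan = np.isnan(X).any(axis=0)
        rho = np.full(len(genes), np.nan)
        p = np.full(len(genes), np.nan)
        npairs = np.zeros(len(genes), dtype=int)
        insufficient = np.ones(len(genes), dtype=bool)
        clean = ~gene_nan
        if clean.any():
            r, pv, npr, ins = _column_spearman_vs_vector(
                X[:, clean], y, min_pairs
            )
            rho[clean], p[clean], npairs[clean] = r, pv, npr
            insufficient[clean] = ins
        for j in np.nonzero(gene_nan)[0]:
            res = spearman(X[:, j], y, min_pairs=min_pairs)
            rho[j], p[j], npairs[j] = res.rho, res.p_value, res.n_pairs
            insufficient[j] = res.insufficient
        blocks.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "approach": approach,
                    "rho": rho,
                    "p_value": p,
                    "n_pairs": npairs,
                    "insufficient": insufficient,
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    out = out.sort_values(["gene", "approach"], kind="mergesort").reset_index(
        drop=True
    )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def select_signature(
    corr: pd.DataFrame,
    alpha: float = 0.05,
    min_evidence: int = 2,
    bh: bool = False,
) -> SelectionResult:
    """Evidence-count selection: keep genes with >= ``min_evidence``
    approaches at P < ``alpha``.

    Direction is resistance when every significant rho is positive,
    sensitizing when every one is negative, discordant on a sign conflict.
    Insufficient-data records never count as evidence.  ``bh=True``
    applies Benjamini-Hochberg within each approach before thresholding
    (off by default: the screen's published form filters on raw P).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if min_evidence < 1:
        raise ValueError(f"min_evidence must be >= 1, got {min_evidence}")
    if corr.empty:
        raise ValueError("correlation table is empty")
    tab = corr.copy()
    pcol = "p_value"
    if bh:
        tab["p_adj"] = np.nan
        for _, idx in tab.groupby("approach").groups.items():
            tab.loc[idx, "p_adj"] = bh_adjust(tab.loc[idx, "p_value"].to_numpy())
        pcol = "p_adj"
    usable = ~tab["insufficient"].astype(bool)
    sig = tab[usable & (tab[pcol] < alpha)]

    resistance, sensitizing, discordant = [], [], []
    evidence_rows = []
    for gene, grp in sig.groupby("gene", sort=True):
        if len(grp) < min_evidence:
            continue
        signs = np.sign(grp["rho"].to_numpy())
        if np.all(signs > 0):
            resistance.append(gene)
        elif np.all(signs < 0):
            sensitizing.append(gene)
        else:
            discordant.append(gene)
        evidence_rows.append(grp)
    evidence = (
        pd.concat(evidence_rows, ignore_index=True)
        if evidence_rows
        else pd.DataFrame(columns=list(tab.columns))
    )
    return SelectionResult(
        resistance_genes=sorted(resistance),
        sensitizing_genes=sorted(sensitizing),
        discordant_genes=sorted(discordant),
        evidence=evidence,
        alpha=alpha,
        min_evidence=min_evidence,
    )
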