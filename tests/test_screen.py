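"""Spearman correlation, pairwise-complete screening and signature selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mitoscreen as ms
from mitoscreen.screen import bh_adjust

from conftest import spearman_oracle


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
            # classic no-tie formula 1 - 6*sum(d^2)/(n(n^2-1)): d = (1,1,1,1)
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_known_values(self, x, y, expected):
        res = ms.spearman(x, y, min_pairs=3)
        assert res.rho == pytest.approx(expected, abs=1e-12)
        assert not res.insufficient

    def test_perfect_correlation_has_minimal_p(self):
        res = ms.spearman([1, 2, 3, 4, 5, 6], [1, 4, 9, 16, 25, 36], min_pairs=3)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_pairwise_complete_drops_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0, 12.0]
        res = ms.spearman(x, y, min_pairs=4)
        assert res.n_pairs == 4
        assert res.rho == pytest.approx(1.0)

    def test_constant_vector_is_flagged_not_raised(self):
        res = ms.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], min_pairs=3)
        assert res.insufficient and np.isnan(res.rho)

    def test_too_few_pairs_flagged(self):
        res = ms.spearman([1, 2, 3], [3, 1, 2], min_pairs=10)
        assert res.insufficient and res.n_pairs == 3

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="mismatch"):
            ms.spearman([1, 2, 3], [1, 2], min_pairs=3)

    def test_series_with_different_index_order_aligned(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([8.0, 6.0, 4.0, 2.0], index=list("dcba"))
        res = ms.spearman(x, y, min_pairs=3)
        assert res.rho == pytest.approx(1.0)

    def test_oracle_agreement_with_ties(self):
        """Mid-rank Pearson must match the brute-force oracle to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 4, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = ms.spearman(x, y, min_pairs=3)
            assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_exact_permutation_matches_enumeration_oracle(self):
        """Exact P equals the fraction of all orderings with |rho| >= |obs|."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 6
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = ms.spearman(x, y, min_pairs=3, method="exact")
            obs = spearman_oracle(x, y)
            count = 0
            total = 0
            for perm in itertools.permutations(y):
                total += 1
                if abs(spearman_oracle(x, perm)) >= abs(obs) - 1e-12:
                    count += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=10,
            max_size=25,
        ),
        scale=st.floats(0.1, 5.0),
    )
    def test_rank_invariance_under_monotone_transform(self, data, scale):
        x = np.array([d[0] for d in data], dtype=float)
        y = np.array([d[1] for d in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        base = ms.spearman(x, y, min_pairs=3)
        warped = ms.spearman(np.exp(scale * x / 50.0), y, min_pairs=3)
        assert warped.rho == pytest.approx(base.rho, abs=1e-10)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-10)


class TestCorrelateAll:
    def test_record_cardinality(self):
        panel = ms.generate_panel(
            n_lines=20, n_genes=5, n_resistance=1, n_sensitizing=1,
            target_rho=0.5, n_approaches=3, signal_approaches_per_gene=1,
            missing_rate=0.0, seed=1,
        )
        corr = ms.correlate_all(panel.expression, panel.effects, min_pairs=5)
        assert len(corr) == 5 * 3
        assert list(corr.columns) == [
            "gene", "approach", "rho", "p_value", "n_pairs", "insufficient",
        ]

    def test_constant_gene_flagged_insufficient(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {"flat": np.ones(15), "ok": rng.normal(size=15)},
            index=[f"L{i}" for i in range(15)],
        )
        eff = pd.DataFrame(
            {"a": rng.normal(size=15)}, index=[f"L{i}" for i in range(15)]
        )
        corr = ms.correlate_all(expr, eff, min_pairs=5)
        assert corr.set_index("gene").loc["flat", "insufficient"]
        assert not corr.set_index("gene").loc["ok", "insufficient"]

    def test_no_shared_lines_raises(self):
        expr = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        eff = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["d", "e", "f"])
        with pytest.raises(ValueError, match="shared cell lines"):
            ms.correlate_all(expr, eff, min_pairs=3)

    def test_pairwise_complete_per_approach(self):
        """n_pairs reflects each approach's own missing pattern."""
        rng = np.random.default_rng(3)
        idx = [f"L{i}" for i in range(30)]
        expr = pd.DataFrame({"g": rng.normal(size=30)}, index=idx)
        eff = pd.DataFrame(
            {"full": rng.normal(size=30), "holey": rng.normal(size=30)}, index=idx
        )
        eff.loc[idx[:8], "holey"] = np.nan
        corr = ms.correlate_all(expr, eff, min_pairs=5).set_index("approach")
        assert corr.loc["full", "n_pairs"] == 30
        assert corr.loc["holey", "n_pairs"] == 22

    def test_planted_gene_recovers_target_rho(self):
        """A resistance gene planted at rho=0.6 lands within 0.1 on its
        signal approaches at n=200."""
        panel = ms.generate_panel(
            n_lines=200, n_genes=30, n_resistance=3, n_sensitizing=3,
            target_rho=0.6, n_approaches=8, signal_approaches_per_gene=4,
            missing_rate=0.0, seed=9,
        )
        corr = ms.correlate_all(panel.expression, panel.effects).set_index(
            ["gene", "approach"]
        )
        for gene in panel.truth.planted_resistance:
            for app in panel.truth.approaches_with_signal[gene]:
                assert corr.loc[(gene, app), "rho"] == pytest.approx(0.6, abs=0.1)
        for gene in panel.truth.planted_sensitizing:
            for app in panel.truth.approaches_with_signal[gene]:
                assert corr.loc[(gene, app), "rho"] == pytest.approx(-0.6, abs=0.1)


def _corr_table(records):
    rows = []
    for gene, approach, rho, p in records:
        rows.append((gene, approach, rho, p, 50, False))
    return pd.DataFrame(
        rows, columns=["gene", "approach", "rho", "p_value", "n_pairs", "insufficient"]
    )


class TestSelectSignature:
    def test_two_positive_evidences_give_resistance(self):
        corr = _corr_table(
            [("g1", "a", 0.5, 0.01), ("g1", "b", 0.4, 0.03), ("g1", "c", 0.1, 0.5)]
        )
        sel = ms.select_signature(corr)
        assert sel.resistance_genes == ["g1"]
        assert sel.sensitizing_genes == [] and sel.discordant_genes == []

    def test_single_evidence_not_selected(self):
        corr = _corr_table([("g1", "a", 0.5, 0.01), ("g1", "b", 0.4, 0.2)])
        sel = ms.select_signature(corr)
        assert sel.selected_genes == []

    def test_sign_conflict_is_discordant(self):
        corr = _corr_table([("g1", "a", 0.5, 0.01), ("g1", "b", -0.5, 0.01)])
        sel = ms.select_signature(corr)
        assert sel.discordant_genes == ["g1"]
        assert sel.resistance_genes == [] and sel.sensitizing_genes == []

    def test_insufficient_records_never_count(self):
        corr = _corr_table([("g1", "a", 0.5, 0.01), ("g1", "b", 0.6, 0.001)])
        corr.loc[1, "insufficient"] = True
        sel = ms.select_signature(corr)
        assert sel.selected_genes == []

    def test_sets_are_disjoint(self, standard_screen):
        _, sel = standard_screen
        r, s, d = (
            set(sel.resistance_genes),
            set(sel.sensitizing_genes),
            set(sel.discordant_genes),
        )
        assert not (r & s) and not (r & d) and not (s & d)

    @pytest.mark.parametrize("alpha2, min_ev2", [(0.01, 2), (0.05, 3), (0.01, 4)])
    def test_selection_monotonicity(self, standard_screen, alpha2, min_ev2):
        """Shrinking alpha or raising min_evidence never adds a gene."""
        corr, sel = standard_screen
        stricter = ms.select_signature(corr, alpha=alpha2, min_evidence=min_ev2)
        assert set(stricter.selected_genes) <= set(sel.selected_genes)

    def test_parameter_validation(self):
        corr = _corr_table([("g1", "a", 0.5, 0.01)])
        with pytest.raises(ValueError):
            ms.select_signature(corr, alpha=1.5)
        with pytest.raises(ValueError):
            ms.select_signature(corr, min_evidence=0)
        with pytest.raises(ValueError):
            ms.select_signature(corr.iloc[:0])

    def test_bh_mode_is_stricter_on_nulls(self):
        panel = ms.generate_panel(
            n_lines=60, n_genes=300, n_resistance=0, n_sensitizing=0,
            target_rho=0.5, n_approaches=6, signal_approaches_per_gene=1,
            missing_rate=0.0, seed=5, approach_correlation=0.0,
        )
        corr = ms.correlate_all(panel.expression, panel.effects)
        raw = ms.select_signature(corr)
        adj = ms.select_signature(corr, bh=True)
        assert set(adj.selected_genes) <= set(raw.selected_genes)

    def test_bh_adjust_matches_direct_computation(self):
        p = np.array([0.01, 0.02, 0.03, 0.5, np.nan])
        adj = bh_adjust(p)
        # step-up: sorted p * m / rank with monotone enforcement
        assert adj[0] == pytest.approx(0.04)
        assert adj[3] == pytest.approx(0.5)
        assert np.isnan(adj[4])
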