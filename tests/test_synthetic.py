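"""Synthetic-panel generators: determinism, planted signal, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mitoscreen as ms
from mitoscreen.synthetic import spearman_to_pearson


class TestGeneratePanel:
    def test_truth_lists_exactly_the_planted_genes(self, standard_panel):
        truth = standard_panel.truth
        assert len(truth.planted_resistance) == 20
        assert len(truth.planted_sensitizing) == 20
        assert not set(truth.planted_resistance) & set(truth.planted_sensitizing)
        assert all(g in standard_panel.expression.columns for g in truth.planted)
        assert all(truth.approaches_with_signal[g] for g in truth.planted)

    def test_seeded_regeneration_is_identical(self):
        a = ms.generate_panel(seed=7)
        b = ms.generate_panel(seed=7)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.effects.values, b.effects.values)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        assert a.truth == b.truth
        c = ms.generate_panel(seed=8)
        assert not a.expression.equals(c.expression)

    def test_missing_rate_is_respected(self, standard_panel):
        frac = standard_panel.effects.values.isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.05)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ms.generate_panel(n_genes=10, n_resistance=8, n_sensitizing=8)
        with pytest.raises(ValueError):
            ms.generate_panel(target_rho=1.2)
        with pytest.raises(ValueError):
            ms.generate_panel(missing_rate=1.0)
        with pytest.raises(ValueError):
            ms.generate_panel(signal_approaches_per_gene=99)

    def test_infeasible_rho_needs_approach_correlation(self):
        with pytest.raises(ValueError, match="approach_correlation"):
            ms.generate_panel(target_rho=0.9, signal_approaches_per_gene=4,
                              approach_correlation=0.0)

    def test_panel_overlap_configuration(self):
        panel = ms.generate_panel(
            n_lines=30, n_genes=20, n_resistance=2, n_sensitizing=2,
            target_rho=0.5, n_approaches=4, signal_approaches_per_gene=2,
            missing_rate=0.0, seed=2,
            n_extra_expression_lines=5, n_extra_effect_lines=7,
        )
        expr_lines = set(panel.expression.index)
        eff_lines = set(panel.effects.values.index)
        assert len(expr_lines & eff_lines) == 30
        assert len(expr_lines - eff_lines) == 5
        assert len(eff_lines - expr_lines) == 7

    def test_planted_correlation_fidelity(self):
        """Mean empirical Spearman of planted genes vs their signal
        approaches is within 0.05 of +/-target_rho over replicates."""
        devs_r, devs_s = [], []
        for seed in range(25):
            panel = ms.generate_panel(
                n_lines=200, n_genes=8, n_resistance=2, n_sensitizing=2,
                target_rho=0.6, n_approaches=8, signal_approaches_per_gene=4,
                missing_rate=0.0, seed=seed,
            )
            eff = panel.effects.values
            for gene in panel.truth.planted:
                for app in panel.truth.approaches_with_signal[gene]:
                    rho = stats.spearmanr(
                        panel.expression[gene], eff[app]
                    ).statistic
                    (devs_r if gene in panel.truth.planted_resistance else devs_s).append(rho)
        assert np.mean(devs_r) == pytest.approx(0.6, abs=0.05)
        assert np.mean(devs_s) == pytest.approx(-0.6, abs=0.05)

    def test_null_pvalues_are_uniform(self):
        """Null genes' screen P values pass a KS uniformity check."""
        panel = ms.generate_panel(
            n_lines=100, n_genes=400, n_resistance=0, n_sensitizing=0,
            target_rho=0.5, n_approaches=4, signal_approaches_per_gene=1,
            missing_rate=0.0, seed=9, approach_correlation=0.0,
        )
        corr = ms.correlate_all(panel.expression, panel.effects)
        p = corr.loc[~corr["insufficient"], "p_value"].to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_annotation_tags_planted_genes_mitochondrial(self, standard_panel):
        ann = standard_panel.annotation
        assert ann.loc[standard_panel.truth.planted, "is_mitochondrial"].all()
        mito = ann["is_mitochondrial"]
        assert (ann.loc[mito, "pathway_labels"] != "").all()

    def test_pearson_spearman_relation(self):
        # rho_S = (6/pi) * arcsin(rho_P / 2) inverts spearman_to_pearson
        for rho_s in (0.2, 0.5, 0.8):
            rho_p = spearman_to_pearson(rho_s)
            assert (6 / np.pi) * np.arcsin(rho_p / 2) == pytest.approx(rho_s)


class TestGenerateDeTable:
    def test_exact_counts_per_state(self):
        states = {"stateA": [f"A{i}" for i in range(10)]}
        de = ms.generate_de_table(states, {"stateA": 0.4}, {"stateA": 0.1}, seed=0)
        calls = ms.call_de(de)
        in_state = calls[calls["gene"].str.startswith("A")]
        assert (in_state["call"] == "up").sum() == 4
        assert (in_state["call"] == "down").sum() == 1

    def test_background_is_nonsignificant(self):
        de = ms.generate_de_table({}, {}, {}, n_background=50, seed=1)
        calls = ms.call_de(de)
        assert (calls["call"] == "not_significant").all()

    def test_zero_fractions_give_zero_polarization(self):
        states = ms.generate_state_sets(10)
        de = ms.generate_de_table(states, {}, {}, seed=4)
        pol = ms.polarization_score(ms.call_de(de), states)
        assert (pol["percent_up"] == 0).all() and (pol["percent_down"] == 0).all()

    def test_fraction_validation(self):
        states = {"s": ["g1", "g2"]}
        with pytest.raises(ValueError, match="exceed"):
            ms.generate_de_table(states, {"s": 0.7}, {"s": 0.5}, seed=0)

    def test_seeded_regeneration_identical(self):
        states = ms.generate_state_sets(5)
        a = ms.generate_de_table(states, {"melanocytic": 0.4}, {}, seed=3)
        b = ms.generate_de_table(states, {"melanocytic": 0.4}, {}, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateFluxRun:
    def test_noise_free_round_trip(self, noise_free_flux_run):
        prof = ms.compute_profile(
            noise_free_flux_run, {w: "g" for w in noise_free_flux_run.wells}
        )
        row = prof.per_group.loc["g"]
        assert row["basal_respiration"] == pytest.approx(80.0)
        assert row["maximal_respiration"] == pytest.approx(160.0)
        assert row["glycolytic_reserve"] == pytest.approx(40.0)

    def test_rotaa_equals_basal_gives_zero_corrected_basal(self):
        run = ms.generate_flux_run(basal_ocr=50, rotaa_ocr=50, noise_sd=0, n_wells=2)
        prof = ms.compute_profile(run, {w: "g" for w in run.wells})
        assert prof.per_group.loc["g", "basal_respiration"] == pytest.approx(0.0)

    def test_seeded_regeneration_identical(self):
        a = ms.generate_flux_run(noise_sd=2.0, seed=5)
        b = ms.generate_flux_run(noise_sd=2.0, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ms.generate_flux_run(n_wells=0)
        with pytest.raises(ValueError):
            ms.generate_flux_run(noise_sd=-1)


class TestGenerateCtTable:
    def test_realizes_requested_folds(self):
        table = ms.generate_ct_table({"treated": 4.0}, seed=0)
        folds = ms.delta_delta_ct(table, "GENE", "TBP", "control")
        by_cond = folds.set_index("condition")["fold_change"]
        assert by_cond["control"] == pytest.approx(1.0)
        assert by_cond["treated"] == pytest.approx(4.0)
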