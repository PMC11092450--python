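"""Dirichlet-multinomial fitting and differential transcript usage tests."""

import numpy as np
import pandas as pd
import pytest

from isocell.dtu import (
    DMFit,
    DTUError,
    adjust_fdr,
    aggregate_rare,
    detect_switching,
    dm_loglik,
    fit_dm,
    lrt_gene,
    lrt_transcript,
    run_dtu,
    test_gene as dtu_test_gene,
)


def simulate_counts(alpha, n_cells, rng, lam=7.5):
    n = rng.poisson(lam, n_cells)
    pi = rng.dirichlet(alpha, n_cells)
    return np.array([rng.multinomial(nc, pc) for nc, pc in zip(n, pi)])


class TestAggregateRare:
    def test_five_percent_rule(self):
        """Pooled totals (900, 60, 40) of 1000: only the 40-count column is
        at or below 5% and is aggregated."""
        X = np.zeros((10, 3), dtype=int)
        X[:, 0], X[:, 1], X[:, 2] = 90, 6, 4
        data = aggregate_rare(X, np.array(["A"] * 5 + ["B"] * 5))
        assert data.K == 3
        assert data.columns == ["iso1", "iso2", "rare"]
        assert data.X[:, 2].sum() == 40
        assert data.rare_index == 2

    def test_exactly_five_percent_is_aggregated(self):
        X = np.zeros((4, 2), dtype=int)
        X[:, 0], X[:, 1] = 95, 5  # pooled: 380 vs 20 = exactly 5%
        data = aggregate_rare(X, np.array(["A", "A", "B", "B"]))
        assert data.columns[-1] == "rare"
        assert data.rare_index == 1

    def test_low_count_gene_excluded(self):
        X = np.array([[5, 5], [3, 2]])
        data = aggregate_rare(X, np.array(["A", "B"]))
        assert data.excluded and data.exclusion_reason == "gene_read_floor"

    def test_balanced_gene_unchanged(self):
        X = np.tile([50, 50], (10, 1))
        data = aggregate_rare(X, np.array(["A"] * 5 + ["B"] * 5))
        assert data.K == 2 and data.rare_index is None

    def test_all_but_one_rare_collapses_to_untestable(self):
        X = np.tile([98, 1, 1], (20, 1))
        data = aggregate_rare(X, np.array(["A", "B"] * 10))
        assert data.K == 2  # dominant + merged rare stays testable


class TestFitDM:
    def test_phi_formula(self):
        fit = DMFit(alpha=np.array([1.0, 1.0]), loglik=0.0)
        assert fit.phi == pytest.approx(1 / 3)
        assert fit.pi_bar.tolist() == [0.5, 0.5]

    def test_near_exclusive_expression(self):
        rng = np.random.default_rng(0)
        X = np.zeros((50, 2), dtype=int)
        X[:, 0] = rng.poisson(8, 50) + 1
        fit = fit_dm(X)
        assert fit.pi_bar[0] > 0.99
        assert fit.boundary or fit.alpha[1] < 0.01

    def test_simulated_recovery_beats_grid_oracle(self):
        """MLE log-likelihood dominates a 3-D grid search and pi_bar lands
        within 0.03 of the truth."""
        rng = np.random.default_rng(42)
        alpha = np.array([4.0, 2.0, 2.0])
        X = simulate_counts(alpha, 400, rng)
        fit = fit_dm(X)
        grid = np.arange(0.1, 8.01, 0.1)
        best = -np.inf
        for a1 in grid[::4]:
            for a2 in grid[::4]:
                for a3 in grid[::4]:
                    best = max(best, dm_loglik(np.array([a1, a2, a3]), X))
        assert fit.loglik >= best - 1e-6
        assert np.abs(fit.pi_bar - alpha / alpha.sum()).max() < 0.03

    def test_mean_invariance_of_pi(self):
        """Scaling alpha changes phi but the fitted pi_bar stays put."""
        rng = np.random.default_rng(7)
        base = np.array([3.0, 1.5, 1.5])
        pis = []
        for scale in (0.5, 4.0):
            X = simulate_counts(base * scale, 800, rng)
            pis.append(fit_dm(X).pi_bar)
        assert np.abs(pis[0] - pis[1]).max() < 0.05

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DTUError):
            fit_dm(np.zeros((5, 2)))
        with pytest.raises(DTUError):
            fit_dm(np.array([[3, 1]]))

    def test_phi_recovery_correlates(self):
        """Across genes, fitted phi tracks the true phi (Spearman > 0.8)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        true_phi, est_phi = [], []
        for _ in range(30):
            alpha = np.clip(rng.gamma(2, 2, 3), 0.05, None)
            X = simulate_counts(alpha, 300, rng)
            true_phi.append(1 / (1 + alpha.sum()))
            est_phi.append(fit_dm(X).phi)
        assert spearmanr(true_phi, est_phi).statistic > 0.8


class TestLRT:
    def _data(self, XA, XB):
        X = np.vstack([XA, XB])
        labels = np.array(["A"] * len(XA) + ["B"] * len(XB))
        return aggregate_rare(X, labels)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        X = simulate_counts(np.array([3.0, 2.0]), 100, rng)
        data = self._data(X, X.copy())
        stat, p = lrt_gene(data)
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert p > 0.99

    def test_opposite_compositions_detected(self):
        rng = np.random.default_rng(1)
        XA = simulate_counts(np.array([8.0, 2.0]), 500, rng)
        XB = simulate_counts(np.array([2.0, 8.0]), 500, rng)
        stat, p = lrt_gene(self._data(XA, XB))
        assert p < 1e-6

    def test_statistic_nonnegative_and_nested(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            alpha = np.clip(rng.gamma(2, 2, 3), 0.05, None)
            XA = simulate_counts(alpha, 60, rng)
            XB = simulate_counts(alpha, 60, rng)
            data = self._data(XA, XB)
            if data.excluded:
                continue
            stat, _ = lrt_gene(data)
            assert stat >= 0

    def test_transcript_test_k2_equals_gene_test(self):
        rng = np.random.default_rng(9)
        XA = simulate_counts(np.array([5.0, 3.0]), 150, rng)
        XB = simulate_counts(np.array([3.0, 5.0]), 150, rng)
        data = self._data(XA, XB)
        assert data.K == 2
        sg, pg = lrt_gene(data)
        st, pt = lrt_transcript(data, 0)
        assert sg == pytest.approx(st, rel=1e-6)
        assert pg == pytest.approx(pt, rel=1e-6)

    def test_targeted_component_detected_others_null(self):
        """Only the perturbed isoform's transcript test fires."""
        rng = np.random.default_rng(11)
        # same composition except component 0 swapped with component 1
        XA = simulate_counts(np.array([6.0, 3.0, 3.0]), 400, rng)
        XB = simulate_counts(np.array([3.0, 6.0, 3.0]), 400, rng)
        data = self._data(XA, XB)
        assert data.K == 3
        _, p0 = lrt_transcript(data, 0)
        _, p2 = lrt_transcript(data, 2)
        assert p0 < 1e-4
        assert p2 > 0.01


class TestSwitching:
    def test_switch_and_effect_size(self):
        fa = DMFit(alpha=np.array([9.0, 1.0]), loglik=0)
        fb = DMFit(alpha=np.array([1.0, 9.0]), loglik=0)
        sw, eff, da, db = detect_switching(fa, fb, ["t1", "t2"])
        assert sw and da == "t1" and db == "t2"
        assert eff == pytest.approx(1.6)

    def test_no_switch(self):
        f = DMFit(alpha=np.array([5.0, 2.0]), loglik=0)
        sw, eff, _, _ = detect_switching(f, f, ["t1", "t2"])
        assert not sw and np.isnan(eff)

    def test_rare_column_excluded_from_dominance(self):
        fa = DMFit(alpha=np.array([2.0, 1.0, 10.0]), loglik=0)
        fb = DMFit(alpha=np.array([1.0, 2.0, 10.0]), loglik=0)
        sw, _, da, db = detect_switching(fa, fb, ["t1", "t2", "rare"],
                                         rare_index=2)
        assert sw and da == "t1" and db == "t2"


class TestFDR:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.04]).tolist() == [0.04]

    def test_textbook_bh(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_nan_passthrough(self):
        out = adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(out[1]) and not np.isnan(out[0])


def test_run_dtu_end_to_end_tables():
    """Two DTU genes out of four are flagged; padj >= p everywhere."""
    rng = np.random.default_rng(21)
    barcodes = [f"A{i}" for i in range(200)] + [f"B{i}" for i in range(200)]
    groups = pd.Series(["A"] * 200 + ["B"] * 200, index=barcodes)
    rows = []
    specs = {
        "g1": (np.array([6.0, 2.0]), np.array([2.0, 6.0])),  # DTU
        "g2": (np.array([4.0, 4.0]), np.array([4.0, 4.0])),  # null
        "g3": (np.array([1.0, 5.0, 2.0]), np.array([5.0, 1.0, 2.0])),  # DTU
        "g4": (np.array([3.0, 3.0, 3.0]), np.array([3.0, 3.0, 3.0])),  # null
    }
    for gid, (aA, aB) in specs.items():
        XA = simulate_counts(aA, 200, rng)
        XB = simulate_counts(aB, 200, rng)
        X = np.vstack([XA, XB])
        for k in range(X.shape[1]):
            rows.append(pd.Series(
                {"gene_id": gid, "isoform_id": f"t{k + 1}",
                 **dict(zip(barcodes, X[:, k]))}
            ))
    counts = pd.DataFrame(rows)
    gene_table, tx_table = run_dtu(counts, groups)
    gt = gene_table.set_index("gene_id")
    assert gt.loc["g1", "padj"] < 0.01 and gt.loc["g3", "padj"] < 0.01
    assert gt.loc["g2", "padj"] > 0.05 and gt.loc["g4", "padj"] > 0.05
    assert (gene_table["padj"] >= gene_table["p"] - 1e-12).all()
    assert (tx_table["padj"] >= tx_table["p"] - 1e-12).all()
    assert bool(gt.loc["g1", "switching"]) is True
    assert 0 <= gt.loc["g1", "effect_size"] <= 2


def test_bootstrap_sd_columns():
    rng = np.random.default_rng(2)
    X = simulate_counts(np.array([4.0, 2.0]), 120, rng)
    labels = np.array(["A", "B"] * 60)
    res = dtu_test_gene("g", X, labels, n_boot=20, rng=rng)
    sd = res.transcript_stats["pi_A_sd"]
    assert (sd.dropna() > 0).all() and (sd.dropna() < 0.5).all()
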