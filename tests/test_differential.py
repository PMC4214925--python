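import numpy as np
import pandas as pd
import pytest

from trainmap.differential import (
    bh_adjust,
    factorial_test,
    factorial_test_matrix,
    run_differential,
    select_responders,
)

from conftest import cell_means_matrix, make_annotations, make_matrix


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Explicit min-over-suffix step-up, independent of the implementation."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_textbook_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_constant_vector_unchanged(self):
        out = bh_adjust([0.2] * 7)
        assert np.allclose(out, 0.2)

    def test_matches_min_over_suffix_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.abs(bh_adjust(p) - bh_oracle(p)).max() < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q, atol=1e-12)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([-0.1])

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=300)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestFactorialTest:
    def test_noiseless_additive_truth_has_zero_interaction(self):
        means = {
            ("trainer", "baseline"): 8.0,
            ("trainer", "stimulated"): 9.0,
            ("comparator", "baseline"): 8.0,
            ("comparator", "stimulated"): 9.0,
        }
        rng = np.random.default_rng(0)
        m = cell_means_matrix(means, 0.0, 5, 3, rng)
        out = factorial_test_matrix(m)
        assert np.allclose(out["interaction_estimate"], 0.0, atol=1e-10)
        assert np.allclose(out["beta_comparator"], 1.0, atol=1e-10)
        assert np.allclose(out["beta_trainer"], 1.0, atol=1e-10)

    def test_betas_recover_cell_mean_contrasts(self):
        means = {
            ("trainer", "baseline"): 8.0,
            ("trainer", "stimulated"): 10.5,
            ("comparator", "baseline"): 8.0,
            ("comparator", "stimulated"): 8.5,
        }
        rng = np.random.default_rng(1)
        m = cell_means_matrix(means, 0.0, 3, 2, rng)
        out = factorial_test_matrix(m)
        assert np.allclose(out["beta_trainer"], 2.5, atol=1e-10)
        assert np.allclose(out["beta_comparator"], 0.5, atol=1e-10)
        assert np.allclose(out["interaction_estimate"], 2.0, atol=1e-10)

    def test_f_matches_nested_rss_oracle(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(8, 1, size=(20, 12)), replicates=3)
        out = factorial_test_matrix(m)
        ann = m.annotations.loc[m.sample_ids]
        stim = (ann["state"] == "stimulated").to_numpy(float)
        trn = (ann["stimulus"] == "trainer").to_numpy(float)
        x1 = np.column_stack([np.ones_like(stim), stim, trn, stim * trn])
        x0 = x1[:, :3]
        for i, gene in enumerate(m.gene_ids):
            y = m.values.loc[gene].to_numpy()
            rss1 = np.sum((y - x1 @ np.linalg.lstsq(x1, y, rcond=None)[0]) ** 2)
            rss0 = np.sum((y - x0 @ np.linalg.lstsq(x0, y, rcond=None)[0]) ** 2)
            f_oracle = (rss0 - rss1) / (rss1 / (len(y) - 4))
            assert out["F"].iloc[i] == pytest.approx(f_oracle, rel=1e-9)

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(8, 1, size=(5, 12)), replicates=3)
        out = factorial_test_matrix(m)
        ann = m.annotations.loc[m.sample_ids]
        stim = (ann["state"] == "stimulated").astype(float)
        trn = (ann["stimulus"] == "trainer").astype(float)
        x = sm.add_constant(
            pd.DataFrame({"stim": stim, "trn": trn, "inter": stim * trn})
        )
        for gene in m.gene_ids:
            fit = sm.OLS(m.values.loc[gene].to_numpy(), x).fit()
            assert out.loc[gene, "p_interaction"] == pytest.approx(
                fit.pvalues["inter"], rel=1e-9
            )
            assert out.loc[gene, "interaction_estimate"] == pytest.approx(
                fit.params["inter"], rel=1e-9
            )

    def test_interaction_recovery_under_noise(self):
        # c=2 with sd 0.1 at 2 replicates/cell: estimate within 0.5 of truth
        # in at least 95% of simulations
        means = {
            ("trainer", "baseline"): 8.0,
            ("trainer", "stimulated"): 10.0,
            ("comparator", "baseline"): 8.0,
            ("comparator", "stimulated"): 8.0,
        }
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 400
        m = cell_means_matrix(means, 0.1, n_sim, 2, rng)
        out = factorial_test_matrix(m)
        hits = (np.abs(out["interaction_estimate"] - 2.0) < 0.5).sum()
        assert hits / n_sim >= 0.95

    def test_zero_variance_interaction_reported_extreme(self, caplog):
        # constant within cells, different across: c != 0, zero residual
        means = {
            ("trainer", "baseline"): 8.0,
            ("trainer", "stimulated"): 10.0,
            ("comparator", "baseline"): 8.0,
            ("comparator", "stimulated"): 8.0,
        }
        rng = np.random.default_rng(5)
        m = cell_means_matrix(means, 0.0, 2, 2, rng)
        with caplog.at_level("WARNING"):
            out = factorial_test_matrix(m)
        assert (out["p_interaction"] == 0.0).all()
        assert "zero residual" in caplog.text
        flat = cell_means_matrix({k: 8.0 for k in means}, 0.0, 2, 2, rng)
        out_flat = factorial_test_matrix(flat)
        assert (out_flat["p_interaction"] == 1.0).all()

    def test_missing_cell_fatal_names_cell(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(3, 8)))
        from trainmap.io_formats import ExpressionMatrix

        values = m.values.drop(columns=m.samples_in("comparator", "stimulated"))
        short = ExpressionMatrix(values=values, annotations=m.annotations)
        with pytest.raises(ValueError, match=r"comparator.*stimulated"):
            factorial_test_matrix(short)

    def test_single_gene_wrapper_agrees(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(8, 1, size=(1, 12)), replicates=3)
        table = factorial_test_matrix(m)
        bt, bc, f, p = factorial_test(m.values.iloc[0], m.annotations)
        assert bt == pytest.approx(table["beta_trainer"].iloc[0])
        assert bc == pytest.approx(table["beta_comparator"].iloc[0])
        assert f == pytest.approx(table["F"].iloc[0])
        assert p == pytest.approx(table["p_interaction"].iloc[0])


class TestSelection:
    @staticmethod
    def _results(rows):
        frame = pd.DataFrame(
            rows,
            columns=["gene", "cluster", "interaction_estimate", "p_interaction"],
        ).set_index("gene")
        return frame

    def test_direction_and_significance_gates(self):
        results = self._results(
            [
                ("up_sig", 0, 1.5, 0.0001),
                ("up_weak", 0, 1.5, 0.8),
                ("down_sig", 0, -1.5, 0.0001),
            ]
        )
        selected = select_responders(results, alpha=0.05, per_cluster=False)
        assert selected == ["up_sig"]

    def test_selection_monotone_in_alpha(self):
        rng = np.random.default_rng(8)
        results = self._results(
            [
                (f"g{i}", int(i % 3), rng.normal(), rng.uniform())
                for i in range(200)
            ]
        )
        previous: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5, 1.0):
            current = set(select_responders(results, alpha=alpha))
            assert previous <= current
            previous = current

    def test_per_cluster_vs_global_families(self):
        # one tight cluster of small p-values is diluted by a global family
        rows = [(f"s{i}", 0, 1.0, 0.004) for i in range(10)]
        rows += [(f"n{i}", 1, 1.0, 0.9) for i in range(90)]
        results = self._results(rows)
        per_cluster = set(select_responders(results, alpha=0.05, per_cluster=True))
        global_bh = set(select_responders(results, alpha=0.05, per_cluster=False))
        assert per_cluster == {f"s{i}" for i in range(10)}
        assert global_bh <= per_cluster

    def test_run_differential_output_contract(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(8, 1, size=(30, 12)), replicates=3)
        clusters = pd.Series(rng.integers(0, 3, 30), index=m.gene_ids)
        out = run_differential(m, clusters, alpha=0.05)
        assert (out["p_adjusted"] >= out["p_interaction"] - 1e-15).all()
        assert (
            out.loc[out["selected"], "interaction_estimate"] > 0
        ).all()
        assert (out.loc[out["selected"], "p_adjusted"] < 0.05).all()
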