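import numpy as np
import pandas as pd
import pytest

from protraits import (
    TraitTable,
    TraitRegime,
    loess_fit,
    pca_loading_significance,
    run_pca,
    sim_trait_table,
    spearman_matrix,
    stratified_correlations,
    transform_traits,
)

from oracles import spearman_bruteforce


def _table(**cols):
    n = len(next(iter(cols.values())))
    return TraitTable(pd.DataFrame(cols, index=[f"r{i}" for i in range(n)]))


class TestTransform:
    def test_hgt_log_shift_handles_zero(self):
        t = transform_traits(_table(pct_hgt=[0.0, 1.0]))
        assert t.data["pct_hgt"].iloc[0] == pytest.approx(np.log(0.001))
        assert t.data["pct_hgt"].iloc[1] == pytest.approx(np.log(1.001))

    def test_generation_time_log(self):
        t = transform_traits(_table(generation_time=[1.0, np.e]))
        assert t.data["generation_time"].tolist() == pytest.approx([0.0, 1.0])

    def test_rrn_and_prophages_untouched(self):
        t = transform_traits(_table(rrn=[7.0], prophages=[3.0]))
        assert t.data["rrn"].iloc[0] == 7.0
        assert t.data["prophages"].iloc[0] == 3.0

    def test_double_transform_rejected(self):
        t = transform_traits(_table(pct_hgt=[1.0]))
        with pytest.raises(ValueError, match="transformed"):
            transform_traits(t)


class TestPca:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 20)
        res = run_pca(_table(a=x, b=2 * x + 1), ["a", "b"])
        assert res.explained_variance["PC1"] == pytest.approx(100.0)
        assert res.loadings["PC1"].tolist() == pytest.approx([1.0, 1.0])

    def test_constant_column_rejected_by_name(self):
        with pytest.raises(ValueError, match="b"):
            run_pca(_table(a=[1.0, 2.0, 3.0], b=[5.0, 5.0, 5.0]), ["a", "b"])

    def test_explained_variance_sums_to_100_and_is_sorted(self):
        rng = np.random.default_rng(0)
        res = run_pca(
            _table(**{f"t{i}": rng.normal(size=40) for i in range(6)}),
            [f"t{i}" for i in range(6)],
        )
        ev = res.explained_variance.to_numpy()
        assert ev.sum() == pytest.approx(100.0)
        assert (np.diff(ev) <= 1e-9).all()

    def test_loadings_are_trait_score_correlations(self):
        rng = np.random.default_rng(1)
        traits = [f"t{i}" for i in range(5)]
        base = rng.normal(size=50)
        cols = {t: base * w + rng.normal(size=50) for t, w in zip(traits, [2, 1, 0.5, 0, 0])}
        res = run_pca(_table(**cols), traits)
        df = pd.DataFrame(cols)
        z = (df - df.mean()) / df.std(ddof=1)
        for t in traits:
            for c in res.scores.columns:
                expected = np.corrcoef(z[t], res.scores[c])[0, 1]
                assert res.loadings.loc[t, c] == pytest.approx(expected, abs=1e-9)

    def test_identity_covariance_gives_flat_spectrum(self):
        rng = np.random.default_rng(2)
        traits = [f"t{i}" for i in range(9)]
        res = run_pca(
            _table(**{t: rng.normal(size=4000) for t in traits}), traits
        )
        assert res.explained_variance.max() < 14.0  # each component near 100/9


class TestPcaPermutation:
    def test_aligned_trait_attains_minimal_p(self):
        x = np.linspace(0, 1, 40)
        table = _table(a=x, b=x + 0.01 * np.random.default_rng(0).normal(size=40))
        p = pca_loading_significance(table, ["a", "b"], n_perm=49, seed=1)
        assert p.loc["a", "PC1"] == pytest.approx(1 / 50)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        table = _table(a=rng.normal(size=30), b=rng.normal(size=30))
        p1 = pca_loading_significance(table, ["a", "b"], n_perm=20, seed=7)
        p2 = pca_loading_significance(table, ["a", "b"], n_perm=20, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            pca_loading_significance(_table(a=[1.0, 2.0, 3.0]), ["a"], n_perm=0)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(-2, 2, 20)
        res = spearman_matrix(_table(a=x, b=x**3), ["a", "b"])
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.linspace(0, 1, 15)
        res = spearman_matrix(_table(a=x, b=-x), ["a", "b"])
        assert res.rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman_matrix(
            _table(a=[1.0, 2.0, 3.0, 4.0], b=[1.0, 3.0, 2.0, 4.0]), ["a", "b"]
        )
        assert res.rho.loc["a", "b"] == pytest.approx(0.8)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = rng.integers(8, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            # inject ties
            x[: n // 4] = x[0]
            res = spearman_matrix(_table(a=x, b=y), ["a", "b"])
            assert res.rho.loc["a", "b"] == pytest.approx(
                spearman_bruteforce(x, y), abs=1e-12
            )

    def test_bonferroni_scaling_and_pairwise_complete(self):
        rng = np.random.default_rng(5)
        traits = [f"t{i}" for i in range(4)]
        cols = {t: rng.normal(size=30) for t in traits}
        cols["t0"][:5] = np.nan
        res = spearman_matrix(_table(**cols), traits)
        assert res.m_tests == 6
        assert res.n.loc["t0", "t1"] == 25
        mask = res.p_adj < 1
        ratio = (res.p_adj[mask] / res.p_raw[mask]).stack()
        assert np.allclose(ratio, res.m_tests)

    def test_short_pairs_give_missing_cells(self):
        cols = {"a": [1.0, 2.0, np.nan, np.nan, np.nan],
                "b": [1.0, np.nan, 2.0, 3.0, 4.0],
                "c": [1.0, 2.0, 3.0, 4.0, 5.0]}
        res = spearman_matrix(_table(**cols), ["a", "b", "c"])
        assert np.isnan(res.rho.loc["a", "b"])


class TestLoess:
    def test_exact_on_linear_data(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 10, 50))
        y = 2.0 * x + 1.0
        curve = loess_fit(x, y)
        assert np.max(np.abs(curve.fitted - (2.0 * curve.x + 1.0))) < 1e-6

    def test_robustness_iterations_downweight_outlier(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 60))
        y = x.copy()
        y[30] += 50.0
        robust = loess_fit(x, y, iters=3)
        naive = loess_fit(x, y, iters=0)
        line = robust.x
        assert np.max(np.abs(robust.fitted - line)) < np.max(np.abs(naive.fitted - line))

    def test_hump_shaped_data_has_single_interior_maximum(self):
        table, _ = sim_trait_table(TraitRegime(), 1500, seed=8)
        x = table.data["genome_size"].to_numpy()
        y = table.data["cub_f"].to_numpy()
        curve = loess_fit(np.log(x), y)
        peak = int(np.argmax(curve.fitted))
        assert 0 < peak < len(curve.x) - 1
        assert curve.fitted[peak] > curve.fitted[0] + 0.01
        assert curve.fitted[peak] > curve.fitted[-1] + 0.01
        # rises before the peak, falls after (allowing small local wiggles)
        before = np.diff(curve.fitted[: peak + 1])
        after = np.diff(curve.fitted[peak:])
        assert (before > 0).mean() > 0.8
        assert (after < 0).mean() > 0.8

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            loess_fit(np.array([1.0, np.nan] + [2.0] * 10), np.arange(12.0))


class TestStratified:
    def test_single_stratum_equals_global_matrix(self):
        rng = np.random.default_rng(9)
        table = _table(
            genome_size=rng.uniform(1e6, 3.9e6, 40),
            cub_f=rng.uniform(0, 0.5, 40),
            rrn=rng.uniform(1, 10, 40),
        )
        report = stratified_correlations(
            table, pairs=(("genome_size", "cub_f"),), strata="size"
        )
        full = spearman_matrix(table, ["genome_size", "cub_f"])
        cell = report.get("lt4Mbp", "genome_size", "cub_f")
        assert cell["rho"] == pytest.approx(full.rho.loc["genome_size", "cub_f"])
        assert cell["n"] == 40

    def test_gap_rows_belong_to_no_size_stratum(self):
        table = _table(
            genome_size=np.array([3e6, 4.5e6, 6e6] * 4, dtype=float),
            cub_f=np.tile([0.1, 0.2, 0.3], 4),
        )
        report = stratified_correlations(table, pairs=(("genome_size", "cub_f"),))
        assert report.strata_n["lt4Mbp"] == 4
        assert report.strata_n["gt5Mbp"] == 4

    def test_planted_sign_flip_recovered(self):
        table, _ = sim_trait_table(TraitRegime(), 2000, seed=10)
        report = stratified_correlations(transform_traits(table))
        small = report.get("lt4Mbp", "genome_size", "cub_f")
        large = report.get("gt5Mbp", "genome_size", "cub_f")
        assert small["rho"] > 0 and small["p_adj"] < 0.05
        assert large["rho"] < 0 and large["p_adj"] < 0.05

    def test_habitat_strata_from_free_text(self):
        rng = np.random.default_rng(11)
        n = 30
        table = _table(
            genome_size=rng.uniform(1e6, 9e6, n),
            cub_f=rng.uniform(0, 0.5, n),
            rrn=rng.uniform(1, 10, n),
        )
        table.data["habitat"] = ["agricultural soil", "marine water"] * (n // 2)
        report = stratified_correlations(
            table,
            pairs=(("genome_size", "cub_f"), ("genome_size", "rrn")),
            strata="habitat",
        )
        assert {"soil", "aquatic"} <= set(report.table["stratum"])

    def test_tiny_strata_yield_missing_cells(self):
        table = _table(genome_size=[1e6, 2e6, 6e6], cub_f=[0.1, 0.2, 0.3])
        report = stratified_correlations(table, pairs=(("genome_size", "cub_f"),))
        assert np.isnan(report.get("gt5Mbp", "genome_size", "cub_f")["rho"])
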