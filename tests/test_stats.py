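import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from rapoport import stats
from rapoport.errors import (
    CombinatorialLimitError,
    DegenerateInputError,
    LabelsMismatchError,
    RankDeficiencyError,
)
from rapoport.phylo import Phylogeny
from rapoport.synthetic import brownian_traits, simulate_tree


class TestZscore:
    def test_simple(self):
        np.testing.assert_allclose(stats.zscore([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self, rng):
        z = stats.zscore(rng.normal(5, 3, 100))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            stats.zscore([5, 5, 5])


class TestVIF:
    def test_orthogonal_predictors(self):
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1], [0, 0]], dtype=float)
        np.testing.assert_allclose(stats.vif(X), [1.0, 1.0], atol=1e-12)

    def test_duplicated_predictor_flags_infinity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        X = np.column_stack([x, x, rng.standard_normal(20)])
        out = stats.vif(X)
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_matches_independent_ols_oracle(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 2] += 0.7 * X[:, 0]  # induce correlation
        got = stats.vif(X)
        for j in range(3):
            yj = X[:, j]
            Z = np.column_stack([np.ones(40), np.delete(X, j, axis=1)])
            beta = np.linalg.pinv(Z) @ yj
            r2 = 1 - ((yj - Z @ beta) ** 2).sum() / ((yj - yj.mean()) ** 2).sum()
            assert got[j] == pytest.approx(1 / (1 - r2), abs=1e-10)


class TestOLS:
    def test_exact_line(self, rng):
        x = rng.standard_normal(30)
        f = stats.fit_ols(2 * x, x)
        assert f.coef_[0] == pytest.approx(2.0)
        assert f.r2_ == pytest.approx(1.0)

    def test_orthogonal_response(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        f = stats.fit_ols(y, x)
        assert abs(f.coef_[0]) < 1e-12

    def test_matches_pseudoinverse_oracle(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        f = stats.fit_ols(y, X)
        Z = np.column_stack([np.ones(10), X])
        beta = np.linalg.pinv(Z) @ y
        np.testing.assert_allclose(
            np.r_[f.intercept_, f.coef_], beta, atol=1e-10
        )

    def test_singular_design_names_columns(self):
        x = np.linspace(0, 1, 12)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(RankDeficiencyError) as err:
            stats.fit_ols(x, X)
        assert err.value.columns  # offending columns reported

    def test_aicc_converges_to_aic_for_large_n(self, rng):
        n = 100000
        X = rng.standard_normal((n, 4))
        y = X @ np.ones(4) + rng.standard_normal(n)
        f = stats.fit_ols(y, X)  # k = 6
        assert f.aicc_ - f.aic_ < 1e-3


class TestPGLS:
    def test_lambda_zero_equals_ols(self, rng):
        tree = simulate_tree(24, seed=3)
        X = rng.standard_normal((24, 2))
        y = rng.standard_normal(24)
        o = stats.fit_ols(y, X)
        p = stats.fit_pgls(y, X, tree, lam=0.0)
        np.testing.assert_allclose(p.coef_, o.coef_, atol=1e-10)
        np.testing.assert_allclose(p.intercept_, o.intercept_, atol=1e-10)

    def test_star_tree_ml_equals_ols(self, rng):
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(12)) + ");"
        )
        X = rng.standard_normal((12, 1))
        y = rng.standard_normal(12)
        o = stats.fit_ols(y, X)
        p = stats.PGLS(tree=star, lam="ML").fit(X, y, species=star.tip_labels)
        np.testing.assert_allclose(p.coef_, o.coef_, atol=1e-8)

    def test_labels_mismatch_reported(self):
        tree = simulate_tree(8, seed=1)
        with pytest.raises(LabelsMismatchError) as err:
            stats.PGLS(tree=tree).fit(
                np.zeros((8, 1)), np.arange(8.0),
                species=["x"] * 4 + tree.tip_labels[:4],
            )
        assert err.value.missing_in_tree

    def test_bm_simulation_recovers_high_lambda(self, tree64):
        """y = 0.5 x + BM noise on a 64-tip tree: ML lambda > 0.8 in at
        least 90% of 50 seeded replicates."""
        C, labels = tree64.brownian_covariance()
        L = np.linalg.cholesky(C + 1e-12 * np.eye(64))
        hits = 0
        rng = np.random.default_rng(77)
        for _ in range(50):
            x = rng.standard_normal(64)
            y = 0.5 * x + L @ rng.standard_normal(64)
            f = stats.PGLS(tree=tree64).fit(x[:, None], y, species=labels)
            hits += f.lambda_ > 0.8
        assert hits >= 45

    def test_lambda_always_in_unit_interval(self, tree64, rng):
        for _ in range(5):
            y = rng.standard_normal(64)
            f = stats.PGLS(tree=tree64).fit(np.empty((64, 0)), y)
            assert 0.0 <= f.lambda_ <= 1.0


class TestSignal:
    def test_constant_trait_rejected(self, tree64):
        with pytest.raises(DegenerateInputError):
            stats.blomberg_k(np.ones(64), tree64)

    def test_white_noise_lambda_low(self, tree64):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            res = stats.pagel_lambda_signal(rng.standard_normal(64), tree64)
            hits += res.lam < 0.2
        assert hits >= 45

    def test_bm_traits_lambda_high(self, tree64):
        traits, labels = brownian_traits(tree64, 50, seed=5)
        hits = sum(
            stats.pagel_lambda_signal(traits[i], tree64).lam > 0.8
            for i in range(50)
        )
        assert hits >= 45

    def test_k_permutation_detects_strong_signal(self, tree64):
        traits, _ = brownian_traits(tree64, 1, seed=9)
        res = stats.blomberg_k(traits[0], tree64, n_perm=199, seed=0)
        assert res.K > 0
        assert res.p_K < 0.05

    def test_matches_phytools_oracle(self):
        """Independent cross-check of K and lambda against phytools::phylosig."""
        tree = simulate_tree(16, seed=4)
        traits, labels = brownian_traits(tree, 1, seed=2)
        y = traits[0]
        newick = tree.to_newick()
        vals = ", ".join(repr(float(v)) for v in y)
        names = ", ".join(f'"{s}"' for s in labels)
        script = textwrap.dedent(f"""
            suppressMessages(library(phytools))
            tree <- read.tree(text='{newick}')
            x <- c({vals}); names(x) <- c({names})
            k <- phylosig(tree, x, method="K")
            l <- phylosig(tree, x, method="lambda")
            cat(sprintf("%.10f %.10f\\n", as.numeric(k), l$lambda))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        k_r, lam_r = map(float, out.stdout.split())
        res_k = stats.blomberg_k(y, tree, n_perm=49, seed=0)
        res_l = stats.pagel_lambda_signal(y, tree)
        assert res_k.K == pytest.approx(k_r, rel=1e-6)
        # phytools searches lambda slightly beyond 1; we constrain to [0, 1]
        assert res_l.lam == pytest.approx(min(lam_r, 1.0), abs=1e-3)


def lattice_coords(n_side, spacing=50.0):
    xs, ys = np.meshgrid(
        np.arange(n_side) * spacing + spacing / 2,
        np.arange(n_side) * spacing + spacing / 2,
    )
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestSpatialWeights:
    def test_threshold_50_on_50km_lattice_is_rook(self):
        w = stats.build_spatial_weights(lattice_coords(5), 50.0)
        deg = np.asarray(w.B.sum(axis=1)).ravel()
        assert deg.min() == 2 and deg.max() == 4  # no diagonal neighbours

    def test_row_standardized_rows_sum_to_one(self):
        w = stats.build_spatial_weights(lattice_coords(5), 50.0,
                                        "row_standardized")
        rows = np.asarray(w.W.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0)

    def test_globally_standardized_total_is_n(self):
        w = stats.build_spatial_weights(lattice_coords(5), 50.0,
                                        "globally_standardized")
        assert w.W.sum() == pytest.approx(25.0)

    def test_variance_stabilizing_total_is_n(self):
        w = stats.build_spatial_weights(lattice_coords(5), 50.0,
                                        "variance_stabilizing")
        assert w.W.sum() == pytest.approx(25.0)

    def test_isolated_site_flagged_with_zero_row(self):
        coords = np.vstack([lattice_coords(3), [[1e6, 1e6]]])
        w = stats.build_spatial_weights(coords, 50.0)
        assert 9 in w.isolated
        assert w.W[9].nnz == 0

    def test_no_self_neighbours(self):
        w = stats.build_spatial_weights(lattice_coords(4), 80.0)
        assert w.B.diagonal().sum() == 0


class TestSAR:
    def test_zero_weights_reduce_to_ols_exactly(self, rng):
        coords = lattice_coords(4)
        w = stats.build_spatial_weights(coords, threshold_km=1.0)  # no pairs
        X = rng.standard_normal((16, 1))
        y = rng.standard_normal(16)
        o = stats.fit_ols(y, X)
        s = stats.fit_sar_error(y, X, w)
        assert s.rho_ == 0.0
        np.testing.assert_allclose(s.coef_, o.coef_)
        np.testing.assert_allclose(s.loglik_, o.loglik_)

    def test_rho_recovery_quick(self):
        coords = lattice_coords(15)
        w = stats.build_spatial_weights(coords, 50.0, "row_standardized")
        W = w.W.toarray()
        n = coords.shape[0]
        rng = np.random.default_rng(3)
        X = rng.standard_normal((n, 1))
        u = np.linalg.solve(np.eye(n) - 0.7 * W, rng.standard_normal(n) * 0.5)
        f = stats.fit_sar_error(1.0 + 0.5 * X[:, 0] + u, X, w)
        assert 0.4 < f.rho_ < 0.95
        assert 0.0 <= f.r2_ <= 1.0

    def test_predictor_order_invariance(self, rng):
        coords = lattice_coords(8)
        w = stats.build_spatial_weights(coords, 50.0)
        X = rng.standard_normal((64, 2))
        y = X @ [0.5, -0.3] + rng.standard_normal(64)
        a = stats.fit_sar_error(y, X, w)
        b = stats.fit_sar_error(y, X[:, ::-1], w)
        assert a.loglik_ == pytest.approx(b.loglik_, abs=1e-6)
        np.testing.assert_allclose(a.coef_, b.coef_[::-1], atol=1e-6)


class TestMultimodel:
    def test_weights_sum_to_one(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        y = X["a"] * 0.5 + rng.standard_normal(30)
        ms = stats.multimodel_inference(y, X)
        assert ms.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominant_model_reproduces_its_coefficients(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        # both predictors indispensable: every submodel fits catastrophically
        y = 3.0 * X["a"].to_numpy() - 2.0 * X["b"].to_numpy() \
            + 0.05 * rng.standard_normal(200)
        ms = stats.multimodel_inference(y, X)
        top = ms.table.sort_values("weight", ascending=False).iloc[0]
        assert top["weight"] > 0.99
        assert ms.averaged["a"] == pytest.approx(top["coef_a"], abs=1e-6)
        assert ms.averaged["b"] == pytest.approx(top["coef_b"], abs=1e-6)

    def test_two_predictor_weights_match_closed_form(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 2)), columns=["a", "b"])
        y = X["a"] * 0.8 + 0.4 * rng.standard_normal(25)
        ms = stats.multimodel_inference(y, X)
        aicc = ms.table["aicc"].to_numpy()
        delta = aicc - aicc.min()
        expected = np.exp(-delta / 2) / np.exp(-delta / 2).sum()
        np.testing.assert_allclose(
            ms.table["weight"].to_numpy(), expected, atol=1e-10
        )

    def test_confidence_set_is_minimal_prefix(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
        y = X["a"] * 0.4 + X["b"] * 0.2 + rng.standard_normal(40)
        ms = stats.multimodel_inference(y, X)
        tab = ms.table.sort_values("weight", ascending=False)
        in_set = tab["in_confidence_set"].to_numpy()
        m = in_set.sum()
        assert in_set[:m].all() and not in_set[m:].any()
        cum = tab["weight"].cumsum().to_numpy()
        assert cum[m - 1] >= 0.95 - 1e-12
        assert m == 1 or cum[m - 2] < 0.95

    def test_too_many_predictors_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 13)))
        X.columns = [f"p{i}" for i in range(13)]
        with pytest.raises(CombinatorialLimitError):
            stats.multimodel_inference(rng.standard_normal(30), X)


class TestModelChoice:
    def test_lowest_aic_wins(self):
        a = type("F", (), {"aic_": 10.0, "r2_": 0.2})()
        b = type("F", (), {"aic_": 12.0, "r2_": 0.9})()
        assert stats.select_spatial_model({"a": a, "b": b}) == "a"

    def test_aic_tie_broken_by_r2(self):
        a = type("F", (), {"aic_": 10.0, "r2_": 0.2})()
        b = type("F", (), {"aic_": 10.0, "r2_": 0.9})()
        assert stats.select_spatial_model({"a": a, "b": b}) == "b"
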