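"""Association statistics: PCA leading axes, variation partitioning,
partial-RDA permutation tests, (partial) Spearman correlations and
collinearity screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spectromicrobe.errors import DataError
from spectromicrobe.association_stats import (
    collinearity_screen,
    ezekiel_adjust,
    partial_rda_test,
    partial_spearman,
    pca_leading_axes,
    rda_r2,
    spearman_matrix,
    varpart,
    varpart_with_tests,
)


class TestPCALeadingAxes:
    def test_effectively_one_dimensional_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=80)
        block = pd.DataFrame(
            {"a": t, "b": 2 * t + 1e-6 * rng.normal(size=80), "c": -t}
        )
        res = pca_leading_axes(block, 0.8)
        assert res.n_axes == 1
        assert res.explained_ratio[0] > 0.99

    def test_two_uncorrelated_variables_need_both_axes(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        res = pca_leading_axes(pd.DataFrame({"a": a, "b": b}), 0.8)
        assert res.n_axes == 2
        assert abs(res.explained_ratio[0] - 0.5) < 0.05

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(2)
        block = pd.DataFrame({"a": rng.normal(size=30), "k": np.ones(30)})
        res = pca_leading_axes(block)
        assert res.dropped_constant == ["k"]


class TestVarpart:
    def test_single_group_unique_equals_adjusted_r2(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 3)))
        Y = X.to_numpy() @ rng.normal(size=(3, 2)) + rng.normal(size=(60, 2))
        part = varpart(Y, {"only": X})
        r2, rank = rda_r2(Y, X.to_numpy())
        assert part.unique("only") == pytest.approx(ezekiel_adjust(r2, 60, rank), abs=1e-12)
        assert part.unique("only", adjusted=False) == pytest.approx(r2, abs=1e-12)

    def test_orthogonal_blocks_have_no_shared_fraction(self):
        rng = np.random.default_rng(4)
        n = 200
        A = rng.normal(size=(n, 3))
        B = rng.normal(size=(n, 2))
        A -= A.mean(axis=0)
        B -= B.mean(axis=0)
        B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]  # exact orthogonality
        Y = A @ rng.normal(size=(3, 2)) + B @ rng.normal(size=(2, 2)) + rng.normal(size=(n, 2))
        part = varpart(Y, {"a": pd.DataFrame(A), "b": pd.DataFrame(B)})
        assert abs(part.fractions[frozenset(["a", "b"])]) < 0.02
        # uniques match marginal R2 (oracle: direct regressions)
        for name, block in (("a", A), ("b", B)):
            r2, rank = rda_r2(Y, block)
            assert part.unique(name) == pytest.approx(
                ezekiel_adjust(r2, n, rank), abs=0.02
            )

    def test_inclusion_exclusion_identity_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 80
            groups = {
                g: pd.DataFrame(rng.normal(size=(n, rng.integers(1, 4))))
                for g in ("w", "x", "y")
            }
            Y = rng.normal(size=(n, 3))
            part = varpart(Y, groups)
            total = sum(part.fractions_unadjusted.values()) + part.residual_unadjusted
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(DataError):
            varpart(
                rng.normal(size=(10, 1)), {"big": pd.DataFrame(rng.normal(size=(10, 12)))}
            )


class TestPartialRDA:
    def test_planted_association_reaches_minimum_p(self):
        rng = np.random.default_rng(7)
        n = 100
        X = rng.normal(size=(n, 2))
        Y = X @ rng.normal(size=(2, 3)) * 3 + 0.1 * rng.normal(size=(n, 3))
        res = partial_rda_test(Y, X, None, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.n_permutations == 999

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(40, 2))
        X = rng.normal(size=(40, 2))
        Z = rng.normal(size=(40, 1))
        a = partial_rda_test(Y, X, Z, n_perm=99, seed=5)
        b = partial_rda_test(Y, X, Z, n_perm=99, seed=5)
        assert a.p_value == b.p_value and a.f_statistic == b.f_statistic

    def test_null_p_values_are_uniform(self):
        # response independent of the focal group given conditioners
        rng = np.random.default_rng(9)
        pvals = []
        for i in range(200):
            Z = rng.normal(size=(40, 2))
            X = Z + rng.normal(size=(40, 2))
            Y = Z @ rng.normal(size=(2, 2)) + rng.normal(size=(40, 2))
            pvals.append(partial_rda_test(Y, X, Z, n_perm=99, seed=i).p_value)
        pvals = np.array(pvals)
        assert pvals.min() >= 1 / 100
        # uniformity: rejection rates at several levels within binomial bands
        for alpha in (0.05, 0.10, 0.50):
            rate = (pvals <= alpha).mean()
            band = 3.5 * np.sqrt(alpha * (1 - alpha) / 200)
            assert abs(rate - alpha) <= band, (alpha, rate)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-4

    def test_varpart_with_tests_attaches_result_per_group(self):
        rng = np.random.default_rng(10)
        n = 60
        groups = {
            "a": pd.DataFrame(rng.normal(size=(n, 2))),
            "b": pd.DataFrame(rng.normal(size=(n, 2))),
        }
        Y = groups["a"].to_numpy() @ rng.normal(size=(2, 2)) + rng.normal(size=(n, 2))
        part = varpart_with_tests(Y, groups, n_perm=99, seed=1)
        assert set(part.tests) == {"a", "b"}
        for res in part.tests.values():
            assert 1 / 100 <= res.p_value <= 1.0


class TestSpearman:
    def test_monotone_invariance_gives_unit_rho(self):
        x = pd.DataFrame({"x": np.linspace(-2, 2, 30)})
        y = pd.DataFrame({"y": np.exp(np.linspace(-2, 2, 30))})
        out = spearman_matrix(x, y)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        out = spearman_matrix(
            pd.DataFrame({"x": [1, 2, 3]}), pd.DataFrame({"y": [3, 2, 1]})
        )
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.integers(0, 10, size=25).astype(float)  # ties likely
            y = rng.normal(size=25)
            out = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert out.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged_degenerate(self):
        out = spearman_matrix(
            pd.DataFrame({"x": [1.0, 1.0, 1.0]}), pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        )
        assert out.loc[0, "degenerate"]
        assert not out.loc[0, "significant"]

    def test_bonferroni_monotonicity(self):
        # adding tested pairs never turns a non-significant pair significant
        rng = np.random.default_rng(12)
        n = 40
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        X["x2"] = X["x1"] + 0.5 * rng.normal(size=n)
        Y = pd.DataFrame({f"y{j}": rng.normal(size=n) for j in range(4)})
        Y["y0"] = X["x1"] + 0.4 * rng.normal(size=n)
        small = spearman_matrix(X[["x1"]], Y[["y0"]])
        big = spearman_matrix(X, Y)
        sig_small = set(map(tuple, small.loc[small.significant, ["x", "y"]].to_numpy()))
        sig_big = set(map(tuple, big.loc[big.significant, ["x", "y"]].to_numpy()))
        assert sig_big & {("x1", "y0")} <= sig_small


class TestPartialSpearman:
    def test_empty_confounders_reduce_to_spearman(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        Y = pd.DataFrame({"y": rng.normal(size=30)})
        plain = spearman_matrix(X, Y)
        part = partial_spearman(X, Y, pd.DataFrame(index=X.index))
        assert part.loc[0, "rho"] == pytest.approx(plain.loc[0, "rho"], abs=1e-12)

    def test_single_confounder_matches_recursion_formula(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n = 40
            z = rng.normal(size=n)
            x = z + rng.normal(size=n)
            y = z + rng.normal(size=n)
            out = partial_spearman(
                pd.DataFrame({"x": x}), pd.DataFrame({"y": y}), pd.DataFrame({"z": z})
            )
            rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
            rxy = np.corrcoef(rx, ry)[0, 1]
            rxz = np.corrcoef(rx, rz)[0, 1]
            ryz = np.corrcoef(ry, rz)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert out.loc[0, "rho"] == pytest.approx(expected, abs=1e-10)

    def test_full_mediation_is_degenerate_or_near_zero(self):
        z = np.linspace(0, 1, 25)
        out = partial_spearman(
            pd.DataFrame({"x": z}), pd.DataFrame({"y": z}), pd.DataFrame({"z": z})
        )
        row = out.loc[0]
        assert row["degenerate"] or abs(row["rho"]) < 1e-6 or np.isnan(row["rho"])


class TestCollinearityScreen:
    def test_duplicated_column_removed_once(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept, dropped = collinearity_screen(X, cutoff=0.7)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert "c" in kept

    def test_correlated_pair_resolved_by_mean_abs_rho(self):
        rng = np.random.default_rng(16)
        n = 400
        a = rng.normal(size=n)
        b = a + 0.35 * rng.normal(size=n)          # corr(a,b) ~ 0.95
        c = 0.25 * a + rng.normal(size=n)          # a slightly more connected
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        kept, dropped = collinearity_screen(X, cutoff=0.7)
        assert dropped == ["a"]  # a has the larger mean |rho|
        assert set(kept) == {"b", "c"}

    def test_uncorrelated_data_untouched(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        kept, dropped = collinearity_screen(X, cutoff=0.7)
        assert dropped == [] and kept == list("abcd")
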