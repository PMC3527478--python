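"""CCA, partial CCA, permutation tests, forward selection, variance partition.

The eigenstructure is checked against two independent routes: a brute-force
oracle that forms the weighted projection explicitly and eigen-decomposes it
with a generic dense solver, and scikit-bio's CCA implementation.
"""

import numpy as np
import pandas as pd
import pytest

import lagbeta as lb
from lagbeta.exceptions import DegenerateDesignError, LagbetaError, SaturatedDesignError
from lagbeta.ordination import cca, forward_select, partial_cca, permutation_test, variance_partition


def oracle_constrained_eigenvalues(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Dense-solver oracle: explicit weighted projection, then eigh."""
    P = Y / Y.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    # weighted standardization of X
    Xc = X - r @ X
    Xs = Xc / np.sqrt(r @ Xc**2)
    Z = np.sqrt(r)[:, None] * Xs
    H = Z @ np.linalg.pinv(Z.T @ Z) @ Z.T  # explicit hat matrix
    fitted = H @ Qbar
    eigvals = np.linalg.eigh(fitted @ fitted.T)[0][::-1]
    return eigvals[eigvals > 1e-12]


def random_problem(rng, n=6, m=5, k=2):
    Y = pd.DataFrame(rng.random((n, m)) + 0.05)
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    return Y, X


class TestCCA:
    @pytest.mark.parametrize("seed", range(10))
    def test_eigenvalues_match_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y, X = random_problem(rng)
        result = cca(Y, X)
        expected = oracle_constrained_eigenvalues(Y.to_numpy(), X.to_numpy())
        np.testing.assert_allclose(result.eigenvalues, expected[: len(result.eigenvalues)], atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalues_match_scikit_bio(self, seed):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(100 + seed)
        Y, X = random_problem(rng)
        mine = cca(Y, X)
        Y.index = Y.index.astype(str)
        Y.columns = Y.columns.astype(str)
        X.index = X.index.astype(str)
        theirs = skbio_ordination.cca(Y, X)
        np.testing.assert_allclose(
            mine.eigenvalues, theirs.eigvals.to_numpy()[: len(mine.eigenvalues)], atol=1e-10
        )

    def test_group_indicator_with_identical_profiles_explains_everything(self):
        Y = pd.DataFrame(
            np.vstack([np.tile([0.5, 0.3, 0.2], (3, 1)), np.tile([0.1, 0.2, 0.7], (3, 1))])
        )
        X = pd.DataFrame({"group": [0, 0, 0, 1, 1, 1]})
        assert cca(Y, X).explained_fraction == pytest.approx(1.0, abs=1e-8)

    def test_identical_rows_are_degenerate(self):
        Y = pd.DataFrame(np.tile([0.2, 0.3, 0.5], (5, 1)))
        X = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.raises(DegenerateDesignError, match="total inertia"):
            cca(Y, X)

    def test_constant_predictor_rejected(self, rng):
        Y, _ = random_problem(rng)
        with pytest.raises(DegenerateDesignError, match="constant"):
            cca(Y, pd.DataFrame({"c": np.ones(6)}))

    def test_saturated_design_rejected(self, rng):
        Y, _ = random_problem(rng)
        X = pd.DataFrame(rng.normal(size=(6, 5)))
        with pytest.raises(SaturatedDesignError):
            cca(Y, X)

    def test_inertia_budget_and_ordering(self, rng):
        for _ in range(10):
            Y, X = random_problem(rng, n=8, m=6, k=3)
            res = cca(Y, X)
            assert (res.eigenvalues >= -1e-12).all()
            assert (np.diff(res.eigenvalues) <= 1e-12).all()
            assert res.constrained_inertia <= res.total_inertia + 1e-10
            assert len(res.eigenvalues) <= X.shape[1]

    def test_score_shapes(self, rng):
        Y, X = random_problem(rng, n=7, m=5, k=2)
        res = cca(Y, X)
        k = len(res.eigenvalues)
        assert res.site_scores_lc.shape == (7, k)
        assert res.band_scores.shape == (5, k)
        assert res.biplot_scores.shape == (2, k)
        assert np.abs(res.biplot_scores.to_numpy()).max() <= 1 + 1e-9


class TestPartialCCA:
    def test_empty_covariables_reduce_to_cca(self, rng):
        Y, X = random_problem(rng, n=8, m=6, k=1)
        full = cca(Y, X).explained_fraction
        assert partial_cca(Y, X)["fraction"] == pytest.approx(full, abs=1e-14)

    def test_focus_copy_of_covariable_has_zero_unique_fraction(self, rng):
        Y, X = random_problem(rng, n=8, m=6, k=1)
        copy = X.rename(columns={"x0": "dup"})
        assert partial_cca(Y, copy, X)["fraction"] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_predictors_decompose_additively(self):
        rng = np.random.default_rng(7)
        n = 8
        Y = pd.DataFrame(rng.random((n, 6)) + 0.05)
        # orthogonalize b against a in the row-mass metric of Y
        P = Y.to_numpy() / Y.to_numpy().sum()
        r = P.sum(axis=1)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a_c = a - r @ a
        b_c = b - r @ b
        coef = ((r * a_c) @ b_c) / ((r * a_c) @ a_c)
        b_orth = b_c - coef * a_c
        X = pd.DataFrame({"a": a_c, "b": b_orth})
        joint = cca(Y, X).explained_fraction
        ua = partial_cca(Y, X[["a"]], X[["b"]])["fraction"]
        ub = partial_cca(Y, X[["b"]], X[["a"]])["fraction"]
        assert ua + ub == pytest.approx(joint, abs=1e-10)

    def test_overlapping_focus_and_covariables_rejected(self, rng):
        Y, X = random_problem(rng, n=8, m=6, k=2)
        with pytest.raises(LagbetaError, match="overlap"):
            partial_cca(Y, X[["x0"]], X[["x0", "x1"]])


class TestPermutationTest:
    def test_p_floor_with_maximal_statistic(self):
        # a smooth compositional gradient perfectly tracked by x: no
        # permutation reaches F_obs, so p hits its floor 1/(1+n_perm)
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 12)
        end_a, end_b = np.array([0.7, 0.25, 0.05]), np.array([0.05, 0.25, 0.7])
        Y = pd.DataFrame(np.outer(1 - x, end_a) + np.outer(x, end_b) + rng.random((12, 3)) * 1e-4)
        X = pd.DataFrame({"grad": x})
        _, p = permutation_test(Y, X, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_under_fixed_seed(self, rng):
        Y, X = random_problem(rng, n=9, m=6, k=2)
        out1 = permutation_test(Y, X, n_perm=99, seed=42)
        out2 = permutation_test(Y, X, n_perm=99, seed=42)
        assert out1 == out2

    def test_p_invariant_under_affine_rescaling_of_predictor(self, rng):
        Y, X = random_problem(rng, n=9, m=6, k=1)
        scaled = X * 7.5 - 3.0
        f1, p1 = permutation_test(Y, X, n_perm=99, seed=3)
        f2, p2 = permutation_test(Y, scaled, n_perm=99, seed=3)
        assert f1 == pytest.approx(f2, abs=1e-10)
        assert p1 == p2

    def test_saturated_design_rejected(self, rng):
        Y, _ = random_problem(rng, n=5, m=4)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(SaturatedDesignError):
            permutation_test(Y, X, n_perm=9, seed=0)


class TestForwardSelection:
    def test_constructed_signal_selected_first(self):
        rng = np.random.default_rng(5)
        n = 18
        signal = np.repeat(np.linspace(-1, 1, 6), 3)
        base = rng.random((n, 8)) * 0.2 + 0.1
        bump = np.outer(signal + 1.1, np.linspace(1, 2, 8) % 1.0 + 0.2)
        Y = pd.DataFrame(base + bump)
        X = pd.DataFrame({"signal": signal})
        for k in range(3):
            X[f"noise{k}"] = rng.normal(size=n)
        trace = forward_select(Y, X, alpha=0.05, n_perm=199, seed=9)
        assert trace.selected[0] == "signal"

    def test_alpha_one_matches_exhaustive_greedy_oracle(self, rng):
        Y, X = random_problem(rng, n=10, m=7, k=3)
        trace = forward_select(Y, X, alpha=1.0, n_perm=9, seed=0)
        # oracle: exhaustive greedy on conditional added fraction
        remaining, selected = list(X.columns), []
        while remaining:
            gains = {
                v: partial_cca(Y, X[[v]], X[selected] if selected else None)["fraction"]
                for v in remaining
            }
            best = max(gains, key=gains.__getitem__)
            selected.append(best)
            remaining.remove(best)
        assert trace.selected == selected

    def test_added_fractions_non_increasing_at_alpha_one(self, rng):
        Y, X = random_problem(rng, n=10, m=7, k=3)
        trace = forward_select(Y, X, alpha=1.0, n_perm=9, seed=0)
        added = [s.added_fraction for s in trace.steps]
        assert all(a >= b - 1e-12 for a, b in zip(added, added[1:]))


class TestVariancePartition:
    def test_single_variable_partition(self, rng):
        Y, X = random_problem(rng, n=8, m=6, k=1)
        part = variance_partition(Y, X)
        marginal = cca(Y, X).explained_fraction
        assert part.unique_fractions["x0"] == pytest.approx(marginal, abs=1e-12)
        assert part.residual == pytest.approx(1 - marginal, abs=1e-12)

    def test_duplicated_variable_zeroes_unique_fractions(self, rng):
        Y, X = random_problem(rng, n=8, m=6, k=1)
        X2 = X.copy()
        X2["dup"] = X["x0"]
        part = variance_partition(Y, X2)
        assert part.unique_fractions["x0"] == pytest.approx(0.0, abs=1e-10)
        assert part.unique_fractions["dup"] == pytest.approx(0.0, abs=1e-10)
        assert part.total_explained == pytest.approx(cca(Y, X).explained_fraction, abs=1e-10)

    def test_unique_fractions_bounded_by_total(self, rng):
        Y, X = random_problem(rng, n=10, m=8, k=3)
        part = variance_partition(Y, X)
        for frac in part.unique_fractions.values():
            assert -1e-10 <= frac <= part.total_explained + 1e-10
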