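"""Hellinger transform, distance matrices, lag-pair construction and TLA fits."""

import math
from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import lagbeta as lb
from lagbeta.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)
from lagbeta.timelag import DAYS_PER_MONTH


def _fp(rows, prefix="s"):
    return lb.FingerprintMatrix(
        pd.DataFrame(
            rows,
            index=[f"{prefix}{i}" for i in range(len(rows))],
            columns=[f"b{j}" for j in range(len(rows[0]))],
        ),
        normalized=False,
    )


class TestHellinger:
    def test_known_transforms(self):
        out = lb.hellinger_transform(_fp([[4.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(out.data.iloc[0], [1.0, 0.0])
        row = lb.hellinger_transform(_fp([[1.0, 1.0, 1.0, 1.0]])).data.iloc[0]
        np.testing.assert_allclose(row, [0.5, 0.5, 0.5, 0.5])

    def test_rows_have_unit_norm(self, rng):
        out = lb.hellinger_transform(_fp((rng.random((5, 7)) + 0.01).tolist()))
        np.testing.assert_allclose((out.data**2).sum(axis=1), 1.0, atol=1e-12)

    def test_disjoint_profiles_reach_sqrt_two(self):
        d = lb.distance_matrix(_fp([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]).data, "hellinger")
        assert d.iloc[0, 1] == pytest.approx(math.sqrt(2))


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal_and_duplicates(self, rng):
        rows = rng.random((4, 6)) + 0.01
        rows[3] = rows[0]
        d = lb.distance_matrix(pd.DataFrame(rows), "hellinger").to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert d[0, 3] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", ["hellinger", "bray_curtis"])
    def test_matches_double_loop_oracle(self, rng, metric):
        rows = rng.random((3, 5)) + 0.01
        rel = rows / rows.sum(axis=1, keepdims=True)
        d = lb.distance_matrix(pd.DataFrame(rows), metric).to_numpy()
        for i, j in combinations(range(3), 2):
            if metric == "hellinger":
                expected = math.sqrt(((np.sqrt(rel[i]) - np.sqrt(rel[j])) ** 2).sum())
            else:
                expected = np.abs(rel[i] - rel[j]).sum() / (rel[i] + rel[j]).sum()
            assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestBuildLagPairs:
    def _pairs(self, dates, unit="months"):
        n = len(dates)
        dist = pd.DataFrame(np.zeros((n, n)))
        return lb.build_lag_pairs(dist, pd.to_datetime(dates), time_unit=unit)

    def test_pair_counts(self):
        four = ["2009-04-15", "2009-06-15", "2009-09-15", "2009-11-15"]
        assert self._pairs(four).n_pairs == 6
        eleven = [f"{d:%Y-%m-%d}" for d in lb.preset("full-scale").dates]
        assert self._pairs(eleven).n_pairs == 55

    def test_month_unit_lag(self):
        pairs = self._pairs(["2009-01-15", "2009-04-15"])
        # 90 days apart on the 30.44-day month convention
        assert pairs.sqrt_lag[0] == pytest.approx(math.sqrt(90 / DAYS_PER_MONTH))

    def test_duplicate_dates_rejected(self):
        with pytest.raises(ValidationError):
            self._pairs(["2009-04-15", "2009-04-15"])


class TestFitTLA:
    def _line_pairs(self, slope=0.5, intercept=0.2, n=8):
        x = np.sqrt(np.arange(1.0, n + 1))
        return lb.LagPairSet("g", x, intercept + slope * x)

    def test_exact_line_recovered(self):
        res = lb.fit_tla(self._line_pairs())
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.2, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_distances_give_flat_fit(self):
        res = lb.fit_tla(lb.LagPairSet("g", np.sqrt([1.0, 2, 3, 4]), np.full(4, 0.3)))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_too_few_pairs_and_degenerate_x(self):
        with pytest.raises(InsufficientDataError):
            lb.fit_tla(lb.LagPairSet("g", np.array([1.0, 2.0]), np.array([0.1, 0.2])))
        with pytest.raises(DegenerateDesignError):
            lb.fit_tla(lb.LagPairSet("g", np.ones(4), np.arange(4.0)))

    def test_distance_rescaling_rescales_slope_only(self, rng):
        x = np.sqrt(rng.uniform(1, 30, 12))
        y = 0.3 + 0.1 * x + rng.normal(0, 0.05, 12)
        t, d = np.arange(12.0), np.zeros((12, 12))  # dummy block, unused by shuffle
        base = lb.LagPairSet("g", x, y, blocks=[(t, d)])
        scaled = lb.LagPairSet("g", x, 3.5 * y, blocks=[(t, d)])
        r1 = lb.fit_tla(base, n_perm=99, seed=5, scheme="shuffle")
        r2 = lb.fit_tla(scaled, n_perm=99, seed=5, scheme="shuffle")
        assert r2.slope == pytest.approx(3.5 * r1.slope)
        assert r2.intercept == pytest.approx(3.5 * r1.intercept)
        assert r2.r_squared == pytest.approx(r1.r_squared)
        assert r2.p_parametric == pytest.approx(r1.p_parametric)
        assert r2.p_permutation == pytest.approx(r1.p_permutation)

    def test_invariant_under_time_reversal(self, rng):
        rows = rng.random((5, 8)) + 0.01
        dates = pd.to_datetime(
            ["2009-04-15", "2009-09-15", "2010-04-15", "2010-10-15", "2011-02-15"]
        )
        dist = lb.distance_matrix(pd.DataFrame(rows), "hellinger")
        fwd = lb.fit_tla(lb.build_lag_pairs(dist, dates))
        rev_dist = dist.iloc[::-1, ::-1]
        rev = lb.fit_tla(lb.build_lag_pairs(rev_dist, dates[::-1]))
        assert rev.slope == pytest.approx(fwd.slope)
        assert rev.r_squared == pytest.approx(fwd.r_squared)

    def test_shuffle_p_uniform_under_exchangeable_pairs(self, rng):
        """With i.i.d. distances the shuffle scheme's p is uniform on its support."""
        x = np.sqrt(np.arange(1.0, 16))
        ps = []
        for _ in range(400):
            pairs = lb.LagPairSet("g", x, rng.normal(5, 1, len(x)))
            res = lb.fit_tla(pairs, n_perm=99, rng=rng, scheme="shuffle")
            ps.append(res.p_permutation)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPoolingAndTables:
    def test_pooling_one_site_is_identity(self, rng):
        x = np.sqrt(rng.uniform(1, 20, 10))
        y = 0.2 + 0.05 * x + rng.normal(0, 0.02, 10)
        single = lb.LagPairSet("B", x, y)
        pooled = lb.pool_lag_pairs([single])
        assert lb.fit_tla(pooled).slope == pytest.approx(lb.fit_tla(single).slope)

    def test_two_identical_sets_double_pairs_same_slope(self, rng):
        x = np.sqrt(rng.uniform(1, 20, 10))
        y = 0.2 + 0.05 * x
        a = lb.LagPairSet("A", x, y)
        b = lb.LagPairSet("B", x.copy(), y.copy())
        pooled = lb.fit_tla(lb.pool_lag_pairs([a, b]))
        assert pooled.n_pairs == 20
        assert pooled.slope == pytest.approx(0.05, abs=1e-12)

    def test_pooled_fit_matches_concatenated_ols_oracle(self, rng):
        sets = []
        for g in "ABC":
            x = np.sqrt(rng.uniform(1, 25, 8))
            sets.append(lb.LagPairSet(g, x, 0.3 + rng.normal(0, 0.1, 8)))
        pooled = lb.fit_tla(lb.pool_lag_pairs(sets))
        x_all = np.concatenate([s.sqrt_lag for s in sets])
        y_all = np.concatenate([s.distance for s in sets])
        slope_oracle, intercept_oracle = np.polyfit(x_all, y_all, 1)
        assert pooled.slope == pytest.approx(slope_oracle, abs=1e-10)
        assert pooled.intercept == pytest.approx(intercept_oracle, abs=1e-10)

    def test_mean_slope_mode_averages_site_fits(self, desk_sim):
        _, fp, md, _ = desk_sim
        comps = lb.composite_profiles(fp, md)
        pairs = lb.site_lag_pairs(comps)
        per_site = [lb.fit_tla(p) for p in pairs.values()]
        overall = lb.tla_overall(pairs.values(), mode="mean_slope")
        assert overall.slope == pytest.approx(np.mean([r.slope for r in per_site]))

    def test_tla_table_shape_and_seed_determinism(self, desk_sim):
        scenario, fp, md, _ = desk_sim
        comps = lb.composite_profiles(fp, md)
        t1 = lb.tla_table(comps, n_perm=49, seed=11)
        t2 = lb.tla_table(comps, n_perm=49, seed=11)
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1.index[-1:]) == ["overall"]
        assert len(t1) == len(scenario.sites) + 1
        n_dates = len(scenario.dates)
        assert (t1["n_pairs"].iloc[:-1] == n_dates * (n_dates - 1) // 2).all()

    def test_distance_scale_rescales_table_slopes(self, desk_sim):
        _, fp, md, _ = desk_sim
        comps = lb.composite_profiles(fp, md)
        t1 = lb.tla_table(comps, n_perm=0)
        t100 = lb.tla_table(comps, n_perm=0, distance_scale=100.0)
        np.testing.assert_allclose(t100["slope"], 100 * t1["slope"])
        np.testing.assert_allclose(t100["r_squared"], t1["r_squared"])
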