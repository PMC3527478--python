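"""Time-lag analysis (TLA) of community change.

TLA regresses the community distance between every pair of sampling dates on
the square root of the time lag separating them.  A significantly positive
slope indicates directional compositional change; a flat slope indicates
stochastic fluctuation around a stable composition.  The square-root lag axis
down-weights the sparse long-lag pairs.

The default distance is the Hellinger distance: Euclidean distance between
rows of square-root-transformed relative abundances, bounded by sqrt(2).
Bray-Curtis is available as an alternative metric.

Because the T(T-1)/2 pairs of one series share samples, the parametric OLS
slope test is anti-conservative in principle; a permutation test is provided
alongside.  Two schemes are implemented:

* ``relabel`` (default): permute the date labels within each series and
  recompute the lags, keeping the distance matrix fixed.  This Mantel-style
  scheme respects the correlation between distances that share a composite
  and is calibrated under an exchangeable null.
* ``shuffle``: reassign the observed distance multiset to the fixed
  sqrt-lag design.  Simpler, but conservative for the same reason the
  parametric test is liberal; retained for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    LagbetaError,
    ValidationError,
)
from .io import FingerprintMatrix

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

TIME_UNITS = {"days": 1.0, "months": DAYS_PER_MONTH, "years": DAYS_PER_YEAR}
METRICS = ("hellinger", "bray_curtis")
PERMUTATION_SCHEMES = ("relabel", "shuffle")


@dataclass
class LagPairSet:
    """All unordered date pairs of one group: sqrt-lag vs community distance.

    ``blocks`` keeps, per constituent series, the date coordinates (in
    ``time_unit``) and the full distance matrix; the date-relabeling
    permutation scheme needs them.  Pooled sets carry one block per site.
    """

    group: str
    sqrt_lag: np.ndarray
    distance: np.ndarray
    time_unit: str = "months"
    blocks: list = field(default_factory=list)  # [(times, dist_matrix), ...]

    @property
    def n_pairs(self) -> int:
        return len(self.sqrt_lag)


@dataclass
class TLAResult:
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_parametric: float
    n_pairs: int
    p_permutation: float | None = None
    n_permutations: int = 0


def hellinger_transform(fp: FingerprintMatrix) -> FingerprintMatrix:
    """Square root of relative abundances; transformed rows have unit norm."""
    sums = fp.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise LagbetaError(f"all-zero rows cannot be Hellinger-transformed: {list(zero.index)}")
    return FingerprintMatrix(np.sqrt(fp.data.div(sums, axis=0)), normalized=False)


def distance_matrix(profiles: pd.DataFrame, metric: str = "hellinger") -> pd.DataFrame:
    """Symmetric labelled distance matrix among profile rows.

    ``hellinger``: Euclidean distance on square-root relative abundances.
    ``bray_curtis``: on raw relative abundances.
    """
    if metric not in METRICS:
        raise LagbetaError(f"unknown metric {metric!r}; use one of {METRICS}")
    if len(profiles) < 2:
        raise InsufficientDataError("distance matrix needs at least 2 profiles")
    values = profiles.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if (sums == 0).any():
        raise LagbetaError("all-zero profiles have no defined distance")
    rel = values / sums[:, None]
    if metric == "hellinger":
        condensed = pdist(np.sqrt(rel), metric="euclidean")
    else:
        condensed = pdist(rel, metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=profiles.index, columns=profiles.index)


def _times_in_units(dates, time_unit: str) -> np.ndarray:
    if time_unit not in TIME_UNITS:
        raise LagbetaError(f"unknown time unit {time_unit!r}; use one of {sorted(TIME_UNITS)}")
    days = pd.to_datetime(pd.Index(dates)).to_julian_date().to_numpy()
    return days / TIME_UNITS[time_unit]


def build_lag_pairs(
    dist: pd.DataFrame,
    dates,
    group: str = "overall",
    time_unit: str = "months",
) -> LagPairSet:
    """Pair every two dates of a group: x = sqrt(lag), y = their distance."""
    t = _times_in_units(dates, time_unit)
    if len(t) != len(dist):
        raise LagbetaError("dates and distance matrix must have matching length")
    if len(np.unique(t)) != len(t):
        raise ValidationError(f"duplicate sampling dates within group {group!r}")
    d = np.asarray(dist, dtype=float)
    i_idx, j_idx = np.triu_indices(len(t), k=1)
    sqrt_lag = np.sqrt(np.abs(t[j_idx] - t[i_idx]))
    distance = d[i_idx, j_idx]
    return LagPairSet(
        group=group,
        sqrt_lag=sqrt_lag,
        distance=distance,
        time_unit=time_unit,
        blocks=[(t, d)],
    )


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc @ y) / (xc @ xc))


def _permutation_p(
    pairs: LagPairSet, slope_obs: float, n_perm: int, scheme: str, rng: np.random.Generator
) -> float:
    """Two-sided p = (1 + #{|slope_perm| >= |slope_obs|}) / (1 + n_perm)."""
    x, y = pairs.sqrt_lag, pairs.distance
    target = abs(slope_obs) - 1e-12
    count = 0
    if scheme == "shuffle":
        xc = x - x.mean()
        sxx = float(xc @ xc)
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        count = int((np.abs(perms @ xc) / sxx >= target).sum())
    else:  # relabel dates within each series, lags recomputed, distances fixed
        if not pairs.blocks:
            raise LagbetaError(
                "date-relabeling permutation needs per-series blocks; "
                "build the pair set with build_lag_pairs/pool_lag_pairs"
            )
        per_block = [
            (t, d[np.triu_indices(len(t), k=1)])
            for t, d in ((t, np.asarray(d)) for t, d in pairs.blocks)
        ]
        idx_pairs = [np.triu_indices(len(t), k=1) for t, _ in per_block]
        y_all = np.concatenate([dv for _, dv in per_block])
        for _ in range(n_perm):
            xs = []
            for (t, _), (ii, jj) in zip(per_block, idx_pairs):
                tp = rng.permutation(t)
                xs.append(np.sqrt(np.abs(tp[jj] - tp[ii])))
            if abs(_slope(np.concatenate(xs), y_all)) >= target:
                count += 1
    return float((1 + count) / (1 + n_perm))


def fit_tla(
    pairs: LagPairSet,
    n_perm: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    scheme: str = "relabel",
) -> TLAResult:
    """OLS of distance on sqrt(lag), with parametric and permutation p-values."""
    x, y = pairs.sqrt_lag, pairs.distance
    if pairs.n_pairs < 3:
        raise InsufficientDataError(f"TLA needs >= 3 pairs, got {pairs.n_pairs}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("sqrt-lag values are constant; slope undefined")
    if scheme not in PERMUTATION_SCHEMES:
        raise LagbetaError(f"unknown permutation scheme {scheme!r}; use {PERMUTATION_SCHEMES}")
    if np.ptp(y) == 0:
        # constant distances: flat line, no explainable variance
        return TLAResult(
            group=pairs.group,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_parametric=1.0,
            n_pairs=pairs.n_pairs,
            p_permutation=1.0 if n_perm > 0 else None,
            n_permutations=n_perm,
        )
    fit = linregress(x, y)
    p_perm = None
    if n_perm > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        p_perm = _permutation_p(pairs, fit.slope, n_perm, scheme, rng)
    return TLAResult(
        group=pairs.group,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_parametric=float(fit.pvalue),
        n_pairs=pairs.n_pairs,
        p_permutation=p_perm,
        n_permutations=n_perm,
    )


def site_lag_pairs(
    composites: pd.DataFrame,
    metric: str = "hellinger",
    time_unit: str = "months",
    distance_scale: float = 1.0,
) -> dict[str, LagPairSet]:
    """Per-site lag pairs from (site, date)-indexed composite profiles.

    ``distance_scale`` multiplies all distances (e.g. 100 for a percentage
    axis); it rescales slopes and intercepts only.
    """
    out: dict[str, LagPairSet] = {}
    for site in composites.index.get_level_values("site").unique():
        block = composites.xs(site, level="site").sort_index()
        if len(block) < 2:
            raise InsufficientDataError(f"site {site!r} has fewer than 2 dates")
        dist = distance_matrix(block, metric=metric) * distance_scale
        out[site] = build_lag_pairs(dist, block.index, group=site, time_unit=time_unit)
    return out


def pool_lag_pairs(pair_sets, group: str = "overall") -> LagPairSet:
    """Concatenate per-site pair sets into one pooled set (blocks preserved)."""
    sets = list(pair_sets)
    if not sets:
        raise InsufficientDataError("no lag-pair sets to pool")
    units = {s.time_unit for s in sets}
    if len(units) > 1:
        raise LagbetaError(f"cannot pool pair sets with mixed time units {units}")
    return LagPairSet(
        group=group,
        sqrt_lag=np.concatenate([s.sqrt_lag for s in sets]),
        distance=np.concatenate([s.distance for s in sets]),
        time_unit=sets[0].time_unit,
        blocks=[b for s in sets for b in s.blocks],
    )


def tla_overall(
    pair_sets,
    mode: str = "pooled",
    n_perm: int = 0,
    seed: int | None = None,
    scheme: str = "relabel",
) -> TLAResult:
    """Overall TLA across sites.

    ``pooled`` (default) fits one regression over all sites' pairs, so the
    overall row carries a single R^2 over all points; ``mean_slope`` averages
    per-site fits instead (slope/intercept/R^2 are means, p-values are not
    combined).
    """
    sets = list(pair_sets)
    if mode == "pooled":
        return fit_tla(pool_lag_pairs(sets), n_perm=n_perm, seed=seed, scheme=scheme)
    if mode == "mean_slope":
        fits = [fit_tla(s) for s in sets]
        return TLAResult(
            group="overall",
            slope=float(np.mean([f.slope for f in fits])),
            intercept=float(np.mean([f.intercept for f in fits])),
            r_squared=float(np.mean([f.r_squared for f in fits])),
            p_parametric=float("nan"),
            n_pairs=sum(f.n_pairs for f in fits),
        )
    raise LagbetaError(f"unknown overall mode {mode!r}; use 'pooled' or 'mean_slope'")


def tla_table(
    composites: pd.DataFrame,
    metric: str = "hellinger",
    time_unit: str = "months",
    n_perm: int = 999,
    seed: int | None = None,
    distance_scale: float = 1.0,
    overall_mode: str = "pooled",
    scheme: str = "relabel",
) -> pd.DataFrame:
    """Per-site TLA plus the overall row, as a tidy frame."""
    pairs = site_lag_pairs(
        composites, metric=metric, time_unit=time_unit, distance_scale=distance_scale
    )
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = ss.spawn(len(pairs) + 1)
    results = [
        fit_tla(ps, n_perm=n_perm, rng=np.random.default_rng(child), scheme=scheme)
        for ps, child in zip(pairs.values(), children[:-1])
    ]
    if overall_mode == "pooled":
        overall = fit_tla(
            pool_lag_pairs(pairs.values()),
            n_perm=n_perm,
            rng=np.random.default_rng(children[-1]),
            scheme=scheme,
        )
    else:
        overall = tla_overall(pairs.values(), mode=overall_mode)
    results.append(overall)
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "r_squared": [r.r_squared for r in results],
            "p_parametric": [r.p_parametric for r in results],
            "p_permutation": [r.p_permutation for r in results],
            "n_pairs": [r.n_pairs for r in results],
        }
    ).set_index("group")
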