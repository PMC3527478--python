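"""Alpha diversity (Shannon H', band richness) and temporal beta diversity.

Temporal beta diversity of one site is the mean of all pairwise Bray-Curtis
dissimilarities among that site's time-point community profiles: 0 means the
community never changed, values near 1 mean near-complete turnover.  Replicate
lanes of one sampling date are first averaged into a composite profile
(the default policy) so that beta measures change *between* dates, not
replicate scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import entropy as _entropy

from .exceptions import InsufficientDataError, LagbetaError
from .io import FingerprintMatrix

REPLICATE_POLICIES = ("replicate_mean", "separate")


@dataclass
class DiversityRecord:
    sample_id: str
    shannon_h: float
    richness: int


@dataclass
class TemporalBetaRecord:
    site: str
    beta: float
    n_pairs: int


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H' = -sum p_i log p_i over positive entries.

    Natural log by default (H' in nats); pass ``base=2`` for bits.  The input
    is renormalized internally, so any non-negative intensity scale works.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise LagbetaError("abundances must be non-negative")
    if p.sum() == 0:
        raise LagbetaError("Shannon index undefined for an all-zero profile")
    return float(_entropy(p, base=base))


def richness(abundances, epsilon: float = 0.0) -> int:
    """Number of bands with intensity strictly above the detection epsilon."""
    p = np.asarray(abundances, dtype=float)
    return int((p > epsilon).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LagbetaError("profiles must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise LagbetaError("profiles must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise LagbetaError("Bray-Curtis undefined when both profiles are all-zero")
    return float(_braycurtis(a, b))


def composite_profiles(
    fp: FingerprintMatrix,
    metadata: pd.DataFrame,
    policy: str = "replicate_mean",
) -> pd.DataFrame:
    """One relative-abundance profile per (site, date).

    ``replicate_mean``: average the replicate relative-abundance vectors of a
    date and renormalize.  ``separate``: keep replicate lanes as individual
    rows (index gains a replicate level).
    """
    if policy not in REPLICATE_POLICIES:
        raise LagbetaError(f"unknown replicate policy {policy!r}; use {REPLICATE_POLICIES}")
    data = fp.data
    sums = data.sum(axis=1)
    if (sums == 0).any():
        raise LagbetaError("all-zero sample rows cannot form composites")
    rel = data.div(sums, axis=0)
    md = metadata.loc[rel.index]
    if policy == "separate":
        rel = rel.copy()
        rel.index = pd.MultiIndex.from_arrays(
            [md["site"], md["date"], md["replicate"]], names=["site", "date", "replicate"]
        )
        return rel.sort_index()
    grouped = rel.groupby([md["site"], md["date"]]).mean()
    grouped.index.names = ["site", "date"]
    return grouped.div(grouped.sum(axis=1), axis=0).sort_index()


def temporal_beta(
    fp: FingerprintMatrix,
    metadata: pd.DataFrame,
    site: str,
    policy: str = "replicate_mean",
) -> TemporalBetaRecord:
    """Mean pairwise Bray-Curtis among one site's time-point composites."""
    comps = composite_profiles(fp, metadata, policy=policy)
    if policy == "separate":
        comps = comps.groupby(level=["site", "date"]).mean()
        comps = comps.div(comps.sum(axis=1), axis=0)
    try:
        block = comps.xs(site, level="site")
    except KeyError:
        raise LagbetaError(f"site {site!r} not present in metadata") from None
    if len(block) < 2:
        raise InsufficientDataError(
            f"site {site!r} has {len(block)} time point(s); temporal beta needs >= 2"
        )
    values = block.to_numpy()
    dists = [bray_curtis(values[i], values[j]) for i, j in combinations(range(len(block)), 2)]
    return TemporalBetaRecord(site=site, beta=float(np.mean(dists)), n_pairs=len(dists))


def alpha_diversity_table(
    fp: FingerprintMatrix,
    epsilon: float = 0.0,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-sample Shannon H' and band richness as a tidy frame."""
    records = [
        DiversityRecord(sid, shannon(row), richness(row, epsilon=epsilon))
        for sid, row in zip(fp.sample_ids, fp.data.to_numpy())
    ]
    if base is not None:
        records = [
            DiversityRecord(r.sample_id, shannon(fp.data.loc[r.sample_id], base=base), r.richness)
            for r in records
        ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "shannon_h": [r.shannon_h for r in records],
            "richness": [r.richness for r in records],
        }
    ).set_index("sample_id")


def temporal_beta_table(
    fp: FingerprintMatrix,
    metadata: pd.DataFrame,
    policy: str = "replicate_mean",
) -> pd.DataFrame:
    """Temporal beta per site, with the site's texture class attached."""
    sites = metadata["site"].unique()
    records = [temporal_beta(fp, metadata, site, policy=policy) for site in sites]
    texture = metadata.drop_duplicates("site").set_index("site")["texture"]
    return pd.DataFrame(
        {
            "site": [r.site for r in records],
            "beta": [r.beta for r in records],
            "n_pairs": [r.n_pairs for r in records],
            "texture": [texture[r.site] for r in records],
        }
    ).set_index("site")


def texture_summary(table: pd.DataFrame, value: str) -> pd.DataFrame:
    """Mean and standard error of ``value`` per texture class (sandy/clayey)."""
    grouped = table.groupby("texture")[value]
    return pd.DataFrame(
        {
            "mean": grouped.mean(),
            "se": grouped.std(ddof=1) / np.sqrt(grouped.size()),
            "n": grouped.size(),
        }
    )
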