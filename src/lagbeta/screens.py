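"""Transform-aware Pearson correlation screens between biotic summaries and
soil variables.

The screening convention: every variable except those flagged exempt
(default: pH, already on a log-like scale) is log(x+1)-transformed before
correlating; missing cells are handled pairwise-complete.  Raw two-sided
p-values are reported to mirror the classical significance-star convention,
and a Benjamini-Hochberg q column is added because a grid of 15+ tests
without correction is a known caveat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .exceptions import LagbetaError

DEFAULT_EXEMPT = ("pH",)
MIN_PAIRS = 3


def apply_transform_policy(
    table: pd.DataFrame,
    exempt=DEFAULT_EXEMPT,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """log(x+1) on every column not listed in ``exempt``.

    Returns the transformed table and a per-column record of the transform
    applied ('log1p' or 'identity'), for provenance.
    """
    out = table.copy()
    applied: dict[str, str] = {}
    for col in out.columns:
        if col in exempt:
            applied[col] = "identity"
            continue
        x = pd.to_numeric(out[col], errors="coerce")
        if (x.dropna() <= -1).any():
            raise LagbetaError(f"log(x+1) undefined for {col!r}: values <= -1 present")
        out[col] = np.log1p(x)
        applied[col] = "log1p"
    return out, applied


def pearson_screen(
    biotic: pd.DataFrame,
    abiotic: pd.DataFrame,
    exempt=DEFAULT_EXEMPT,
    transform: bool = True,
) -> pd.DataFrame:
    """Pearson r and two-sided p over the biotic x abiotic variable grid.

    Rows must be aligned on the same observation units (the index is joined
    on intersection).  Pairs with fewer than 3 complete observations are
    reported with NaN statistics rather than raised.
    """
    common = biotic.index.intersection(abiotic.index)
    if len(common) < MIN_PAIRS:
        raise LagbetaError(
            f"only {len(common)} shared observation(s); the screen needs >= {MIN_PAIRS}"
        )
    b = biotic.loc[common]
    a = abiotic.loc[common]
    if transform:
        b, b_applied = apply_transform_policy(b, exempt=exempt)
        a, a_applied = apply_transform_policy(a, exempt=exempt)
    else:
        b_applied = {c: "identity" for c in b.columns}
        a_applied = {c: "identity" for c in a.columns}

    rows = []
    for bv in b.columns:
        for av in a.columns:
            pair = pd.concat([b[bv], a[av]], axis=1).dropna()
            n = len(pair)
            if n < MIN_PAIRS or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {
                    "biotic": bv,
                    "abiotic": av,
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "p": float(p) if np.isfinite(p) else np.nan,
                    "n": n,
                    "transform_biotic": b_applied[bv],
                    "transform_abiotic": a_applied[av],
                }
            )
    result = pd.DataFrame(rows)
    # BH q-values over the tests that produced a p (non-standard addition,
    # clearly labelled; the raw p column mirrors the classical convention)
    mask = result["p"].notna()
    result["q_bh"] = np.nan
    if mask.any():
        result.loc[mask, "q_bh"] = multipletests(result.loc[mask, "p"], method="fdr_bh")[1]
    return result
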