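"""Canonical correspondence analysis (CCA), partial CCA, Monte Carlo
permutation tests, forward selection and variance partitioning.

The implementation follows the weighted-averaging / chi-square formulation:
the species table is converted to the correspondence-analysis residual matrix

    qbar_ij = (p_ij - r_i c_j) / sqrt(r_i c_j)

(p = table rescaled to sum 1, r/c = row and column masses), whose total sum
of squares is the total inertia.  Environmental variables are standardized to
weighted mean 0 / variance 1 and projected in the row-mass metric; the
singular values of the projected residual matrix give the constrained
eigenvalues.  Partial analyses first remove the covariables' weighted fit
from both the residual matrix and the focus predictors, so each variable's
*unique* (conditional) contribution can be isolated — the basis of variance
partitioning.

Significance uses the pseudo-F statistic with reduced-model permutations:
rows of the covariable-residualized predictors are permuted, re-residualized
and re-projected; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, LagbetaError, SaturatedDesignError
from .io import FingerprintMatrix

_RANK_TOL = 1e-10


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores_lc: pd.DataFrame
    site_scores_wa: pd.DataFrame
    band_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    pseudo_f: float | None = None
    p_permutation: float | None = None

    @property
    def explained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


@dataclass
class VariancePartition:
    total_explained: float
    unique_fractions: dict[str, float]
    residual: float


@dataclass
class ForwardSelectionStep:
    variable: str
    added_fraction: float
    p_value: float
    retained: bool


@dataclass
class ForwardSelectionTrace:
    selected: list[str]
    steps: list[ForwardSelectionStep] = field(default_factory=list)
    stopping_reason: str = ""


def _as_frame(Y) -> pd.DataFrame:
    if isinstance(Y, FingerprintMatrix):
        return Y.data
    return pd.DataFrame(Y)


def _chi_square_standardize(Y: pd.DataFrame):
    """Correspondence-analysis residual matrix plus row/column masses.

    All-zero band columns are dropped (they carry no inertia); all-zero
    sample rows are rejected.
    """
    A = Y.to_numpy(dtype=float)
    if (A < 0).any():
        raise LagbetaError("species table must be non-negative")
    row_sums = A.sum(axis=1)
    if (row_sums == 0).any():
        bad = list(Y.index[row_sums == 0])
        raise LagbetaError(f"all-zero sample rows have undefined chi-square profile: {bad}")
    keep = A.sum(axis=0) > 0
    A = A[:, keep]
    total = A.sum()
    P = A / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    return Qbar, r, c, list(Y.columns[keep])


def _standardize_weighted(X: pd.DataFrame, r: np.ndarray) -> np.ndarray:
    """Weighted (row-mass) standardization to mean 0, variance 1."""
    V = X.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise LagbetaError("environmental variables contain missing values")
    mean = r @ V
    centered = V - mean
    var = r @ centered**2
    const = var <= _RANK_TOL * max(1.0, float(np.abs(V).max()) ** 2)
    if const.any():
        bad = list(X.columns[const])
        raise DegenerateDesignError(f"constant environmental variable(s): {bad}")
    return centered / np.sqrt(var)


def _weighted_basis(X_std: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Orthonormal basis (via SVD) of the weighted predictor columns."""
    Z = np.sqrt(r)[:, None] * X_std
    if Z.shape[1] == 0:
        return np.zeros((Z.shape[0], 0))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)).sum())
    return U[:, :rank]


def _check_X(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if len(X) != len(Y):
        raise LagbetaError("species table and environmental table differ in sample count")
    return X


def cca(Y, X) -> CCAResult:
    """Canonical correspondence analysis of species table Y on predictors X.

    Returns the constrained eigenvalues, inertia budget and type-2-scaled
    scores (band scores multiplied by the axis singular values, linear-
    combination and weighted-average site scores, and biplot arrow
    coordinates from weighted correlations of predictors with the LC axes).
    """
    Yf = _as_frame(Y)
    X = _check_X(X, Yf)
    Qbar, r, c, bands = _chi_square_standardize(Yf)
    n = len(r)
    total_inertia = float((Qbar**2).sum())
    if total_inertia <= _RANK_TOL:
        raise DegenerateDesignError("total inertia is zero: all community profiles identical")
    if n < 3:
        raise LagbetaError("CCA needs at least 3 samples")
    X_std = _standardize_weighted(X, r)
    U_basis = _weighted_basis(X_std, r)
    q = U_basis.shape[1]
    if q >= n - 1:
        raise SaturatedDesignError(
            f"predictor rank {q} saturates the design for {n} samples"
        )
    fitted = U_basis @ (U_basis.T @ Qbar)
    Uf, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(q, Qbar.shape[1])
    s = s[:n_axes]
    eig = s**2
    keep_axes = eig > _RANK_TOL * max(1.0, eig[0] if len(eig) else 1.0)
    eig = eig[keep_axes]
    s = s[keep_axes]
    Uf = Uf[:, : len(s)]
    V = Vt[: len(s)].T
    axes = [f"CCA{i + 1}" for i in range(len(s))]

    with np.errstate(divide="ignore", invalid="ignore"):
        # scaling 2: band scores carry the eigenvalue structure
        band_scores = (V / np.sqrt(c)[:, None]) * s
        lc = Uf / np.sqrt(r)[:, None]
        wa = (Qbar @ V) / np.sqrt(r)[:, None] / np.where(s > 0, s, 1.0)
    # biplot arrows: weighted correlation of each predictor with each LC axis
    Zlc = np.sqrt(r)[:, None] * lc
    Zx = np.sqrt(r)[:, None] * X_std
    norm_lc = np.linalg.norm(Zlc, axis=0)
    norm_x = np.linalg.norm(Zx, axis=0)
    biplot = (Zx.T @ Zlc) / np.outer(norm_x, norm_lc)

    return CCAResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        site_scores_lc=pd.DataFrame(lc, index=Yf.index, columns=axes),
        site_scores_wa=pd.DataFrame(wa, index=Yf.index, columns=axes),
        band_scores=pd.DataFrame(band_scores, index=bands, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=X.columns, columns=axes),
    )


def _conditional_inertia(Qbar, r, X_focus_std, U_cov):
    """Constrained inertia of the focus predictors after removing covariables."""
    Q_res = Qbar - U_cov @ (U_cov.T @ Qbar)
    Zf = np.sqrt(r)[:, None] * X_focus_std
    Zf_res = Zf - U_cov @ (U_cov.T @ Zf)
    U, s, _ = np.linalg.svd(Zf_res, full_matrices=False) if Zf_res.shape[1] else (
        np.zeros((len(r), 0)),
        np.zeros(0),
        None,
    )
    rank = int((s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)).sum())
    U = U[:, :rank]
    proj = U.T @ Q_res
    return float((proj**2).sum()), rank, Q_res, Zf_res


def partial_cca(Y, X_focus, X_covariables=None) -> dict:
    """Unique explained fraction of X_focus, conditioning on covariables.

    With no covariables this reduces exactly to :func:`cca`.  The fraction is
    reported relative to the *original* total inertia, so unique fractions
    from different focus sets are directly comparable.
    """
    Yf = _as_frame(Y)
    X_focus = _check_X(X_focus, Yf)
    Qbar, r, _, _ = _chi_square_standardize(Yf)
    total_inertia = float((Qbar**2).sum())
    if total_inertia <= _RANK_TOL:
        raise DegenerateDesignError("total inertia is zero: all community profiles identical")
    Xf_std = _standardize_weighted(X_focus, r)
    if X_covariables is not None and pd.DataFrame(X_covariables).shape[1] > 0:
        X_cov = _check_X(X_covariables, Yf)
        overlap = set(X_focus.columns) & set(X_cov.columns)
        if overlap:
            raise LagbetaError(f"focus and covariables overlap: {sorted(overlap)}")
        Xc_std = _standardize_weighted(X_cov, r)
        U_cov = _weighted_basis(Xc_std, r)
    else:
        U_cov = np.zeros((len(r), 0))
    inertia, rank, _, _ = _conditional_inertia(Qbar, r, Xf_std, U_cov)
    n = len(r)
    if rank + U_cov.shape[1] >= n - 1:
        raise SaturatedDesignError("focus plus covariables saturate the design")
    return {
        "conditional_inertia": inertia,
        "total_inertia": total_inertia,
        "fraction": inertia / total_inertia,
        "rank_focus": rank,
        "rank_covariables": int(U_cov.shape[1]),
    }


def permutation_test(
    Y,
    X_focus,
    X_covariables=None,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pseudo-F and permutation p for the (partial) constrained inertia.

    F = (constrained/q) / (residual/(n-q-c-1)), residual = total minus the
    covariables' and the focus term's inertia.  Reduced-model scheme: the
    covariable-residualized focus predictors are row-permuted (in sample
    space), re-weighted, re-residualized and re-projected each round.
    """
    if n_perm < 1:
        raise LagbetaError("n_perm must be >= 1")
    Yf = _as_frame(Y)
    X_focus = _check_X(X_focus, Yf)
    Qbar, r, _, _ = _chi_square_standardize(Yf)
    total_inertia = float((Qbar**2).sum())
    if total_inertia <= _RANK_TOL:
        raise DegenerateDesignError("total inertia is zero: all community profiles identical")
    Xf_std = _standardize_weighted(X_focus, r)
    if X_covariables is not None and pd.DataFrame(X_covariables).shape[1] > 0:
        Xc_std = _standardize_weighted(_check_X(X_covariables, Yf), r)
        U_cov = _weighted_basis(Xc_std, r)
    else:
        U_cov = np.zeros((len(r), 0))
    cov_inertia = float(((U_cov.T @ Qbar) ** 2).sum())
    focus_inertia, q, Q_res, Zf_res = _conditional_inertia(Qbar, r, Xf_std, U_cov)
    c = U_cov.shape[1]
    n = len(r)
    df_resid = n - q - c - 1
    if df_resid <= 0:
        raise SaturatedDesignError(f"no residual degrees of freedom (n={n}, q={q}, c={c})")
    resid_inertia = total_inertia - cov_inertia - focus_inertia

    def resid(constrained: float) -> float:
        return max(total_inertia - cov_inertia - constrained, _RANK_TOL)

    f_obs = (focus_inertia / q) / (max(resid_inertia, _RANK_TOL) / df_resid)

    if rng is None:
        rng = np.random.default_rng(seed)
    sqrt_r = np.sqrt(r)[:, None]
    # back to sample space so row weights stay attached to samples, not rows
    Xres_sample = Zf_res / sqrt_r
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Zp = sqrt_r * Xres_sample[perm]
        if c:
            Zp = Zp - U_cov @ (U_cov.T @ Zp)
        Up, sp, _ = np.linalg.svd(Zp, full_matrices=False)
        rank_p = int((sp > _RANK_TOL * max(1.0, sp[0] if len(sp) else 1.0)).sum())
        inertia_p = float(((Up[:, :rank_p].T @ Q_res) ** 2).sum())
        f_p = (inertia_p / q) / (resid(inertia_p) / df_resid)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def forward_select(
    Y,
    X_all,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelectionTrace:
    """Greedy forward selection of environmental variables.

    Each step adds the candidate with the largest additional explained
    inertia conditional on the already-selected set, retained only if its
    conditional permutation p <= alpha.
    """
    Yf = _as_frame(Y)
    X_all = _check_X(X_all, Yf)
    if X_all.shape[1] < 1:
        raise LagbetaError("forward selection needs at least one candidate variable")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rng = np.random.default_rng(ss)
    selected: list[str] = []
    steps: list[ForwardSelectionStep] = []
    remaining = list(X_all.columns)
    reason = "candidates exhausted"
    while remaining:
        gains = {}
        for var in remaining:
            cov = X_all[selected] if selected else None
            try:
                gains[var] = partial_cca(Yf, X_all[[var]], cov)["fraction"]
            except (DegenerateDesignError, SaturatedDesignError):
                gains[var] = -np.inf
        best = max(gains, key=gains.__getitem__)
        if not np.isfinite(gains[best]):
            reason = "remaining candidates degenerate"
            break
        cov = X_all[selected] if selected else None
        if alpha >= 1.0:
            p_value = 1.0
        else:
            _, p_value = permutation_test(
                Yf, X_all[[best]], cov, n_perm=n_perm, rng=rng
            )
        retained = p_value <= alpha or alpha >= 1.0
        steps.append(ForwardSelectionStep(best, float(gains[best]), float(p_value), retained))
        if not retained:
            reason = f"best candidate {best!r} not significant (p={p_value:.4g} > {alpha})"
            break
        selected.append(best)
        remaining.remove(best)
    return ForwardSelectionTrace(selected=selected, steps=steps, stopping_reason=reason)


def variance_partition(Y, X_all) -> VariancePartition:
    """Unique explained fraction per variable, all others as covariables.

    ``total_explained`` is the joint constrained fraction of all variables;
    ``residual`` is its complement.  Perfectly collinear duplicates get a
    unique fraction of 0 without changing the total.
    """
    Yf = _as_frame(Y)
    X_all = _check_X(X_all, Yf)
    total = cca(Yf, X_all).explained_fraction
    unique = {}
    for var in X_all.columns:
        others = [v for v in X_all.columns if v != var]
        cov = X_all[others] if others else None
        unique[var] = float(partial_cca(Yf, X_all[[var]], cov)["fraction"])
    return VariancePartition(
        total_explained=float(total),
        unique_fractions=unique,
        residual=float(1.0 - total),
    )
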