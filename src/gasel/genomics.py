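"""Marker QC, imputation, genomic relationships and REML mixed models.

The module exposes the two interchangeable parameterizations of whole-genome
regression: ridge regression on marker effects (:func:`fit_rrblup`) and the
line-level kinship model (:func:`fit_gblup`).  Both are fitted by restricted
maximum likelihood using a single eigendecomposition of the relationship
matrix followed by a one-dimensional optimization of the variance ratio,
so that with a kinship built from the identical centered marker matrix the
two routes produce the same line-level predictions (up to solver tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .exceptions import (
    AlignmentError,
    ConvergenceWarning,
    DomainError,
    EmptyPanelError,
)

__all__ = [
    "MarkerMatrix",
    "GenomicRelationship",
    "MixedModelFit",
    "QCReport",
    "qc_filter_markers",
    "impute_missing",
    "genomic_relationship",
    "fit_rrblup",
    "fit_gblup",
    "h2_from_lambda",
    "lambda_from_h2",
    "predict_gebv",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Lines x markers genotype codes in {-1, 0, +1}, NaN for missing.

    After imputation entries may be fractional but must stay in [-1, +1].
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        n, m = self.codes.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lengths do not match codes shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("line ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("genotype codes outside [-1, +1]")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def dosages(self) -> np.ndarray:
        """Recode {-1,0,+1} to {0,1,2} allele dosages (NaN preserved)."""
        return self.codes + 1.0

    def _line_index(self) -> dict:
        return {lid: i for i, lid in enumerate(self.line_ids)}

    def select_lines(self, line_ids: Sequence) -> "MarkerMatrix":
        idx = self._line_index()
        missing = [l for l in line_ids if l not in idx]
        if missing:
            raise AlignmentError(f"lines not in marker matrix: {missing[:10]}")
        rows = [idx[l] for l in line_ids]
        return MarkerMatrix(
            np.asarray(list(line_ids), dtype=object),
            self.marker_ids.copy(),
            self.codes[rows, :].copy(),
        )

    def select_markers(self, marker_ids: Sequence) -> "MarkerMatrix":
        midx = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in marker_ids if m not in midx]
        if missing:
            raise AlignmentError(f"markers not in panel: {missing[:10]}")
        cols = [midx[m] for m in marker_ids]
        if not cols:
            raise EmptyPanelError("marker selection removed every marker")
        return MarkerMatrix(
            self.line_ids.copy(),
            np.asarray(list(marker_ids), dtype=object),
            self.codes[:, cols].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))


@dataclass
class GenomicRelationship:
    """N x N realized kinship with the allele frequencies used to build it."""

    line_ids: np.ndarray
    K: np.ndarray
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.line_ids),) * 2:
            raise ValueError("K shape does not match line ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K is not symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])

    def _line_index(self) -> dict:
        return {lid: i for i, lid in enumerate(self.line_ids)}

    def subset(self, line_ids: Sequence) -> "GenomicRelationship":
        idx = self._line_index()
        missing = [l for l in line_ids if l not in idx]
        if missing:
            raise AlignmentError(f"lines not in kinship: {missing[:10]}")
        rows = np.array([idx[l] for l in line_ids])
        return GenomicRelationship(
            np.asarray(list(line_ids), dtype=object),
            self.K[np.ix_(rows, rows)].copy(),
            self.allele_freqs.copy(),
        )

    @classmethod
    def identity(cls, line_ids: Sequence) -> "GenomicRelationship":
        n = len(line_ids)
        return cls(np.asarray(list(line_ids), dtype=object), np.eye(n), np.array([]))


@dataclass
class MixedModelFit:
    """REML solution of a single-random-effect mixed model.

    ``random_effects`` holds marker effects (``kind='rrblup'``) or line
    genetic values (``kind='gblup'``).  ``lambda2`` is the shrinkage ratio
    sigma2_e / sigma2_g and ``h2 = 1 / (1 + lambda2)`` exactly.
    """

    sigma2_g: float
    sigma2_e: float
    fixed_effects: pd.Series
    random_effects: pd.Series
    log_likelihood: float
    kind: str
    boundary: bool = False
    pev: np.ndarray | None = field(default=None, repr=False)
    marker_ids: np.ndarray | None = field(default=None, repr=False)
    column_centers: np.ndarray | None = field(default=None, repr=False)

    @property
    def lambda2(self) -> float:
        if self.sigma2_g <= 0.0:
            return float("inf")
        return self.sigma2_e / self.sigma2_g

    @property
    def h2(self) -> float:
        return h2_from_lambda(self.lambda2)

    @property
    def intercept(self) -> float:
        return float(self.fixed_effects.iloc[0])


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def h2_from_lambda(lambda2: float) -> float:
    """Heritability from the shrinkage ratio: h2 = 1 / (1 + lambda2)."""
    if np.isinf(lambda2):
        return 0.0
    if lambda2 < 0:
        raise DomainError("lambda2 must be >= 0")
    return 1.0 / (1.0 + lambda2)


def lambda_from_h2(h2: float) -> float:
    """Shrinkage ratio from heritability: lambda2 = 1/h2 - 1."""
    if not 0.0 < h2 < 1.0:
        raise DomainError("h2 must be in the open interval (0, 1)")
    return 1.0 / h2 - 1.0


# ---------------------------------------------------------------------------
# marker QC and imputation
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    n_input: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_missing: int
    n_retained: int


def qc_filter_markers(
    markers: MarkerMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
) -> tuple[MarkerMatrix, QCReport]:
    """Drop markers failing call-rate, minor-allele-frequency or missingness.

    A marker is removed when its call rate is below ``call_rate_min``, its
    minor allele frequency is below ``maf_min`` (strict), or its fraction
    of missing entries exceeds ``missing_max``.  Lines are never removed.
    """
    if markers.n_markers == 0:
        raise EmptyPanelError("marker panel is empty")
    codes = markers.codes
    n = markers.n_lines
    n_obs = np.sum(np.isfinite(codes), axis=0)
    call_rate = n_obs / n
    miss_frac = 1.0 - call_rate
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes + 1.0, axis=0) / 2.0
    maf = np.fmin(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    fail_cr = call_rate < call_rate_min
    fail_maf = maf < maf_min
    fail_miss = miss_frac > missing_max
    keep = ~(fail_cr | fail_maf | fail_miss)
    report = QCReport(
        n_input=markers.n_markers,
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
    )
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")
    out = MarkerMatrix(
        markers.line_ids.copy(), markers.marker_ids[keep].copy(), codes[:, keep].copy()
    )
    return out, report


def impute_missing(
    markers: MarkerMatrix,
    method: str = "mean",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> MarkerMatrix:
    """Fill missing genotype codes.

    ``mean`` replaces each missing entry by its marker's observed mean.
    ``em`` iterates the multivariate-normal conditional expectation of the
    missing entries given the observed ones (markers as variables, lines as
    samples) until the imputed values stabilize; on non-convergence it falls
    back to marker means with a warning.  Imputed values are clipped to
    [-1, +1]; fully observed input is returned unchanged.
    """
    if method not in {"mean", "em"}:
        raise ValueError(f"unknown imputation method: {method!r}")
    codes = markers.codes.copy()
    mask = np.isnan(codes)
    if not mask.any():
        return MarkerMatrix(markers.line_ids.copy(), markers.marker_ids.copy(), codes)

    col_mean = np.nanmean(codes, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    mean_filled = np.where(mask, col_mean[np.newaxis, :], codes)
    if method == "mean":
        return MarkerMatrix(markers.line_ids.copy(), markers.marker_ids.copy(), mean_filled)

    X = mean_filled.copy()
    n, m = X.shape
    rows_with_missing = np.where(mask.any(axis=1))[0]
    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        S = (Xc.T @ Xc) / max(n - 1, 1)
        S[np.diag_indices_from(S)] += 1e-10 * (np.trace(S) / m + 1.0)
        delta = 0.0
        for i in rows_with_missing:
            mi = mask[i]
            oi = ~mi
            if not oi.any():
                continue  # nothing observed: stays at marker mean
            rhs = X[i, oi] - mu[oi]
            sol = np.linalg.solve(S[np.ix_(oi, oi)], rhs)
            new = mu[mi] + S[np.ix_(mi, oi)] @ sol
            delta = max(delta, float(np.max(np.abs(new - X[i, mi]))))
            X[i, mi] = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "MVN-EM imputation did not converge; falling back to marker means",
            ConvergenceWarning,
        )
        X = mean_filled
    np.clip(X, -1.0, 1.0, out=X)
    return MarkerMatrix(markers.line_ids.copy(), markers.marker_ids.copy(), X)


# ---------------------------------------------------------------------------
# genomic relationship
# ---------------------------------------------------------------------------


def _center_and_normalizer(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center dosages by twice the allele frequency; return (W, p, normalizer)."""
    dos = codes + 1.0
    p = dos.mean(axis=0) / 2.0
    W = dos - 2.0 * p
    norm = 2.0 * float(np.sum(p * (1.0 - p)))
    return W, p, norm


def genomic_relationship(markers: MarkerMatrix) -> GenomicRelationship:
    """Realized kinship K = W W' / (2 * sum p_k (1 - p_k)).

    Markers must be complete (imputed); W centers the {0,1,2} dosage
    recoding of the codes by twice the observed allele frequency.
    """
    if markers.has_missing:
        raise ValueError("markers contain missing values; impute first")
    if markers.n_lines < 2:
        raise ValueError("need at least two lines")
    W, p, norm = _center_and_normalizer(markers.codes)
    if norm <= 0.0:
        raise EmptyPanelError("all markers monomorphic: zero normalizer")
    K = (W @ W.T) / norm
    K = (K + K.T) / 2.0
    return GenomicRelationship(markers.line_ids.copy(), K, p)


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

_LOG_DELTA_BOUNDS = (-20.0, 20.0)


def _reml_spectral(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float, bool]:
    """Profiled REML for V = sigma2_g * K + sigma2_e * diag(1/w).

    Rotates out the fixed effects with the orthogonal complement of X,
    eigendecomposes the rotated kinship once and optimizes the restricted
    likelihood over log(delta), delta = sigma2_e / sigma2_g.
    Returns (sigma2_g, sigma2_e, restricted log-likelihood, boundary flag).
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    if weights is not None:
        s = np.sqrt(weights)
        y = y * s
        X = X * s[:, None]
        K = K * np.outer(s, s)
    Q, _ = np.linalg.qr(X, mode="complete")
    Q2 = Q[:, p:]
    A = Q2.T @ K @ Q2
    theta, U = np.linalg.eigh((A + A.T) / 2.0)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ (Q2.T @ y)
    s2 = eta**2
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    total = float(s2.sum())
    if total < 1e-300:
        # constant response: no variance at all
        return 0.0, 1e-12, 0.0, True

    def negll(t: float) -> float:
        delta = np.exp(t)
        d = theta + delta
        s2g = float(np.sum(s2 / d)) / df
        return 0.5 * (df * np.log(s2g) + float(np.sum(np.log(d))))

    res = minimize_scalar(
        negll,
        bounds=_LOG_DELTA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12},
    )
    t_opt = float(res.x)
    boundary = (
        t_opt <= _LOG_DELTA_BOUNDS[0] + 1e-3 or t_opt >= _LOG_DELTA_BOUNDS[1] - 1e-3
    )
    delta = np.exp(t_opt)
    d = theta + delta
    sigma2_g = float(np.sum(s2 / d)) / df
    sigma2_e = delta * sigma2_g
    loglik = -float(res.fun) - 0.5 * df * (1.0 + np.log(2.0 * np.pi))
    return sigma2_g, sigma2_e, loglik, boundary


def _reml_fixed_resid(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    se2: np.ndarray,
) -> tuple[float, float, bool]:
    """REML over sigma2_g alone with known residual variances se2.

    Used for stage-two models where the first stage supplies the error
    variance of every entry (sigma2_e is fixed at 1 on the weighted scale).
    Whitening by 1/se reduces V to sigma2_g * K~ + I, handled with one
    eigendecomposition as in :func:`_reml_spectral`.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    s = 1.0 / np.sqrt(se2)
    yw = y * s
    Xw = X * s[:, None]
    Kw = K * np.outer(s, s)
    Q, _ = np.linalg.qr(Xw, mode="complete")
    Q2 = Q[:, p:]
    A = Q2.T @ Kw @ Q2
    theta, U = np.linalg.eigh((A + A.T) / 2.0)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ (Q2.T @ yw)
    s2 = eta**2

    def negll(t: float) -> float:
        v = np.exp(t) * theta + 1.0
        return 0.5 * (float(np.sum(np.log(v))) + float(np.sum(s2 / v)))

    res = minimize_scalar(
        negll, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-12},
    )
    t_opt = float(res.x)
    boundary = (
        t_opt <= _LOG_DELTA_BOUNDS[0] + 1e-3 or t_opt >= _LOG_DELTA_BOUNDS[1] - 1e-3
    )
    s2g = float(np.exp(t_opt))
    if boundary and t_opt <= _LOG_DELTA_BOUNDS[0] + 1e-3:
        s2g = 0.0
    loglik = -float(res.fun) - 0.5 * (n - p) * np.log(2.0 * np.pi)
    return s2g, loglik, boundary


def _gls_solve(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
    weights: np.ndarray | None,
    compute_pev: bool = False,
):
    """Generalized least squares and BLUP pieces at fixed variance components."""
    n = len(y)
    rdiag = sigma2_e / weights if weights is not None else np.full(n, sigma2_e)
    rdiag = np.maximum(rdiag, 1e-12)
    V = sigma2_g * K + np.diag(rdiag)
    cf = cho_factor(V, lower=True)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    Xty = ViX.T @ y
    beta = np.linalg.solve(XtViX, Xty)
    resid = y - X @ beta
    Vir = cho_solve(cf, resid)
    pev = None
    if compute_pev:
        # Var(g_tilde - g) = s2g*K - s2g^2 * K P K with
        # P = Vi - Vi X (X' Vi X)^-1 X' Vi
        Vi_K = cho_solve(cf, K)
        KPK = K @ Vi_K - (K @ ViX) @ np.linalg.solve(XtViX, ViX.T @ K)
        pev = sigma2_g * K - sigma2_g**2 * KPK
        pev = (pev + pev.T) / 2.0
    return beta, Vir, XtViX, pev


def _as_series(y, name: str = "y") -> pd.Series:
    if not isinstance(y, pd.Series):
        raise TypeError(f"{name} must be a pandas Series indexed by line id")
    if y.index.has_duplicates:
        raise ValueError(f"{name} has duplicate line ids")
    return y.astype(float)


def _design_matrix(
    index: pd.Index, fixed_design: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    cols = ["(intercept)"]
    X = [np.ones(len(index))]
    if fixed_design is not None:
        fd = fixed_design.loc[index]
        for c in fd.columns:
            cols.append(str(c))
            X.append(fd[c].to_numpy(float))
    return np.column_stack(X), cols


def fit_gblup(
    y: pd.Series,
    K: GenomicRelationship,
    fixed_design: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    compute_pev: bool = False,
    fixed_residual: bool = False,
) -> MixedModelFit:
    """REML fit of y = Xb + g + e with g ~ N(0, K sigma2_g).

    ``y`` is indexed by line id and may cover a subset of the lines in
    ``K``; BLUPs are returned for *all* lines of ``K`` (prediction of
    unphenotyped lines through the relationship).  ``weights`` scale the
    residual variance per observation as sigma2_e / w.

    With ``fixed_residual`` the residual variances are taken as known from
    the weights (sigma2_e fixed at 1, Var(e_i) = 1/w_i) and only sigma2_g
    is estimated — required when K = I and lines are unreplicated, where
    the two components are otherwise confounded.
    """
    y = _as_series(y)
    kidx = K._line_index()
    missing = [l for l in y.index if l not in kidx]
    if missing:
        raise AlignmentError(f"phenotyped lines missing from K: {missing[:10]}")
    obs = np.array([kidx[l] for l in y.index])
    K_obs = K.K[np.ix_(obs, obs)]
    X, xcols = _design_matrix(y.index, fixed_design)
    w = None
    if weights is not None:
        w = weights.loc[y.index].to_numpy(float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    yv = y.to_numpy(float)

    if np.ptp(yv) < 1e-14:
        # constant response: zero genetic variance by convention
        fe = pd.Series(np.r_[yv.mean(), np.zeros(X.shape[1] - 1)], index=xcols)
        re = pd.Series(np.zeros(len(K.line_ids)), index=K.line_ids)
        return MixedModelFit(0.0, max(float(np.var(yv)), 1e-12), fe, re, 0.0,
                             kind="gblup", boundary=True)

    if fixed_residual:
        if w is None:
            raise ValueError("fixed_residual requires weights (1/se^2)")
        s2g, ll, boundary = _reml_fixed_resid(yv, X, K_obs, 1.0 / w)
        s2e = 1.0
    else:
        s2g, s2e, ll, boundary = _reml_spectral(yv, X, K_obs, w)
    if s2g <= 0.0:
        s2g = 0.0
    beta, Vir, XtViX, pev = _gls_solve(yv, X, K_obs, max(s2g, 1e-12), s2e, w,
                                       compute_pev=compute_pev)
    g_all = s2g * (K.K[:, obs] @ Vir)
    fe = pd.Series(beta, index=xcols)
    re = pd.Series(g_all, index=K.line_ids)
    return MixedModelFit(s2g, s2e, fe, re, ll, kind="gblup", boundary=boundary,
                         pev=pev)


def fit_rrblup(
    y: pd.Series,
    markers: MarkerMatrix,
    fixed_design: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    center: bool = True,
) -> MixedModelFit:
    """REML ridge regression of all marker effects, u ~ N(0, I sigma2_u).

    Solved through the line-level kinship equivalent (one eigendecomposition
    of W W' / c), then marker effects recovered as u = (s2g/c) W' Vi r.
    ``sigma2_g`` is reported on the line scale (c * sigma2_u) so that the
    shrinkage ratio and h2 agree with the matching kinship model.

    Allele frequencies for centering and the normalizer are computed from
    *all* lines of ``markers`` (which may include unphenotyped selection
    candidates) so that marker effects applied to those candidates via
    :func:`predict_gebv` reproduce the kinship-model predictions exactly.
    """
    y = _as_series(y)
    if len(y) < 10:
        raise ValueError("need at least 10 phenotyped lines for RR-BLUP")
    if markers.has_missing:
        raise ValueError("markers contain missing values; impute first")
    if center:
        W_full, p, norm = _center_and_normalizer(markers.codes)
        centers = 2.0 * p
    else:
        centers = np.ones(markers.n_markers)  # dosage - 1 == raw codes
        W_full = markers.codes.copy()
        p = markers.dosages().mean(axis=0) / 2.0
        norm = 2.0 * float(np.sum(p * (1.0 - p)))
    if norm <= 0.0:
        raise EmptyPanelError("all markers monomorphic: zero normalizer")
    lidx = markers._line_index()
    missing = [l for l in y.index if l not in lidx]
    if missing:
        raise AlignmentError(f"phenotyped lines missing from markers: {missing[:10]}")
    rows = np.array([lidx[l] for l in y.index])
    W = W_full[rows, :]
    K = (W @ W.T) / norm
    K = (K + K.T) / 2.0
    X, xcols = _design_matrix(y.index, fixed_design)
    w = None
    if weights is not None:
        w = weights.loc[y.index].to_numpy(float)
    yv = y.to_numpy(float)
    s2g, s2e, ll, boundary = _reml_spectral(yv, X, K, w)
    beta, Vir, _, _ = _gls_solve(yv, X, K, max(s2g, 1e-12), s2e, w)
    u = (s2g / norm) * (W.T @ Vir)
    fe = pd.Series(beta, index=xcols)
    re = pd.Series(u, index=markers.marker_ids)
    return MixedModelFit(
        s2g, s2e, fe, re, ll, kind="rrblup", boundary=boundary,
        marker_ids=markers.marker_ids.copy(), column_centers=centers,
    )


def predict_gebv(markers_new: MarkerMatrix, fit: MixedModelFit) -> pd.Series:
    """Apply fitted marker effects to a new panel: GEBV = b0 + W_new u."""
    if fit.kind != "rrblup" or fit.marker_ids is None:
        raise ValueError("predict_gebv requires an RR-BLUP fit")
    new_ids = list(markers_new.marker_ids)
    fit_ids = list(fit.marker_ids)
    if new_ids != fit_ids:
        extra = sorted(set(new_ids) - set(fit_ids))[:10]
        absent = sorted(set(fit_ids) - set(new_ids))[:10]
        raise AlignmentError(
            f"marker panels differ (unexpected: {extra}, missing: {absent})"
        )
    if markers_new.has_missing:
        raise ValueError("markers contain missing values; impute first")
    W = markers_new.dosages() - fit.column_centers
    gebv = fit.intercept + W @ fit.random_effects.to_numpy(float)
    return pd.Series(gebv, index=markers_new.line_ids)
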