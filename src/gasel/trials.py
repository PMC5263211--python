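"""Two-stage phenotypic analysis of field trials.

Stage one produces per-line adjusted values (BLUEs) with standard errors for
each trial: unreplicated preliminary trials are corrected for additive row
and column trends estimated from the replicated checks, replicated trials
are reduced to line means.  Stage two combines one year's trials in a
weighted mixed model with a random line-by-trial interaction, and the
kinship-enhanced BLUP (KBLUP) shrinks a preliminary trial's own adjusted
values toward relatives using the genomic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import DomainError
from .genomics import GenomicRelationship, MixedModelFit, fit_gblup

__all__ = [
    "BLUE_COLUMNS",
    "HeritabilityReport",
    "validate_trial_data",
    "adjust_spatial",
    "stage_one_met",
    "trial_heritability",
    "heritability_piepho",
    "heritability_cullis",
    "filter_trials",
    "across_trial_blues",
    "kblup",
]

BLUE_COLUMNS = ["line_id", "trial_id", "blue", "se", "weight", "is_check", "n_obs"]


@dataclass
class HeritabilityReport:
    trial_id: str
    h2_piepho: float
    h2_cullis: float
    sigma2_g: float
    sigma2_e: float


def validate_trial_data(trials: pd.DataFrame) -> None:
    """Enforce the plot-record invariants; raises ValueError on violation."""
    required = {"line_id", "trial_id", "year", "stage", "row", "col", "is_check"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial data missing columns: {sorted(missing)}")
    for trial_id, tdf in trials.groupby("trial_id"):
        dup = tdf.duplicated(subset=["row", "col"])
        if dup.any():
            raise ValueError(f"{trial_id}: duplicated (row, col) positions")
        if (tdf.stage == "PYT").any():
            tests = tdf.loc[~tdf.is_check, "line_id"]
            if tests.duplicated().any():
                raise ValueError(f"{trial_id}: replicated non-check line in PYT")
            check_counts = tdf.loc[tdf.is_check, "line_id"].value_counts()
            if len(check_counts) and (check_counts < 2).any():
                raise ValueError(f"{trial_id}: check with fewer than 2 plots")


# ---------------------------------------------------------------------------
# stage one
# ---------------------------------------------------------------------------


MIN_ERROR_DF = 4


def _fit_check_row_col(checks: pd.DataFrame, trait: str, rows, cols,
                       min_error_df: int = MIN_ERROR_DF):
    """Least-squares row/column effects from check plots.

    The design is over-parameterized (intercept + check identity + row +
    column dummies); the minimum-norm solution is re-centered afterwards.
    A model tier is only accepted with at least ``min_error_df`` residual
    degrees of freedom; otherwise it falls back to rows-only, columns-only
    or no adjustment.
    """
    n = len(checks)
    check_levels = sorted(checks.line_id.unique())
    row_levels = sorted(checks.row.unique())
    col_levels = sorted(checks.col.unique())

    def build(use_rows: bool, use_cols: bool):
        blocks = [np.ones((n, 1))]
        names = ["mu"]
        for lv in check_levels:
            blocks.append((checks.line_id == lv).to_numpy(float)[:, None])
            names.append(("check", lv))
        if use_rows:
            for lv in row_levels:
                blocks.append((checks.row == lv).to_numpy(float)[:, None])
                names.append(("row", lv))
        if use_cols:
            for lv in col_levels:
                blocks.append((checks.col == lv).to_numpy(float)[:, None])
                names.append(("col", lv))
        return np.hstack(blocks), names

    for use_rows, use_cols, label in (
        (True, True, "rows+cols"),
        (True, False, "rows only"),
        (False, True, "cols only"),
        (False, False, "none"),
    ):
        X, names = build(use_rows, use_cols)
        rank = np.linalg.matrix_rank(X)
        need = 1 if (not use_rows and not use_cols) else min_error_df
        if n - rank >= need:
            break
    if label != "rows+cols":
        warnings.warn(
            f"too few check plots for full row+column model; using {label}",
            UserWarning,
        )

    y = checks[trait].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    dof = max(n - np.linalg.matrix_rank(X), 1)
    sigma2_e = float(resid @ resid) / dof

    row_eff = pd.Series(0.0, index=rows)
    col_eff = pd.Series(0.0, index=cols)
    for (kind_lv, c) in zip(names, coef):
        if isinstance(kind_lv, tuple):
            kind, lv = kind_lv
            if kind == "row":
                row_eff.loc[lv] = c
            elif kind == "col":
                col_eff.loc[lv] = c
    # rows/cols without any check carry no information
    rows_with = set(row_levels) if label in ("rows+cols", "rows only") else set()
    cols_with = set(col_levels) if label in ("rows+cols", "cols only") else set()
    uncovered_r = [r for r in rows if r not in rows_with]
    uncovered_c = [c for c in cols if c not in cols_with]
    if label in ("rows+cols", "rows only") and uncovered_r:
        warnings.warn(f"rows without checks get zero adjustment: {uncovered_r}",
                      UserWarning)
    if label in ("rows+cols", "cols only") and uncovered_c:
        warnings.warn(f"columns without checks get zero adjustment: {uncovered_c}",
                      UserWarning)
    # center over informative levels (min-norm split is arbitrary otherwise)
    if rows_with:
        row_eff.loc[sorted(rows_with)] -= row_eff.loc[sorted(rows_with)].mean()
    if cols_with:
        col_eff.loc[sorted(cols_with)] -= col_eff.loc[sorted(cols_with)].mean()
    return row_eff, col_eff, sigma2_e


def adjust_spatial(trial: pd.DataFrame, trait: str = "yield",
                   min_error_df: int = MIN_ERROR_DF) -> pd.DataFrame:
    """Check-based spatial adjustment of one unreplicated trial.

    Row and column effects (and the error variance) are estimated from the
    replicated check plots only, then subtracted from every plot.  The
    estimated effects are re-centered so the mean over check plots is zero,
    leaving the trial's check mean untouched.  Test lines get their single
    adjusted plot value as BLUE with SE = sqrt(sigma2_e); checks get the
    mean of their adjusted plots with SE = sqrt(sigma2_e / n_reps).
    """
    if trial.trial_id.nunique() != 1:
        raise ValueError("adjust_spatial expects exactly one trial")
    trial_id = trial.trial_id.iloc[0]
    checks = trial[trial.is_check]
    if checks.empty or checks.line_id.value_counts().min() < 2:
        raise ValueError(f"{trial_id}: needs checks replicated at least twice")
    rows = sorted(trial.row.unique())
    cols = sorted(trial.col.unique())
    row_eff, col_eff, sigma2_e = _fit_check_row_col(checks, trait, rows, cols,
                                                    min_error_df=min_error_df)

    spat = (row_eff.loc[trial.row].to_numpy()
            + col_eff.loc[trial.col].to_numpy())
    # keep the check-plot mean invariant under adjustment
    shift = float(spat[trial.is_check.to_numpy()].mean())
    adjusted = trial[trait].to_numpy(float) - (spat - shift)

    out = trial[["line_id", "is_check"]].copy()
    out["adjusted"] = adjusted
    se_single = float(np.sqrt(max(sigma2_e, 1e-12)))
    rows_out = []
    for lid, grp in out.groupby("line_id", sort=False):
        n_obs = len(grp)
        blue = float(grp.adjusted.mean())
        se = se_single / np.sqrt(n_obs)
        rows_out.append(
            dict(line_id=lid, trial_id=trial_id, blue=blue, se=se,
                 weight=1.0 / se**2, is_check=bool(grp.is_check.iloc[0]),
                 n_obs=n_obs)
        )
    return pd.DataFrame(rows_out, columns=BLUE_COLUMNS)


def stage_one_met(trial: pd.DataFrame, trait: str = "yield") -> pd.DataFrame:
    """Per-line means and standard errors for one replicated trial.

    The error variance is pooled over within-line deviations; lines
    observed once still receive a BLUE with the pooled single-plot SE.
    """
    if trial.trial_id.nunique() != 1:
        raise ValueError("stage_one_met expects exactly one trial")
    trial_id = trial.trial_id.iloc[0]
    g = trial.groupby("line_id", sort=False)[trait]
    n_obs = g.size()
    means = g.mean()
    ss = ((trial[trait] - means.loc[trial.line_id].to_numpy()) ** 2).sum()
    dof = int((n_obs - 1).sum())
    if dof < 1:
        raise ValueError(f"{trial_id}: no replication, cannot estimate error")
    sigma2_e = float(ss) / dof
    se = np.sqrt(max(sigma2_e, 1e-12) / n_obs)
    is_check = trial.groupby("line_id", sort=False)["is_check"].first()
    return pd.DataFrame(
        dict(line_id=means.index, trial_id=trial_id, blue=means.values,
             se=se.values, weight=1.0 / se.values**2,
             is_check=is_check.values, n_obs=n_obs.values)
    )[BLUE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability_piepho(sigma2_g: float, mvd: float) -> float:
    """h2 = sigma2_g / (sigma2_g + MVD/2), MVD the mean variance of a
    difference of the BLUEs."""
    if mvd <= 0:
        raise DomainError("mvd must be positive")
    if sigma2_g < 0:
        raise DomainError("sigma2_g must be non-negative")
    return sigma2_g / (sigma2_g + mvd / 2.0)


def heritability_cullis(vd_blup: float, sigma2_g: float) -> float:
    """h2 = 1 - VD_BLUP / (2 sigma2_g), clipped at zero."""
    if sigma2_g <= 0:
        raise DomainError("sigma2_g must be positive")
    if vd_blup < 0:
        raise DomainError("vd_blup must be non-negative")
    return max(1.0 - vd_blup / (2.0 * sigma2_g), 0.0)


def trial_heritability(
    blues: pd.DataFrame, K: GenomicRelationship | None = None
) -> HeritabilityReport:
    """Piepho and Cullis heritabilities of one trial from its BLUE table.

    Fits the random-line model (identity kinship unless ``K`` given) with
    weights 1/se^2, takes MVD as the mean pairwise sum of squared SEs and
    VD_BLUP as the mean pairwise prediction-error variance of a difference.
    """
    trial_id = str(blues.trial_id.iloc[0])
    lines = blues.line_id.tolist()
    y = pd.Series(blues.blue.to_numpy(float), index=lines)
    w = pd.Series(blues.weight.to_numpy(float), index=lines)
    Kfit = K.subset(lines) if K is not None else GenomicRelationship.identity(lines)
    # residual variances are known from stage one: estimate sigma2_g alone
    fit = fit_gblup(y, Kfit, weights=w, compute_pev=True, fixed_residual=True)
    se2 = blues.se.to_numpy(float) ** 2
    mvd = 2.0 * float(se2.mean())
    if fit.sigma2_g <= 0:
        return HeritabilityReport(trial_id, 0.0, 0.0, 0.0, float(se2.mean()))
    C = fit.pev
    n = C.shape[0]
    vd = (n * np.trace(C) - C.sum()) * 2.0 / (n * (n - 1))
    return HeritabilityReport(
        trial_id,
        heritability_piepho(fit.sigma2_g, mvd),
        heritability_cullis(float(vd), fit.sigma2_g),
        fit.sigma2_g,
        float(se2.mean()),
    )


def filter_trials(reports, h2_min: float = 0.3, metric: str = "piepho") -> list:
    """Trial ids whose heritability strictly exceeds ``h2_min``."""
    attr = {"piepho": "h2_piepho", "cullis": "h2_cullis"}[metric]
    return [r.trial_id for r in reports if getattr(r, attr) > h2_min]


# ---------------------------------------------------------------------------
# stage two
# ---------------------------------------------------------------------------


def across_trial_blues(blues: pd.DataFrame) -> pd.DataFrame:
    """Combine one year's trials: fixed line and trial effects, random
    line-by-trial interaction, observations weighted by 1/se^2.

    Each line-by-trial cell occurs once, so the interaction contributes a
    diagonal variance sigma2_gt estimated by REML; the returned BLUE for a
    line is its effect at the average trial, with its GLS standard error.
    Lines seen in a single trial are flagged ``low_information``.
    """
    trials_ = sorted(blues.trial_id.unique())
    if len(trials_) < 2:
        raise ValueError("across-trial combination needs at least two trials")
    lines = sorted(blues.line_id.unique())
    li = {l: i for i, l in enumerate(lines)}
    ti = {t: j for j, t in enumerate(trials_)}
    n = len(blues)
    L, T = len(lines), len(trials_)
    X = np.zeros((n, L + T - 1))
    for k, (lid, tid) in enumerate(zip(blues.line_id, blues.trial_id)):
        X[k, li[lid]] = 1.0
        j = ti[tid]
        if j < T - 1:
            X[k, L + j] = 1.0
        else:  # sum-to-zero trial coding: last trial = -(others)
            X[k, L:] = -1.0
    y = blues.blue.to_numpy(float)
    se2 = blues.se.to_numpy(float) ** 2
    vy = float(np.var(y)) + 1e-12

    def negll(t: float) -> float:
        s2gt = np.exp(t)
        v = s2gt + se2
        vi = 1.0 / v
        Xw = X * vi[:, None]
        XtViX = X.T @ Xw
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtViX, Xw.T @ y)
        r = y - X @ beta
        return 0.5 * (float(np.sum(np.log(v))) + logdet_x + float(r @ (vi * r)))

    res = minimize_scalar(
        negll,
        bounds=(np.log(vy) - 25.0, np.log(vy) + 5.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    s2gt = float(np.exp(res.x))
    v = s2gt + se2
    vi = 1.0 / v
    Xw = X * vi[:, None]
    XtViX = X.T @ Xw
    beta = np.linalg.solve(XtViX, Xw.T @ y)
    cov = np.linalg.inv(XtViX)
    counts = blues.groupby("line_id").size()
    out = pd.DataFrame(
        dict(
            line_id=lines,
            blue=beta[:L],
            se=np.sqrt(np.clip(np.diag(cov)[:L], 1e-12, None)),
            n_trials=[int(counts[l]) for l in lines],
        )
    )
    out["weight"] = 1.0 / out.se**2
    out["low_information"] = out.n_trials < 2
    out.attrs["sigma2_gt"] = s2gt
    return out


# ---------------------------------------------------------------------------
# KBLUP
# ---------------------------------------------------------------------------


def kblup(
    pyt_blues: pd.DataFrame,
    K: GenomicRelationship,
    use_weights: bool = True,
) -> tuple[MixedModelFit, pd.Series, float]:
    """Kinship-enhanced BLUP of a preliminary trial's own adjusted values.

    The GBLUP machinery is applied to the candidates' spatially adjusted
    single-plot BLUEs with the grand mean as only fixed effect; the trial
    heritability follows from the shrinkage ratio of the fit.  Returns
    (fit, per-line breeding values incl. intercept, h2).
    """
    lines = pyt_blues.line_id.tolist()
    y = pd.Series(pyt_blues.blue.to_numpy(float), index=lines)
    w = None
    if use_weights:
        w = pd.Series(pyt_blues.weight.to_numpy(float), index=lines)
    fit = fit_gblup(y, K.subset(lines), weights=w)
    bv = fit.intercept + fit.random_effects
    return fit, bv, fit.h2
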