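"""Selection methodology: prediction scaling, the heritability index,
sign-change marker pre-selection, training-population designs,
cross-validation schemes and selection-decision metrics.

The central object is the heritability index: genomic predictions (GBLUP,
trained on other years' multi-environment data) and kinship-enhanced
phenotypic breeding values (KBLUP, from the candidates' own preliminary
trial) are standardized over the selection candidates and merged with their
respective model heritabilities as weights.  After sign-change marker
pre-selection the genomic weight is inflated by 1/(1 - |r|), r the
correlation between the two prediction sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, DomainError, EmptyPanelError
from .genomics import (
    GenomicRelationship,
    MarkerMatrix,
    fit_gblup,
    fit_rrblup,
    genomic_relationship,
)
from .simulate import ProgramData
from .trials import across_trial_blues, adjust_spatial, kblup, stage_one_met

__all__ = [
    "IndexResult",
    "TrainingDesign",
    "ComparisonResult",
    "MarkerSelection",
    "scale_predictions",
    "heritability_index",
    "adjusted_gblup_weight",
    "select_markers_sign",
    "refit_sign_fraction",
    "two_tailed_sample",
    "three_year_training_sets",
    "run_method_comparison",
    "summarize_comparison",
    "top_bottom_hit_rate",
    "hit_rate_table",
    "year_fold_cv",
]

METHODS = ("blup", "kblup", "gblup", "index", "index_marker_sel")


# ---------------------------------------------------------------------------
# scaling and the index
# ---------------------------------------------------------------------------


def scale_predictions(preds: pd.Series, method: str = "sd") -> pd.Series:
    """Center to mean zero and normalize spread over the candidates.

    ``sd`` divides by the (population) standard deviation — the index
    selection convention; ``variance`` divides by the variance, the
    literal alternative.
    """
    preds = preds.astype(float)
    if preds.nunique() < 2:
        raise ValueError("cannot scale constant predictions")
    centered = preds - preds.mean()
    var = float(np.mean(centered.to_numpy() ** 2))
    if method == "sd":
        return centered / np.sqrt(var)
    if method == "variance":
        return centered / var
    raise ValueError(f"unknown scaling method: {method!r}")


@dataclass
class IndexResult:
    """Merged genomic-assisted predictions for one set of candidates."""

    table: pd.DataFrame  # line_id index; gblup_scaled, kblup_scaled, gebv_index
    w_gblup: float
    w_kblup: float

    @property
    def gebv_index(self) -> pd.Series:
        return self.table["gebv_index"]


def heritability_index(
    gblup_preds: pd.Series,
    kblup_preds: pd.Series,
    h2_gblup: float,
    h2_kblup: float,
    w_gblup: float | None = None,
    scale: str = "sd",
) -> IndexResult:
    """GEBV_index = scaled GBLUP * w_GBLUP + scaled KBLUP * w_KBLUP.

    Weights default to the model heritabilities; ``w_gblup`` may be
    overridden (the marker-selection variant inflates it).
    """
    for name, h2 in (("h2_gblup", h2_gblup), ("h2_kblup", h2_kblup)):
        if not 0.0 <= h2 < 1.0:
            raise DomainError(f"{name} must be in [0, 1)")
    if set(gblup_preds.index) != set(kblup_preds.index):
        only_g = sorted(set(gblup_preds.index) - set(kblup_preds.index))[:5]
        only_k = sorted(set(kblup_preds.index) - set(gblup_preds.index))[:5]
        raise AlignmentError(f"candidate sets differ (gblup-only {only_g}, "
                             f"kblup-only {only_k})")
    kblup_preds = kblup_preds.loc[gblup_preds.index]
    gs = scale_predictions(gblup_preds, method=scale)
    ks = scale_predictions(kblup_preds, method=scale)
    wg = h2_gblup if w_gblup is None else float(w_gblup)
    wk = h2_kblup
    table = pd.DataFrame(
        {
            "gblup_scaled": gs,
            "kblup_scaled": ks,
            "gebv_index": gs * wg + ks * wk,
        }
    )
    return IndexResult(table=table, w_gblup=wg, w_kblup=wk)


def adjusted_gblup_weight(h2_gblup: float, r_gblup_kblup: float) -> float:
    """Inflated genomic weight w = h2 / (1 - |r|) for the marker-selected
    index."""
    if not 0.0 <= h2_gblup < 1.0:
        raise DomainError("h2_gblup must be in [0, 1)")
    if abs(r_gblup_kblup) >= 1.0:
        raise DomainError("|r| must be < 1 (weight unbounded)")
    return h2_gblup / (1.0 - abs(r_gblup_kblup))


# ---------------------------------------------------------------------------
# sign-change marker selection
# ---------------------------------------------------------------------------


@dataclass
class MarkerSelection:
    retained_ids: list
    fraction_removed: float


def select_markers_sign(
    u_train: pd.Series,
    u_pyt: pd.Series,
    zero_rule: str = "retain",
) -> MarkerSelection:
    """Retain markers whose effects agree in sign between the two fits.

    Markers with a zero effect in either fit carry no sign evidence and
    are retained by default (``zero_rule='drop'`` removes them too).
    """
    if set(u_train.index) != set(u_pyt.index):
        raise AlignmentError("marker panels of the two fits differ")
    if zero_rule not in {"retain", "drop"}:
        raise ValueError(f"unknown zero_rule: {zero_rule!r}")
    u_pyt = u_pyt.loc[u_train.index]
    prod = u_train.to_numpy(float) * u_pyt.to_numpy(float)
    keep = prod > 0
    if zero_rule == "retain":
        keep |= prod == 0
    retained = list(u_train.index[keep])
    frac = 1.0 - len(retained) / len(u_train)
    return MarkerSelection(retained_ids=retained, fraction_removed=frac)


def refit_sign_fraction(
    markers_selected: MarkerMatrix,
    y_train: pd.Series,
    y_pyt: pd.Series,
    fixed_design_train: pd.DataFrame | None = None,
) -> float:
    """Fraction of effects still sign-discordant after refitting both
    RR-BLUP models on the retained panel (diagnostic only)."""
    if markers_selected.n_markers == 0:
        raise EmptyPanelError("no markers retained")
    f1 = fit_rrblup(y_train, markers_selected, fixed_design=fixed_design_train)
    f2 = fit_rrblup(y_pyt, markers_selected)
    prod = f1.random_effects.to_numpy(float) * f2.random_effects.to_numpy(float)
    return float(np.mean(prod < 0))


# ---------------------------------------------------------------------------
# training population designs
# ---------------------------------------------------------------------------


@dataclass
class TrainingDesign:
    design: str
    lines_per_year: int
    years: list
    sampled_ids: list = field(default_factory=list)


def _tails(values: pd.Series, n: int) -> list:
    n_top = -(-n // 2)  # ceil
    n_bot = n // 2
    df = pd.DataFrame({"v": values})
    df["lid"] = df.index
    top = df.sort_values(["v", "lid"], ascending=[False, True]).head(n_top)
    rest = df.drop(top.index)
    bot = rest.sort_values(["v", "lid"], ascending=[True, True]).head(n_bot)
    return top["lid"].tolist() + bot["lid"].tolist()


def two_tailed_sample(
    phenotypes_by_year: Mapping[int, pd.Series],
    n_per_year: int,
    mode: str = "two_tailed",
    seed: int | np.random.Generator | None = None,
) -> TrainingDesign:
    """Per-year training sample: extremes of the phenotype distribution
    (``two_tailed``, deterministic, ties broken by line id) or uniform
    without replacement (``random``)."""
    if mode not in {"two_tailed", "random"}:
        raise ValueError(f"unknown sampling mode: {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampled: list = []
    years = sorted(phenotypes_by_year)
    for yr in years:
        ph = phenotypes_by_year[yr]
        if n_per_year > len(ph):
            raise ValueError(f"year {yr}: requested {n_per_year} of {len(ph)} lines")
        if mode == "two_tailed":
            sampled.extend(_tails(ph, n_per_year))
        else:
            ids = sorted(ph.index)
            pick = rng.choice(len(ids), size=n_per_year, replace=False)
            sampled.extend([ids[i] for i in sorted(pick)])
    return TrainingDesign(mode, n_per_year, years, sampled)


def three_year_training_sets(
    phenotypes_by_year: Mapping[int, pd.Series],
    selection_year: int,
    lines_per_year: int = 60,
    design: str = "two_tailed",
    seed: int | np.random.Generator | None = None,
) -> list[TrainingDesign]:
    """All three-way combinations of the non-selection years, each sampled
    at ``lines_per_year`` lines per year."""
    remaining = sorted(y for y in phenotypes_by_year if y != selection_year)
    if len(remaining) < 3:
        raise ConfigurationError(
            f"need at least 3 non-selection years, have {len(remaining)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    designs = []
    for combo in itertools.combinations(remaining, 3):
        sub = {y: phenotypes_by_year[y] for y in combo}
        designs.append(two_tailed_sample(sub, lines_per_year, mode=design, seed=rng))
    return designs


# ---------------------------------------------------------------------------
# selection-decision metric
# ---------------------------------------------------------------------------


def top_bottom_hit_rate(
    predicted: pd.Series, observed: pd.Series, fraction: float
) -> tuple[float, float]:
    """Proportion of the observed best (worst) q-fraction recovered in the
    predicted best (worst) q-fraction; ties broken by line id."""
    if not 0.0 < fraction <= 0.5:
        raise DomainError("fraction must be in (0, 0.5]")
    if set(predicted.index) != set(observed.index):
        raise AlignmentError("predicted and observed cover different lines")
    observed = observed.loc[predicted.index]
    n = len(predicted)
    k = max(int(np.floor(fraction * n + 1e-9)), 1)

    def top(s: pd.Series) -> set:
        df = pd.DataFrame({"v": s, "lid": s.index})
        return set(df.sort_values(["v", "lid"], ascending=[False, True])
                   .head(k)["lid"])

    def bottom(s: pd.Series) -> set:
        df = pd.DataFrame({"v": s, "lid": s.index})
        return set(df.sort_values(["v", "lid"], ascending=[True, True])
                   .head(k)["lid"])

    best = len(top(predicted) & top(observed)) / k
    worst = len(bottom(predicted) & bottom(observed)) / k
    return best, worst


# ---------------------------------------------------------------------------
# program-level method comparison
# ---------------------------------------------------------------------------


def _program_tables(dataset: ProgramData, trait: str):
    """Stage-one/stage-two analyses of a simulated program, per year."""
    trials = dataset.trials
    pyt_blues: dict[int, pd.DataFrame] = {}
    for (tid, year), tdf in trials[trials.stage == "PYT"].groupby(
        ["trial_id", "year"]
    ):
        pyt_blues[int(year)] = adjust_spatial(tdf, trait=trait)
    met_blues: dict[int, pd.DataFrame] = {}
    for year, ydf in trials[trials.stage == "MET"].groupby("year"):
        stage1 = [
            stage_one_met(tdf, trait=trait) for _, tdf in ydf.groupby("trial_id")
        ]
        met_blues[int(year)] = across_trial_blues(pd.concat(stage1, ignore_index=True))
    return pyt_blues, met_blues


def _clip_h2(h2: float) -> float:
    return float(np.clip(h2, 1e-3, 1.0 - 1e-3))


@dataclass
class ComparisonResult:
    accuracies: pd.DataFrame          # selection_year, fold, method, accuracy, n
    predictions: list[pd.DataFrame]   # per fold: observed + per-method columns


def run_method_comparison(
    dataset: ProgramData,
    methods: Sequence[str] = METHODS,
    trait: str = "yield",
    lines_per_year: int = 60,
    design: str = "two_tailed",
    seed: int = 0,
    scale: str = "sd",
) -> ComparisonResult:
    """Evaluate selection methods on a simulated program.

    For every selection year t (PYT cohort retested in year t+1) and every
    three-year training combination of the other MET years, the retested
    lines are predicted by the requested methods and correlated with their
    next-year across-trial BLUEs.  The genomic fits never see the
    candidates' phenotypes from either their PYT year or their MET year.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        raise ValueError("empty method list")
    rng = np.random.default_rng(seed)
    pyt_blues, met_blues = _program_tables(dataset, trait)
    check_set = set(dataset.check_ids)

    need_genomic = bool(set(methods) & {"gblup", "index", "index_marker_sel"})
    K_full = genomic_relationship(dataset.markers) if (
        need_genomic or "kblup" in set(methods)
    ) else None

    met_ph = {
        yr: df.set_index("line_id").blue.drop(labels=check_set, errors="ignore")
        for yr, df in met_blues.items()
    }
    rows = []
    fold_tables = []
    for t in sorted(pyt_blues):
        if t + 1 not in met_blues:
            continue
        pyt = pyt_blues[t]
        pyt_tests = pyt[~pyt.is_check].set_index("line_id")
        observed = met_ph[t + 1]
        candidates = sorted(set(pyt_tests.index) & set(observed.index))
        if len(candidates) < 3:
            warnings.warn(f"selection year {t}: no retested lines, fold skipped",
                          UserWarning)
            continue
        obs = observed.loc[candidates]

        blup_pred = pyt_tests.blue.loc[candidates]
        kblup_pred = h2_k = None
        if set(methods) & {"kblup", "index", "index_marker_sel"}:
            _, bv, h2_k = kblup(pyt[~pyt.is_check], K_full)
            kblup_pred = bv.loc[candidates]
            h2_k = _clip_h2(h2_k)

        if not need_genomic:
            row_common = dict(selection_year=t, fold="-", n=len(candidates))
            tab = pd.DataFrame({"observed": obs})
            if "blup" in methods:
                rows.append(dict(**row_common, method="blup",
                                 accuracy=float(np.corrcoef(blup_pred, obs)[0, 1])))
                tab["blup"] = blup_pred
            if "kblup" in methods:
                rows.append(dict(**row_common, method="kblup",
                                 accuracy=float(np.corrcoef(kblup_pred, obs)[0, 1])))
                tab["kblup"] = kblup_pred
            fold_tables.append(tab)
            continue

        train_years = {yr: ph for yr, ph in met_ph.items() if yr != t + 1}
        n_per = min(lines_per_year, min(len(p) for p in train_years.values()))
        designs = three_year_training_sets(
            train_years, selection_year=t + 1, lines_per_year=n_per,
            design=design, seed=rng,
        )
        for d in designs:
            fold = "+".join(str(y) for y in d.years)
            row_common = dict(selection_year=t, fold=fold, n=len(candidates))
            tab = pd.DataFrame({"observed": obs})
            # stack training phenotypes with their year labels
            tr_ids, tr_y, tr_year = [], [], []
            for yr in d.years:
                ph = met_ph[yr]
                ids = [l for l in d.sampled_ids if l in ph.index]
                for l in ids:
                    if l in tr_ids:
                        continue
                    tr_ids.append(l)
                    tr_y.append(float(ph.loc[l]))
                    tr_year.append(yr)
            y_train = pd.Series(tr_y, index=tr_ids)
            yd = pd.get_dummies(pd.Series(tr_year, index=tr_ids), drop_first=True)
            yd.columns = [f"year_{c}" for c in yd.columns]
            fixed = yd.astype(float) if yd.shape[1] else None

            fit_ids = tr_ids + [c for c in candidates if c not in set(tr_ids)]
            Ksub = K_full.subset(fit_ids)
            gfit = fit_gblup(y_train, Ksub, fixed_design=fixed)
            gblup_pred = (gfit.intercept + gfit.random_effects).loc[candidates]
            h2_g = _clip_h2(gfit.h2)

            if "blup" in methods:
                rows.append(dict(**row_common, method="blup",
                                 accuracy=float(np.corrcoef(blup_pred, obs)[0, 1])))
                tab["blup"] = blup_pred
            if "kblup" in methods:
                rows.append(dict(**row_common, method="kblup",
                                 accuracy=float(np.corrcoef(kblup_pred, obs)[0, 1])))
                tab["kblup"] = kblup_pred
            if "gblup" in methods:
                rows.append(dict(**row_common, method="gblup",
                                 accuracy=float(np.corrcoef(gblup_pred, obs)[0, 1])))
                tab["gblup"] = gblup_pred
            if "index" in methods:
                idx = heritability_index(gblup_pred, kblup_pred, h2_g, h2_k,
                                         scale=scale)
                rows.append(dict(**row_common, method="index",
                                 accuracy=float(np.corrcoef(idx.gebv_index, obs)[0, 1])))
                tab["index"] = idx.gebv_index
            if "index_marker_sel" in methods:
                markers_fit = dataset.markers.select_lines(fit_ids)
                u_train = fit_rrblup(y_train, markers_fit,
                                     fixed_design=fixed).random_effects
                pyt_markers = dataset.markers.select_lines(list(pyt_tests.index))
                u_pyt = fit_rrblup(
                    pd.Series(pyt_tests.blue.to_numpy(), index=pyt_tests.index),
                    pyt_markers,
                ).random_effects
                sel = select_markers_sign(u_train, u_pyt)
                if not sel.retained_ids:
                    raise EmptyPanelError("sign selection removed every marker")
                Ksel = genomic_relationship(
                    markers_fit.select_markers(sel.retained_ids)
                )
                gfit2 = fit_gblup(y_train, Ksel, fixed_design=fixed)
                g2 = (gfit2.intercept + gfit2.random_effects).loc[candidates]
                r = float(np.corrcoef(g2, kblup_pred)[0, 1])
                r = float(np.clip(r, -0.999, 0.999))
                wg = adjusted_gblup_weight(_clip_h2(gfit2.h2), r)
                idx2 = heritability_index(g2, kblup_pred, _clip_h2(gfit2.h2),
                                          h2_k, w_gblup=wg, scale=scale)
                rows.append(dict(**row_common, method="index_marker_sel",
                                 accuracy=float(np.corrcoef(idx2.gebv_index, obs)[0, 1])))
                tab["index_marker_sel"] = idx2.gebv_index
            fold_tables.append(tab)
    acc = pd.DataFrame(
        rows, columns=["selection_year", "fold", "n", "method", "accuracy"]
    )
    return ComparisonResult(accuracies=acc, predictions=fold_tables)


def summarize_comparison(result: ComparisonResult) -> pd.DataFrame:
    """Mean accuracy with its standard error, per method."""
    g = result.accuracies.groupby("method")["accuracy"]
    out = pd.DataFrame(
        {"mean": g.mean(), "se": g.sem(), "n_folds": g.size()}
    ).reset_index()
    return out


def hit_rate_table(
    result: ComparisonResult,
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Average top/bottom hit rates over folds, per method and fraction."""
    rows = []
    methods = [c for c in result.predictions[0].columns if c != "observed"] \
        if result.predictions else []
    for q in fractions:
        for m in methods:
            best, worst = [], []
            for tab in result.predictions:
                if m not in tab.columns:
                    continue
                b, w = top_bottom_hit_rate(tab[m], tab["observed"], q)
                best.append(b)
                worst.append(w)
            if best:
                rows.append(dict(fraction=q, method=m,
                                 best=float(np.mean(best)),
                                 worst=float(np.mean(worst))))
    return pd.DataFrame(rows, columns=["fraction", "method", "best", "worst"])


# ---------------------------------------------------------------------------
# year-fold cross-validation geometries
# ---------------------------------------------------------------------------


def year_fold_cv(
    dataset: ProgramData,
    trait: str = "yield",
    n_per_year: Sequence[int] = (10, 20, 30),
    fractions: Sequence[float] = (0.2, 0.5, 0.9),
    n_select: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two training-design evaluation geometries on the MET data.

    ``year_fold``: every MET year is a fold; random and two-tailed training
    samples of each size are drawn from the other years and used to predict
    an identical randomly sampled selection population from the fold year.
    ``loyo``: leave-one-year-out, training on a sampled fraction of each
    remaining year (random vs two-tailed), predicting the whole fold year.
    """
    _, met_blues = _program_tables(dataset, trait)
    check_set = set(dataset.check_ids)
    met_ph = {
        yr: df.set_index("line_id").blue.drop(labels=check_set, errors="ignore")
        for yr, df in met_blues.items()
    }
    years = sorted(met_ph)
    if len(years) < 3:
        raise ConfigurationError("year-fold CV needs at least 3 years of MET data")
    rng = np.random.default_rng(seed)
    K_full = genomic_relationship(dataset.markers)
    rows = []

    def _accuracy(train: dict[int, list], sel_ids: list, sel_year: int) -> float:
        tr_ids, tr_y, tr_year = [], [], []
        for yr, ids in train.items():
            for l in ids:
                if l in sel_ids or l in tr_ids:
                    continue
                tr_ids.append(l)
                tr_y.append(float(met_ph[yr].loc[l]))
                tr_year.append(yr)
        yd = pd.get_dummies(pd.Series(tr_year, index=tr_ids), drop_first=True)
        yd.columns = [f"year_{c}" for c in yd.columns]
        fixed = yd.astype(float) if yd.shape[1] else None
        fit_ids = tr_ids + list(sel_ids)
        fit = fit_gblup(pd.Series(tr_y, index=tr_ids), K_full.subset(fit_ids),
                        fixed_design=fixed)
        pred = fit.random_effects.loc[sel_ids]
        obs = met_ph[sel_year].loc[sel_ids]
        return float(np.corrcoef(pred, obs)[0, 1])

    for fold_year in years:
        other = [y for y in years if y != fold_year]
        ph_fold = met_ph[fold_year]
        for n in n_per_year:
            if n > min(len(met_ph[y]) for y in other) or n > len(ph_fold):
                warnings.warn(f"fold {fold_year}: n={n} too large, skipped",
                              UserWarning)
                continue
            sel_ids = sorted(
                rng.choice(sorted(ph_fold.index), size=n, replace=False)
            )
            for mode in ("random", "two_tailed"):
                train = {}
                for yr in other:
                    d = two_tailed_sample({yr: met_ph[yr]}, n, mode=mode, seed=rng)
                    train[yr] = d.sampled_ids
                rows.append(dict(
                    geometry="year_fold", fold=fold_year, design=mode,
                    n_per_year=n, fraction=np.nan,
                    accuracy=_accuracy(train, sel_ids, fold_year),
                ))
        for frac in fractions:
            sel_ids = sorted(ph_fold.index)
            for mode in ("random", "two_tailed"):
                train = {}
                ok = True
                for yr in other:
                    n = max(int(round(frac * len(met_ph[yr]))), 2)
                    if n > len(met_ph[yr]):
                        ok = False
                        break
                    d = two_tailed_sample({yr: met_ph[yr]}, n, mode=mode, seed=rng)
                    train[yr] = d.sampled_ids
                if not ok:
                    warnings.warn(f"fold {fold_year}: fraction {frac} skipped",
                                  UserWarning)
                    continue
                rows.append(dict(
                    geometry="loyo", fold=fold_year, design=mode,
                    n_per_year=np.nan, fraction=frac,
                    accuracy=_accuracy(train, sel_ids, fold_year),
                ))
    return pd.DataFrame(
        rows,
        columns=["geometry", "fold", "design", "n_per_year", "fraction", "accuracy"],
    )
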