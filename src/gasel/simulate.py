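"""Breeding-program simulator.

Generates multi-family inbred genotypes, two correlated traits of
contrasting heritability, replicated multi-environment trials (MET) with
line-by-trial interaction, and unreplicated preliminary yield trials (PYT)
with replicated checks and additive row/column field trends.  A complete
program run chains PYT cohorts year by year into next-year MET retests of a
phenotypically selected fraction, so every downstream analysis stage can be
exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .genomics import MarkerMatrix

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "ProgramData",
    "simulate_genotypes",
    "simulate_true_values",
    "simulate_met",
    "simulate_pyt",
    "simulate_program",
]

TRAITS = ("yield", "protein")

TRIAL_COLUMNS = [
    "line_id", "trial_id", "year", "stage", "row", "col", "is_check",
    "yield", "protein",
]


@dataclass
class SimulationConfig:
    n_lines_per_year: int = 100
    n_years: int = 6
    n_families: int = 10
    n_markers: int = 300
    n_qtl: int = 60
    h2_yield: float = 0.3
    h2_protein: float = 0.7
    var_gxe: float = 0.25
    n_met_locations: int = 3
    met_reps: int = 2
    pyt_rows: int = 13
    pyt_cols: int = 10
    n_checks: int = 3
    check_reps: int = 10
    spatial_row_sd: float = 0.5
    spatial_col_sd: float = 0.5
    carry_fraction: float = 0.5
    trait_cor: float = 0.3
    var_g: float = 1.0
    mu_yield: float = 50.0
    mu_protein: float = 15.0
    var_trial: float = 1.0
    het_rate: float = 0.02
    n_segments: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ConfigurationError("n_qtl cannot exceed n_markers")
        for name in ("h2_yield", "h2_protein"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be strictly in (0, 1)")
        if self.var_gxe < 0:
            raise ConfigurationError("var_gxe must be >= 0")
        if min(self.n_lines_per_year, self.n_years, self.n_families,
               self.n_markers, self.n_checks, self.check_reps,
               self.n_met_locations, self.met_reps) < 1:
            raise ConfigurationError("counts must be positive")
        needed = self.n_lines_per_year + self.n_checks * self.check_reps
        if self.pyt_rows * self.pyt_cols < needed:
            raise ConfigurationError(
                f"PYT grid {self.pyt_rows}x{self.pyt_cols} too small for "
                f"{needed} plots"
            )
        if not 0.0 < self.carry_fraction <= 1.0:
            raise ConfigurationError("carry_fraction must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")

    def h2(self, trait: str) -> float:
        return {"yield": self.h2_yield, "protein": self.h2_protein}[trait]

    def mu(self, trait: str) -> float:
        return {"yield": self.mu_yield, "protein": self.mu_protein}[trait]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground truth: per-line breeding values and the QTL behind them."""

    line_ids: np.ndarray
    true_bv: pd.DataFrame          # columns 'yield', 'protein'
    qtl_indices: np.ndarray
    qtl_effects: pd.DataFrame      # one row per QTL, columns per trait

    def bv(self, trait: str) -> pd.Series:
        return self.true_bv[trait]


@dataclass
class ProgramData:
    """Everything a simulated breeding program produced."""

    markers: MarkerMatrix
    truth: TruthSet
    trials: pd.DataFrame
    config: SimulationConfig

    @property
    def check_ids(self) -> list:
        return sorted(self.trials.loc[self.trials.is_check, "line_id"].unique())


# ---------------------------------------------------------------------------
# genotypes and truth
# ---------------------------------------------------------------------------


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(
    config: SimulationConfig,
    n_lines: int | None = None,
    line_ids: Sequence | None = None,
    families: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> MarkerMatrix:
    """Inbred-like multi-family genotypes from parental haplotype mosaics.

    Each family has two parental haplotypes drawn from common population
    allele frequencies; a line inherits contiguous marker segments from one
    parent or the other, giving within-family relatedness and local LD.
    A small fraction of loci is set heterozygous (residual heterozygosity).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if line_ids is not None:
        n_lines = len(line_ids)
    elif n_lines is None:
        n_lines = config.n_lines_per_year * config.n_years
    if n_lines < 1:
        raise ConfigurationError("need at least one line")
    if line_ids is None:
        line_ids = [f"L{i:04d}" for i in range(n_lines)]
    if families is None:
        families = [i % config.n_families for i in range(n_lines)]
    if len(families) != n_lines:
        raise ConfigurationError("families must match number of lines")

    m = config.n_markers
    p = rng.uniform(0.1, 0.9, size=m)
    fam_ids = sorted(set(families))
    parents = {f: (rng.random(m) < p).astype(float) * 2.0 - 1.0 for f in fam_ids}
    parents2 = {f: (rng.random(m) < p).astype(float) * 2.0 - 1.0 for f in fam_ids}

    bounds = np.linspace(0, m, max(config.n_segments, 1) + 1).astype(int)
    seg_of_marker = np.zeros(m, dtype=int)
    for s in range(len(bounds) - 1):
        seg_of_marker[bounds[s]:bounds[s + 1]] = s
    n_seg = len(bounds) - 1

    codes = np.empty((n_lines, m))
    for i, fam in enumerate(families):
        choice = rng.integers(0, 2, size=n_seg)  # parent per segment
        take_second = choice[seg_of_marker] == 1
        geno = np.where(take_second, parents2[fam], parents[fam])
        codes[i] = geno
    if config.het_rate > 0:
        het = rng.random(codes.shape) < config.het_rate
        codes[het] = 0.0
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = np.nan
    marker_ids = [f"M{j:04d}" for j in range(m)]
    return MarkerMatrix(np.asarray(line_ids, dtype=object), marker_ids, codes)


def simulate_true_values(
    genotypes: MarkerMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Additive true breeding values for the two traits from sampled QTL.

    Effects for the protein-like trait are correlated with the yield-like
    trait at ``config.trait_cor``; each trait's effects are rescaled so the
    realized variance of the true values equals ``config.var_g`` exactly,
    keeping the linear reconstruction true_bv = Z_qtl @ effects intact.
    """
    if genotypes.has_missing:
        raise ConfigurationError("genotypes must be complete for truth simulation")
    if config.n_qtl > genotypes.n_markers:
        raise ConfigurationError("n_qtl exceeds number of markers")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    qtl = np.sort(rng.choice(genotypes.n_markers, size=config.n_qtl, replace=False))
    a_y = rng.standard_normal(config.n_qtl)
    rho = config.trait_cor
    a_p = rho * a_y + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(config.n_qtl)
    Z = genotypes.codes[:, qtl]
    effects = {}
    bv = {}
    for trait, a in (("yield", a_y), ("protein", a_p)):
        raw = Z @ a
        v = float(np.var(raw, ddof=1)) if len(raw) > 1 else float(np.var(raw))
        scale = math.sqrt(config.var_g / v) if v > 0 else 0.0
        effects[trait] = a * scale
        bv[trait] = Z @ effects[trait]
    true_bv = pd.DataFrame(bv, index=genotypes.line_ids)
    qtl_eff = pd.DataFrame(effects, index=genotypes.marker_ids[qtl])
    return TruthSet(genotypes.line_ids.copy(), true_bv, qtl, qtl_eff)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def _residual_sd_met(config: SimulationConfig, trait: str) -> float:
    # per-plot residual sd chosen so the line-mean heritability within a
    # trial (genetic variance incl. GxE over mean error variance) hits target
    h2 = config.h2(trait)
    sg2 = config.var_g + config.var_gxe
    s2e_mean = sg2 * (1.0 / h2 - 1.0)
    return math.sqrt(s2e_mean * config.met_reps)


def _residual_sd_pyt(config: SimulationConfig, trait: str) -> float:
    h2 = config.h2(trait)
    return math.sqrt(config.var_g * (1.0 / h2 - 1.0))


def simulate_met(
    truth: TruthSet,
    config: SimulationConfig,
    lines: Sequence,
    year: int,
    rng: np.random.Generator | None = None,
    check_ids: Sequence = (),
) -> pd.DataFrame:
    """Replicated multi-location trials for one year.

    phenotype = mu + true_bv + trial effect + line-by-trial interaction
    (variance ``var_gxe``) + plot residual; the residual variance is set so
    each trial's line-mean heritability matches the configured target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    all_lines = list(lines) + [c for c in check_ids if c not in set(lines)]
    bv = {t: truth.true_bv[t].reindex(all_lines) for t in TRAITS}
    for t in TRAITS:
        if bv[t].isna().any():
            raise ConfigurationError("truth missing for some MET lines")
    records = []
    check_set = set(check_ids)
    for loc in range(config.n_met_locations):
        trial_id = f"MET_y{year}_l{loc + 1}"
        t_eff = {t: rng.normal(0.0, math.sqrt(config.var_trial)) for t in TRAITS}
        gxe = {
            t: rng.normal(0.0, math.sqrt(config.var_gxe), size=len(all_lines))
            if config.var_gxe > 0 else np.zeros(len(all_lines))
            for t in TRAITS
        }
        plot = 0
        for i, lid in enumerate(all_lines):
            for rep in range(config.met_reps):
                rec = {
                    "line_id": lid, "trial_id": trial_id, "year": year,
                    "stage": "MET", "row": rep + 1, "col": plot + 1,
                    "is_check": lid in check_set,
                }
                for t in TRAITS:
                    e = rng.normal(0.0, _residual_sd_met(config, t))
                    rec[t] = config.mu(t) + bv[t].iloc[i] + t_eff[t] + gxe[t][i] + e
                records.append(rec)
            plot += 1
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def _check_positions(rows: int, cols: int, n_plots: int) -> list[tuple[int, int]]:
    """Spread check plots over the grid.

    Rows are cycled so every row holds a check once n_plots >= rows; the
    column stride cols-1 is coprime with cols, so columns are covered once
    n_plots >= cols.  Collisions fall back to linear probing.
    """
    ccoef = cols - 1 if cols > 1 else 1
    taken: set[tuple[int, int]] = set()
    pos = []
    for k in range(n_plots):
        r = k % rows
        c = (k * ccoef + k // rows) % cols
        while (r, c) in taken:
            c = (c + 1) % cols
        taken.add((r, c))
        pos.append((r, c))
    return pos


def simulate_pyt(
    truth: TruthSet,
    config: SimulationConfig,
    lines: Sequence,
    year: int,
    rng: np.random.Generator | None = None,
    check_ids: Sequence | None = None,
) -> pd.DataFrame:
    """One unreplicated preliminary trial: one plot per test line plus
    ``check_reps`` plots of each check, on a rows x cols grid with additive
    row and column trends."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if check_ids is None:
        check_ids = [f"CHK{c + 1:02d}" for c in range(config.n_checks)]
    n_check_plots = config.n_checks * config.check_reps
    n_plots = len(lines) + n_check_plots
    if n_plots > config.pyt_rows * config.pyt_cols:
        raise ConfigurationError(
            f"PYT grid too small: {n_plots} plots on "
            f"{config.pyt_rows}x{config.pyt_cols}"
        )
    bv = {t: truth.true_bv[t].reindex(list(lines) + list(check_ids)) for t in TRAITS}
    for t in TRAITS:
        if bv[t].isna().any():
            raise ConfigurationError("truth missing for some PYT lines/checks")

    check_pos = _check_positions(config.pyt_rows, config.pyt_cols, n_check_plots)
    check_cells = set(check_pos)
    free_cells = [
        (r, c)
        for r in range(config.pyt_rows)
        for c in range(config.pyt_cols)
        if (r, c) not in check_cells
    ]
    order = rng.permutation(len(lines))
    row_eff = {t: rng.normal(0.0, config.spatial_row_sd, size=config.pyt_rows)
               for t in TRAITS}
    col_eff = {t: rng.normal(0.0, config.spatial_col_sd, size=config.pyt_cols)
               for t in TRAITS}
    trial_id = f"PYT_y{year}"
    records = []

    def _plot(lid, r, c, is_check):
        rec = {
            "line_id": lid, "trial_id": trial_id, "year": year, "stage": "PYT",
            "row": r + 1, "col": c + 1, "is_check": is_check,
        }
        for t in TRAITS:
            e = rng.normal(0.0, _residual_sd_pyt(config, t))
            rec[t] = (
                config.mu(t) + bv[t].loc[lid]
                + row_eff[t][r] + col_eff[t][c] + e
            )
        records.append(rec)

    for k, (r, c) in enumerate(check_pos):
        _plot(check_ids[k % config.n_checks], r, c, True)
    for j, li in enumerate(order):
        r, c = free_cells[j]
        _plot(list(lines)[li], r, c, False)
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# full program
# ---------------------------------------------------------------------------


def simulate_program(config: SimulationConfig) -> ProgramData:
    """Simulate a complete multi-year program.

    Cohort ``y`` (year y = 1..n_years) enters its PYT in year y; the top
    ``carry_fraction`` by *observed* PYT yield is retested in the following
    year's MET, so later-stage data carry the selection pressure a real
    program would.  Checks are shared across all trials and genotyped.
    Deterministic given ``config.seed``.
    """
    rng_geno, rng_truth, rng_met, rng_pyt = _streams(config.seed, 4)
    n_test = config.n_lines_per_year * config.n_years
    line_ids = [
        f"L{y + 1:02d}_{i + 1:03d}"
        for y in range(config.n_years)
        for i in range(config.n_lines_per_year)
    ]
    families = [i % config.n_families for i in range(n_test)]
    check_ids = [f"CHK{c + 1:02d}" for c in range(config.n_checks)]
    # checks are unrelated varieties: one singleton family each
    fam_checks = [config.n_families + c for c in range(config.n_checks)]
    markers = simulate_genotypes(
        config,
        line_ids=line_ids + check_ids,
        families=families + fam_checks,
        rng=rng_geno,
    )
    if markers.has_missing:
        from .genomics import impute_missing

        truth_markers = impute_missing(markers, method="mean")
    else:
        truth_markers = markers
    truth = simulate_true_values(truth_markers, config, rng=rng_truth)

    frames = []
    for y in range(1, config.n_years + 1):
        cohort = line_ids[(y - 1) * config.n_lines_per_year:
                          y * config.n_lines_per_year]
        pyt = simulate_pyt(truth, config, cohort, year=y, rng=rng_pyt,
                           check_ids=check_ids)
        frames.append(pyt)
        if y < config.n_years:
            test = pyt.loc[~pyt.is_check, ["line_id", "yield"]]
            n_keep = max(int(round(config.carry_fraction * len(test))), 2)
            selected = (
                test.sort_values(["yield", "line_id"], ascending=[False, True])
                .head(n_keep)["line_id"].tolist()
            )
            met = simulate_met(truth, config, selected, year=y + 1,
                               rng=rng_met, check_ids=check_ids)
            frames.append(met)
    trials = pd.concat(frames, ignore_index=True)
    return ProgramData(markers=markers, truth=truth, trials=trials, config=config)
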