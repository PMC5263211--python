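import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gasel.exceptions import AlignmentError, ConfigurationError, DomainError
from gasel.selection import (
    adjusted_gblup_weight,
    heritability_index,
    hit_rate_table,
    run_method_comparison,
    scale_predictions,
    select_markers_sign,
    refit_sign_fraction,
    summarize_comparison,
    three_year_training_sets,
    top_bottom_hit_rate,
    two_tailed_sample,
    year_fold_cv,
)
from gasel.simulate import SimulationConfig, simulate_program


class TestScalePredictions:
    def test_sd_standardization(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        out = scale_predictions(s)
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_mean_zero(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.standard_normal(50))
        assert scale_predictions(s).mean() == pytest.approx(0.0, abs=1e-12)
        assert scale_predictions(s, "variance").mean() == pytest.approx(0.0, abs=1e-12)

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        s = pd.Series([0.3, -1.2, 2.5, 0.0, 1.1])
        base = scale_predictions(s)
        trans = scale_predictions(a * s + b)
        np.testing.assert_allclose(trans, base, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_predictions(pd.Series([1.0, 1.0, 1.0]))


class TestHeritabilityIndex:
    def test_linearity_bookkeeping(self):
        rng = np.random.default_rng(1)
        ids = [f"L{i}" for i in range(20)]
        g = pd.Series(rng.standard_normal(20), index=ids)
        k = pd.Series(rng.standard_normal(20), index=ids)
        res = heritability_index(g, k, 0.4, 0.3)
        recon = (res.table.gblup_scaled * res.w_gblup
                 + res.table.kblup_scaled * res.w_kblup)
        np.testing.assert_array_equal(recon.to_numpy(),
                                      res.table.gebv_index.to_numpy())

    def test_zero_kblup_weight_gives_gblup_ranking(self):
        rng = np.random.default_rng(2)
        ids = [f"L{i}" for i in range(30)]
        g = pd.Series(rng.standard_normal(30), index=ids)
        k = pd.Series(rng.standard_normal(30), index=ids)
        res = heritability_index(g, k, 0.5, 0.0)
        assert res.gebv_index.rank().corr(g.rank()) == pytest.approx(1.0)

    def test_cancellation(self):
        ids = [f"L{i}" for i in range(10)]
        g = pd.Series(np.arange(10.0), index=ids)
        res = heritability_index(g, -g, 0.4, 0.4)
        np.testing.assert_allclose(res.gebv_index, 0.0, atol=1e-12)

    def test_id_mismatch(self):
        g = pd.Series([1.0, 2.0], index=["a", "b"])
        k = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(AlignmentError):
            heritability_index(g, k, 0.4, 0.3)


class TestAdjustedWeight:
    def test_closed_form(self):
        assert adjusted_gblup_weight(0.4, 0.5) == pytest.approx(0.8)

    def test_zero_correlation(self):
        assert adjusted_gblup_weight(0.37, 0.0) == pytest.approx(0.37)

    def test_sign_symmetry(self):
        assert adjusted_gblup_weight(0.4, -0.5) == adjusted_gblup_weight(0.4, 0.5)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.3])
    def test_unbounded(self, r):
        with pytest.raises(DomainError):
            adjusted_gblup_weight(0.4, r)


class TestSignSelection:
    def test_identical_fits_keep_all(self):
        u = pd.Series([0.5, -0.2, 1.1], index=["a", "b", "c"])
        sel = select_markers_sign(u, u.copy())
        assert sel.retained_ids == ["a", "b", "c"]
        assert sel.fraction_removed == 0.0

    def test_total_disagreement_removes_all(self):
        u = pd.Series([0.5, -0.2, 1.1], index=["a", "b", "c"])
        sel = select_markers_sign(u, -u)
        assert sel.retained_ids == []
        assert sel.fraction_removed == 1.0

    def test_zero_rule(self):
        u1 = pd.Series([0.0, 1.0], index=["a", "b"])
        u2 = pd.Series([1.0, 1.0], index=["a", "b"])
        assert select_markers_sign(u1, u2, "retain").retained_ids == ["a", "b"]
        assert select_markers_sign(u1, u2, "drop").retained_ids == ["b"]

    def test_independent_noise_removes_half(self):
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(10):
            ids = [f"m{i}" for i in range(500)]
            u1 = pd.Series(rng.standard_normal(500), index=ids)
            u2 = pd.Series(rng.standard_normal(500), index=ids)
            fracs.append(select_markers_sign(u1, u2).fraction_removed)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_disjoint_panels(self):
        u1 = pd.Series([1.0], index=["a"])
        u2 = pd.Series([1.0], index=["b"])
        with pytest.raises(AlignmentError):
            select_markers_sign(u1, u2)


class TestRefitSignFraction:
    def test_orthogonal_noiseless(self, hadamard_markers):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(15)
        y = pd.Series(hadamard_markers.codes @ a,
                      index=hadamard_markers.line_ids)
        frac = refit_sign_fraction(hadamard_markers, y, y.copy())
        assert frac == 0.0

    def test_single_marker_degenerate(self, hadamard_markers):
        mm = hadamard_markers.select_markers(["M03"])
        rng = np.random.default_rng(5)
        y1 = pd.Series(rng.standard_normal(16), index=mm.line_ids)
        y2 = pd.Series(rng.standard_normal(16), index=mm.line_ids)
        assert refit_sign_fraction(mm, y1, y2) in (0.0, 1.0)


class TestTwoTailedSample:
    def test_extremes_selected(self):
        ph = {2011: pd.Series({"a": 1.0, "b": 5.0, "c": 3.0, "d": 9.0})}
        d = two_tailed_sample(ph, 2, mode="two_tailed")
        assert set(d.sampled_ids) == {"d", "a"}

    def test_random_reproducible(self):
        ph = {1: pd.Series(np.arange(10.0), index=[f"l{i}" for i in range(10)])}
        d1 = two_tailed_sample(ph, 4, mode="random", seed=7)
        d2 = two_tailed_sample(ph, 4, mode="random", seed=7)
        assert d1.sampled_ids == d2.sampled_ids

    def test_pair_variance_dominates_exhaustively(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal(6)
        ph = {1: pd.Series(vals, index=[f"l{i}" for i in range(6)])}
        d = two_tailed_sample(ph, 2, mode="two_tailed")
        v_tails = ph[1].loc[d.sampled_ids].var()
        for pair in itertools.combinations(range(6), 2):
            assert v_tails >= ph[1].iloc[list(pair)].var() - 1e-12

    def test_variance_beats_random_on_average(self):
        rng = np.random.default_rng(7)
        vals = pd.Series(rng.standard_normal(12),
                         index=[f"l{i}" for i in range(12)])
        ph = {1: vals}
        v_tails = vals.loc[
            two_tailed_sample(ph, 6, mode="two_tailed").sampled_ids
        ].var()
        v_rand = np.mean([
            vals.loc[two_tailed_sample(ph, 6, mode="random", seed=s).sampled_ids].var()
            for s in range(200)
        ])
        assert v_tails > v_rand

    def test_oversampling_rejected(self):
        ph = {1: pd.Series([1.0, 2.0], index=["a", "b"])}
        with pytest.raises(ValueError, match="requested"):
            two_tailed_sample(ph, 3)

    def test_ties_broken_by_line_id(self):
        ph = {1: pd.Series({"b": 1.0, "a": 1.0, "d": 0.0, "c": 0.0})}
        d = two_tailed_sample(ph, 2, mode="two_tailed")
        assert d.sampled_ids == ["a", "c"]


class TestThreeYearTrainingSets:
    def _ph(self, years, n=70):
        rng = np.random.default_rng(8)
        return {
            y: pd.Series(rng.standard_normal(n),
                         index=[f"y{y}_l{i}" for i in range(n)])
            for y in years
        }

    def test_four_remaining_years_give_four_sets(self):
        designs = three_year_training_sets(self._ph([1, 2, 3, 4, 5]), 1,
                                           lines_per_year=60)
        assert len(designs) == 4

    def test_set_size_180(self):
        designs = three_year_training_sets(self._ph([1, 2, 3, 4, 5]), 1,
                                           lines_per_year=60)
        assert all(len(d.sampled_ids) == 180 for d in designs)

    def test_three_remaining_years_one_combo(self):
        designs = three_year_training_sets(self._ph([1, 2, 3, 4]), 4,
                                           lines_per_year=10)
        assert len(designs) == 1

    def test_too_few_years(self):
        with pytest.raises(ConfigurationError):
            three_year_training_sets(self._ph([1, 2, 3]), 1)


class TestHitRate:
    def test_perfect_prediction(self):
        s = pd.Series(np.arange(20.0), index=[f"l{i:02d}" for i in range(20)])
        for q in (0.05, 0.1, 0.25, 0.5):
            assert top_bottom_hit_rate(s, s, q) == (1.0, 1.0)

    def test_anti_prediction(self):
        s = pd.Series(np.arange(20.0), index=[f"l{i:02d}" for i in range(20)])
        best, worst = top_bottom_hit_rate(-s, s, 0.5)
        assert best == 0.0 and worst == 0.0

    def test_hypergeometric_expectation_exhaustive(self):
        # all C(10, k) predicted top-sets equally likely -> mean hit rate k/10
        n = 10
        ids = [f"l{i}" for i in range(n)]
        observed = pd.Series(np.arange(float(n)), index=ids)
        for k in (1, 2, 5):
            rates = []
            for chosen in itertools.combinations(range(n), k):
                pred = pd.Series(0.0, index=ids)
                for rank, i in enumerate(chosen):
                    pred.iloc[i] = 100.0 + rank
                # remaining get distinct low values so ties cannot interfere
                low = [i for i in range(n) if i not in chosen]
                for rank, i in enumerate(low):
                    pred.iloc[i] = -float(rank)
                best, _ = top_bottom_hit_rate(pred, observed, k / n)
                rates.append(best)
            assert np.mean(rates) == pytest.approx(k / n, abs=1e-12)

    def test_fraction_domain(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        for q in (0.0, 0.6, -0.1):
            with pytest.raises(DomainError):
                top_bottom_hit_rate(s, s, q)


@pytest.fixture(scope="module")
def comparison_result(small_program):
    return run_method_comparison(small_program, trait="yield",
                                 lines_per_year=20, seed=0)


class TestMethodComparison:
    def test_structure(self, comparison_result):
        acc = comparison_result.accuracies
        assert set(acc.method) == {"blup", "kblup", "gblup", "index",
                                   "index_marker_sel"}
        assert acc.accuracy.between(-1, 1).all()
        # 4 selection years x C(3,3)=1 combo in a 5-year program
        assert acc.groupby("method").size().eq(4).all()

    def test_blup_is_pyt_met_correlation(self, small_program, comparison_result):
        from gasel.selection import _program_tables

        pyt_blues, met_blues = _program_tables(small_program, "yield")
        t = 1
        pyt = pyt_blues[t]
        tests = pyt[~pyt.is_check].set_index("line_id")
        met = met_blues[t + 1].set_index("line_id").blue
        cands = sorted(set(tests.index) & set(met.index))
        expected = float(np.corrcoef(tests.blue.loc[cands], met.loc[cands])[0, 1])
        got = comparison_result.accuracies.query(
            "method == 'blup' and selection_year == 1"
        ).accuracy.iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_noiseless_limit(self):
        cfg = SimulationConfig(
            n_lines_per_year=60, n_years=5, n_markers=200, n_qtl=200,
            seed=42, pyt_rows=10, pyt_cols=9, check_reps=10,
            h2_yield=0.99, h2_protein=0.99, var_gxe=0.0,
            spatial_row_sd=0.0, spatial_col_sd=0.0, carry_fraction=0.6,
            n_families=6,
        )
        res = run_method_comparison(simulate_program(cfg), trait="yield",
                                    lines_per_year=20, seed=0)
        m = summarize_comparison(res).set_index("method")["mean"]
        assert m["blup"] > 0.9
        assert m["kblup"] > 0.9
        assert m["gblup"] > 0.5
        assert m["index"] > 0.8

    def test_empty_method_list(self, small_program):
        with pytest.raises(ValueError):
            run_method_comparison(small_program, methods=())

    def test_summary_and_hit_rates(self, comparison_result):
        summary = summarize_comparison(comparison_result)
        assert {"method", "mean", "se", "n_folds"} <= set(summary.columns)
        hits = hit_rate_table(comparison_result, fractions=(0.2, 0.5))
        assert len(hits) == 2 * 5
        assert hits.best.between(0, 1).all()


class TestYearFoldCV:
    def test_geometries_present(self, small_program):
        out = year_fold_cv(small_program, n_per_year=(10,), fractions=(0.5,),
                           seed=0)
        assert set(out.geometry) == {"year_fold", "loyo"}
        assert set(out.design) == {"random", "two_tailed"}
        assert out.accuracy.between(-1, 1).all()

    def test_paired_selection_population(self, small_program):
        # both arms of a fold share the identical selection population by
        # construction: accuracy rows come in random/two-tailed pairs
        out = year_fold_cv(small_program, n_per_year=(10,), fractions=(),
                           seed=1)
        counts = out.groupby(["fold", "n_per_year"]).design.nunique()
        assert (counts == 2).all()

    def test_single_year_errors(self):
        cfg = SimulationConfig(n_lines_per_year=40, n_years=2, n_markers=80,
                               n_qtl=30, pyt_rows=9, pyt_cols=8, seed=13)
        data = simulate_program(cfg)
        with pytest.raises(ConfigurationError):
            year_fold_cv(data)


@pytest.fixture(scope="module")
def replicated_runs():
    rows = []
    hit_rows = []
    for s in range(12):
        cfg = SimulationConfig(
            n_lines_per_year=60, n_years=5, n_markers=200, n_qtl=60,
            seed=950 + s, pyt_rows=10, pyt_cols=9, check_reps=10,
            carry_fraction=0.6, n_families=8,
        )
        data = simulate_program(cfg)
        res = run_method_comparison(data, trait="yield",
                                    lines_per_year=20, seed=s)
        m = res.accuracies.groupby("method").accuracy.mean()
        rows.append(m)
        h = hit_rate_table(res, fractions=(0.2,)).set_index("method")
        hit_rows.append(h.best)
    return pd.DataFrame(rows), pd.DataFrame(hit_rows)


class TestStochasticSuperiority:
    """Directional properties of the method ordering, on repeated simulated
    programs, each asserted up to twice its simulation standard error."""

    @staticmethod
    def _ge_within_se(diffs):
        diffs = np.asarray(diffs)
        return diffs.mean() >= -2.0 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_index_at_least_components(self, replicated_runs):
        acc, _ = replicated_runs
        assert self._ge_within_se(acc["index"] - acc["gblup"])
        assert self._ge_within_se(acc["index"] - acc["kblup"])

    def test_marker_selected_index_at_least_index(self, replicated_runs):
        acc, _ = replicated_runs
        assert self._ge_within_se(acc["index_marker_sel"] - acc["index"])

    def test_kblup_and_gblup_beat_plain_blup(self, replicated_runs):
        acc, _ = replicated_runs
        assert self._ge_within_se(acc["kblup"] - acc["blup"])
        assert self._ge_within_se(acc["gblup"] - acc["blup"])

    def test_index_hit_rate_beats_blup_at_20pct(self, replicated_runs):
        _, hits = replicated_runs
        assert self._ge_within_se(hits["index"] - hits["blup"])

    def test_two_tailed_at_least_random(self):
        diffs = []
        for s in range(8):
            cfg = SimulationConfig(
                n_lines_per_year=60, n_years=5, n_markers=200, n_qtl=60,
                seed=900 + s, pyt_rows=10, pyt_cols=9, check_reps=10,
                carry_fraction=0.6, n_families=8,
            )
            data = simulate_program(cfg)
            out = year_fold_cv(data, n_per_year=(15,), fractions=(), seed=s)
            m = out.groupby("design").accuracy.mean()
            diffs.append(m["two_tailed"] - m["random"])
        assert self._ge_within_se(diffs)
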