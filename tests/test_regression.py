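"""Standardization and least-squares attribution, with independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopop import (PARAM_NAMES, SurrogateSpec, fit_least_squares,
                       generate_biomarker_table, regress_all, standardize)
from cardiopop.regression import (exclusion_mask, fit_biomarker,
                                  reported_coefficients, results_frame)


class TestStandardize:
    def test_small_example_exact(self):
        z = standardize([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-15)
        assert z.std() == pytest.approx(1.0, abs=1e-15)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([4.0, 4.0, 4.0])

    def test_idempotent_up_to_float_tolerance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 3, 500)
        once = standardize(x)
        twice = standardize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            standardize([1.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
    def test_output_moments_for_arbitrary_input(self, values):
        z = standardize(values)
        assert abs(z.mean()) < 1e-7
        assert abs(z.std() - 1.0) < 1e-7

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(-100.0, 100.0), st.floats(0.01, 1e3))
    def test_affine_invariance(self, shift, scale):
        x = np.array([2.0, 5.0, 11.0, 3.0, 7.0])
        assert np.allclose(standardize(x), standardize(shift + scale * x),
                           atol=1e-9)


class TestFitLeastSquares:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (50, 4))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        res = fit_least_squares(X, y, ["a", "b", "c", "d"])
        assert res.coefficients["a"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["b"] == pytest.approx(-1.0, abs=1e-10)
        assert res.coefficients["c"] == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients["d"] == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_brute_force_grid_search(self):
        """6-row, 2-predictor instance: exhaustive lattice search over
        (b1, b2, intercept) is the oracle for the RSS minimizer."""
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0],
                      [0.5, 0.2], [0.3, 0.9], [0.8, 0.5]])
        y = np.array([0.3, 1.1, 1.5, 0.7, 0.6, 1.2])
        grid = np.arange(-2.0, 2.001, 0.05)
        best, best_rss = None, np.inf
        for b1, b2, b0 in itertools.product(grid, grid[(grid >= -1) & (grid <= 1)],
                                            grid[(grid >= -1) & (grid <= 1)]):
            r = y - (b1 * X[:, 0] + b2 * X[:, 1] + b0)
            rss = r @ r
            if rss < best_rss:
                best, best_rss = (b1, b2, b0), rss
        res = fit_least_squares(X, y, ["b1", "b2"])
        assert res.coefficients["b1"] == pytest.approx(best[0], abs=0.05)
        assert res.coefficients["b2"] == pytest.approx(best[1], abs=0.05)
        assert res.intercept == pytest.approx(best[2], abs=0.05)

    def test_pure_noise_gives_null_coefficients_and_r2(self):
        rng = np.random.default_rng(2)
        n = 5000
        X = rng.uniform(0.7, 1.3, (n, 7))
        y = standardize(rng.normal(size=n))
        res = fit_least_squares((X - X.mean(0)) / X.std(0), y, PARAM_NAMES)
        assert all(abs(c) < 0.06 for c in res.coefficients.values())
        assert res.r_squared < 0.01

    def test_rank_deficiency_names_dependent_columns(self):
        X = np.zeros((30, 3))
        X[:, 0] = np.linspace(0, 1, 30)
        X[:, 1] = 2.0 * X[:, 0]
        X[:, 2] = np.linspace(1, 0, 30)
        with pytest.raises(ValueError, match="dup"):
            fit_least_squares(X, np.arange(30.0), ["base", "dup", "other"])

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_least_squares(np.ones((3, 7)), np.ones(3))


class TestRegressAll:
    def _table(self, n=1500, noise=2.0, seed=5):
        spec = SurrogateSpec(
            effects={"APD80": {"s_Kr": -90.0, "s_CaL": 30.0, "s_Ks": -8.0}},
            noise_sd={"APD80": noise}, seed=seed)
        return generate_biomarker_table(n, "non-failing", spec)

    def test_planted_effect_ranking_recovered(self):
        table = self._table()
        res = regress_all(table, biomarkers=("APD80",))[("non-failing", 1500, "APD80")]
        coef = {p: abs(c) for p, c in res.coefficients.items()}
        ranked = sorted(coef, key=coef.get, reverse=True)
        assert ranked[:2] == ["s_Kr", "s_CaL"]
        assert res.coefficients["s_Kr"] < 0 < res.coefficients["s_CaL"]

    def test_no_exclusions_uses_all_rows(self):
        table = self._table(n=200)
        res = fit_biomarker(table, "non-failing", 1500, "APD80")
        assert res.n_used == 200 and res.n_excluded == 0

    def test_alternans_and_noncaptured_rows_excluded(self):
        table = self._table(n=300)
        table.loc[:9, "alternans_V"] = True
        table.loc[10:19, "alternans_Ca"] = True
        table.loc[20:29, "captured"] = False
        res = fit_biomarker(table, "non-failing", 1500, "APD80")
        assert res.n_used == 270 and res.n_excluded == 30
        assert exclusion_mask(table, "APD80").sum() == 30

    def test_small_sample_skipped_with_warning(self):
        table = self._table(n=30)
        with pytest.warns(UserWarning, match="skipping"):
            assert fit_biomarker(table, "non-failing", 1500, "APD80") is None

    def test_coefficients_invariant_to_row_order(self):
        table = self._table(n=400)
        shuffled = table.sample(frac=1.0, random_state=11).reset_index(drop=True)
        a = fit_biomarker(table, "non-failing", 1500, "APD80")
        b = fit_biomarker(shuffled, "non-failing", 1500, "APD80")
        for p in PARAM_NAMES:
            assert a.coefficients[p] == pytest.approx(b.coefficients[p], abs=1e-9)

    def test_results_frame_and_display_threshold(self):
        table = self._table()
        results = regress_all(table, biomarkers=("APD80",))
        df = results_frame(results)
        assert set(df.columns) >= {"condition", "bcl", "biomarker", "parameter",
                                   "coefficient", "r_squared", "n_used",
                                   "n_excluded"}
        shown = reported_coefficients(results, threshold=0.2)
        assert (shown["coefficient"].abs() > 0.2).all()
        # the dominant planted effect survives the display threshold
        assert "s_Kr" in set(shown["parameter"])
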