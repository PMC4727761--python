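"""Preprocessing operators: analytic oracles and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftirquant.exceptions import ConfigError, NumericError
from ftirquant.preprocess import (
    PreprocessRecipe,
    apply_recipe,
    baseline_linear,
    offset_correct,
    savgol,
    select_regions,
    snv,
)
from ftirquant.spectra_io import SpectraSet


class TestOffset:
    def test_mean_subtraction(self):
        out = offset_correct(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out[1], [-1, 0, 1], atol=1e-12)

    def test_shift_invariance_and_idempotence(self, rng):
        X = rng.normal(size=(4, 30))
        np.testing.assert_allclose(
            offset_correct(X + 7.3), offset_correct(X), atol=1e-12
        )
        once = offset_correct(X)
        np.testing.assert_allclose(offset_correct(once), once, atol=1e-12)


class TestBaselineLinear:
    def test_pure_linear_row_removed_exactly(self):
        grid = np.arange(650.0, 750.0, 2.0)
        X = (0.003 * grid + 1.2)[None, :]
        out = baseline_linear(X, grid, [grid[0], grid[-1]])
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_peak_on_ramp_recovered(self):
        grid = np.arange(900.0, 1300.0, 2.0)
        peak = 0.5 * np.exp(-((grid - 1100.0) ** 2) / (2 * 20.0**2))
        ramp = 1e-3 * grid - 0.4
        out = baseline_linear((peak + ramp)[None, :], grid, [900.0, 1298.0])
        # where the peak is negligible only the ramp was present -> ~0
        far = (grid < 960) | (grid > 1240)
        np.testing.assert_allclose(out[0][far], peak[far], atol=1e-8)
        # peak apex preserved
        assert out[0].max() == pytest.approx(0.5, abs=1e-6)

    def test_anchor_outside_grid_rejected(self):
        grid = np.arange(650.0, 700.0, 2.0)
        with pytest.raises(ConfigError):
            baseline_linear(np.ones((1, len(grid))), grid, [600.0, 698.0])


class TestSavitzkyGolay:
    @pytest.mark.parametrize("spacing", [1.0, 2.0, 4.0])
    def test_first_derivative_of_linear_signal(self, spacing):
        grid = np.arange(1000.0, 1000.0 + 40 * spacing, spacing)
        X = (3.0 * grid)[None, :]
        out = savgol(X, grid, window=9, polyorder=3, deriv=1)
        np.testing.assert_allclose(out[0][4:-4], 3.0, atol=1e-8)

    @pytest.mark.parametrize("spacing", [1.0, 2.0, 4.0])
    def test_second_derivative_of_quadratic(self, spacing):
        grid = np.arange(900.0, 900.0 + 50 * spacing, spacing)
        X = (grid**2)[None, :]
        out = savgol(X, grid, window=9, polyorder=3, deriv=2)
        np.testing.assert_allclose(out[0][4:-4], 2.0, atol=1e-8)

    def test_smoothing_reproduces_polynomial(self):
        grid = np.arange(0.0, 60.0, 2.0)
        X = (0.5 * grid**2 - 3 * grid + 1)[None, :]
        out = savgol(X, grid, window=9, polyorder=2, deriv=0)
        np.testing.assert_allclose(out[0][4:-4], X[0][4:-4], atol=1e-10)

    def test_non_uniform_grid_rejected(self):
        grid = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 17.0, 18.0, 19.0, 20.0])
        with pytest.raises(NumericError, match="uniform"):
            savgol(np.ones((1, len(grid))), grid, window=9, polyorder=3, deriv=1)

    @pytest.mark.parametrize(
        "kw",
        [
            {"window": 8},  # even window
            {"window": 9, "polyorder": 9},  # polyorder >= window
            {"window": 9, "polyorder": 0, "deriv": 1},  # polyorder < deriv
            {"window": 99},  # window > n points
        ],
    )
    def test_bad_parameters_rejected(self, kw):
        grid = np.arange(0.0, 40.0, 2.0)
        with pytest.raises(ConfigError):
            savgol(np.ones((1, len(grid))), grid, **kw)


class TestSNV:
    def test_standardizes_rows(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], [-1, 0, 1], atol=1e-12)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        X = np.random.default_rng(seed).normal(size=(3, 25))
        np.testing.assert_allclose(snv(a * X + b), snv(X), atol=1e-8)

    def test_rows_have_zero_mean_unit_sample_sd(self, rng):
        out = snv(rng.normal(2.0, 0.3, size=(6, 40)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected_naming_sample(self):
        with pytest.raises(NumericError, match="s2"):
            snv(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]), sample_ids=["s1", "s2"])


class TestSelectRegions:
    def test_inclusive_window(self):
        grid = np.arange(600.0, 2101.0, 50.0)
        sub, subgrid = select_regions(np.tile(grid, (2, 1)), grid, [(2000.0, 650.0)])
        assert subgrid[0] == 650.0 and subgrid[-1] == 2000.0
        np.testing.assert_array_equal(sub[0], subgrid)

    def test_union_of_nested_intervals(self, rng):
        grid = np.arange(650.0, 2001.0, 7.0)
        X = rng.normal(size=(3, len(grid)))
        both, g_both = select_regions(X, grid, [(1500.0, 980.0), (1500.0, 900.0)])
        wide, g_wide = select_regions(X, grid, [(1500.0, 900.0)])
        np.testing.assert_array_equal(g_both, g_wide)
        np.testing.assert_array_equal(both, wide)

    def test_union_count_matches_brute_force(self, rng):
        for _ in range(20):
            grid = np.sort(rng.uniform(600, 2100, size=rng.integers(20, 80)))
            grid = np.unique(grid)
            regions = [
                tuple(sorted(rng.uniform(600, 2100, size=2), reverse=True))
                for _ in range(3)
            ]
            regions = [(h, l) for h, l in regions if ((grid >= l) & (grid <= h)).any()]
            if not regions:
                continue
            sub, subgrid = select_regions(np.tile(grid, (1, 1)), grid, regions)
            expected = sorted(
                {v for v in grid for h, l in regions if l <= v <= h}
            )
            np.testing.assert_allclose(subgrid, expected)

    def test_empty_region_rejected(self):
        grid = np.arange(650.0, 2001.0, 2.0)
        with pytest.raises(ConfigError):
            select_regions(np.ones((1, len(grid))), grid, [(500.0, 400.0)])


class TestRecipe:
    def _spectra_set(self, rng, n=4):
        grid = np.arange(650.0, 2001.0, 2.0)
        X = rng.normal(0.3, 0.05, size=(n, len(grid)))
        return SpectraSet(grid, X, tuple(f"s{i}" for i in range(n)))

    def test_empty_recipe_is_identity(self, rng):
        sset = self._spectra_set(rng)
        X, grid = apply_recipe(sset, PreprocessRecipe())
        np.testing.assert_array_equal(X, sset.matrix)
        np.testing.assert_array_equal(grid, sset.grid)

    def test_offset_twice_equals_once(self, rng):
        sset = self._spectra_set(rng)
        once, _ = apply_recipe(sset, PreprocessRecipe(steps=(("offset", {}),)))
        twice, _ = apply_recipe(
            sset, PreprocessRecipe(steps=(("offset", {}), ("offset", {})))
        )
        np.testing.assert_allclose(twice, once, atol=1e-15)

    def test_composition_matches_manual_steps(self, rng):
        sset = self._spectra_set(rng)
        recipe = PreprocessRecipe(
            steps=(
                ("savgol", {"window": 9, "polyorder": 3, "deriv": 1}),
                ("snv", {}),
                ("select_regions", {"regions": ((1500.0, 900.0),)}),
            ),
            drop_edges=False,
        )
        X, grid = apply_recipe(sset, recipe)
        manual = savgol(sset.matrix, sset.grid, 9, 3, 1)
        manual = snv(manual)
        manual, mgrid = select_regions(manual, sset.grid, [(1500.0, 900.0)])
        np.testing.assert_array_equal(X, manual)
        np.testing.assert_array_equal(grid, mgrid)

    def test_drop_edges_removes_half_window_columns(self, rng):
        sset = self._spectra_set(rng)
        recipe = PreprocessRecipe(
            steps=(("savgol", {"window": 9, "polyorder": 3, "deriv": 1}),),
            drop_edges=True,
        )
        X, grid = apply_recipe(sset, recipe)
        assert X.shape[1] == sset.matrix.shape[1] - 8
        assert grid[0] == sset.grid[4] and grid[-1] == sset.grid[-5]

    def test_pure_function_bit_identical(self, rng):
        sset = self._spectra_set(rng)
        recipe = PreprocessRecipe(
            steps=(
                ("offset", {}),
                ("savgol", {"window": 9, "polyorder": 3, "deriv": 1}),
                ("snv", {}),
            )
        )
        a, _ = apply_recipe(sset, recipe)
        b, _ = apply_recipe(sset, recipe)
        assert np.array_equal(a, b)

    def test_roundtrip_serialization(self):
        recipe = PreprocessRecipe(
            steps=(
                ("offset", {}),
                ("savgol", {"window": 9, "polyorder": 3, "deriv": 2}),
                ("select_regions", {"regions": ((2000.0, 650.0), (1500.0, 980.0))}),
            )
        )
        assert PreprocessRecipe.from_dict(recipe.to_dict()) == recipe

    @pytest.mark.parametrize(
        "steps",
        [
            (("mystery", {}),),
            (("select_regions", {"regions": ()}),),
            (("select_regions", {"regions": ((900.0, 1500.0),)}),),
            (("savgol", {"window": 4}),),
        ],
    )
    def test_invalid_recipes_rejected(self, steps):
        with pytest.raises(ConfigError):
            PreprocessRecipe(steps=steps)
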