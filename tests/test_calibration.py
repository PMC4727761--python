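"""SEP metrics, cross-validation, LV selection and the QC gate."""

import numpy as np
import pytest

from ftirquant.calibration import (
    QC_ESTIMATE,
    QC_QUANTIFY,
    SEPCurve,
    calibrate_analyte,
    correlation_r,
    cross_validate,
    qc_verdict,
    select_optimal_lv,
    sep,
    sep_percent,
    variance_explained,
)
from ftirquant.exceptions import DataError, NumericError
from ftirquant.pls_model import PLS1Regression
from ftirquant.preprocess import PreprocessRecipe


LINEAR_RECIPE = PreprocessRecipe(
    steps=(
        ("offset", {}),
        ("savgol", {"window": 9, "polyorder": 3, "deriv": 1}),
        ("select_regions", {"regions": ((1500.0, 900.0),)}),
    )
)


class TestSep:
    def test_perfect_predictions_give_zero(self):
        assert sep([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_errors(self):
        assert sep([0, 0, 0, 0], [1, -1, 1, -1]) == pytest.approx(1.0)

    def test_n_denominator(self):
        # errors 3 and 4 with n=2: sqrt(25/2)
        assert sep([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_scales_linearly(self, rng):
        y, yp = rng.normal(size=30), rng.normal(size=30)
        assert sep(5 * y, 5 * yp) == pytest.approx(5 * sep(y, yp))

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            sep([1.0], [1.0, 2.0])


class TestSepPercentAndQC:
    def test_definition(self):
        assert sep_percent(0.009, [0.05, 0.05]) == pytest.approx(18.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(NumericError):
            sep_percent(0.1, [0.0, 0.0])

    @pytest.mark.parametrize(
        "sp, verdict",
        [
            (13.54, QC_QUANTIFY),
            (18.51, QC_ESTIMATE),
            (0.0, QC_QUANTIFY),
            (14.999, QC_QUANTIFY),
            (15.0, QC_ESTIMATE),  # strict < 15 gate
        ],
    )
    def test_gate_boundary(self, sp, verdict):
        assert qc_verdict(sp) == verdict


class TestVarianceAndCorrelation:
    def test_variance_examples(self):
        assert variance_explained([1, 2, 3], [1, 2, 3]) == pytest.approx(100.0)
        assert variance_explained([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)
        assert variance_explained([1, 2, 3], [1, 2, 4]) == pytest.approx(50.0)

    def test_variance_constant_truth_rejected(self):
        with pytest.raises(NumericError):
            variance_explained([2, 2, 2], [1, 2, 3])

    def test_correlation_examples(self):
        y = np.array([1.0, 2.0, 3.0])
        assert correlation_r(y, y) == pytest.approx(1.0)
        assert correlation_r(y, -y + 10) == pytest.approx(-1.0)
        assert correlation_r(y, [1.0, 2.0, 4.0]) == pytest.approx(0.9820, abs=1e-3)

    def test_variance_equals_100_r2_for_ls_rescaling(self, rng):
        y = rng.normal(size=40)
        yp = y + rng.normal(scale=0.3, size=40)
        # least-squares fit of y on yp makes variance == 100 r^2
        a, b = np.polyfit(yp, y, 1)
        fitted = a * yp + b
        assert variance_explained(y, fitted) == pytest.approx(
            100 * correlation_r(y, fitted) ** 2, abs=1e-9
        )


class TestCrossValidate:
    def test_loo_matches_brute_force_refits(self, rng):
        X, y = rng.normal(size=(15, 8)), rng.normal(size=15)
        max_lv = 5
        curve = cross_validate(X, y, max_lv, scheme="loo")
        brute = np.empty((max_lv + 1, 15))
        for i in range(15):
            tr = np.delete(np.arange(15), i)
            for k in range(max_lv + 1):
                m = PLS1Regression(n_components=k).fit(X[tr], y[tr])
                brute[k, i] = m.predict(X[i][None, :])[0]
        assert np.array_equal(curve.predictions, brute)  # bit-level

    def test_max_lv_zero_gives_mean_model_curve(self, rng):
        X, y = rng.normal(size=(6, 4)), rng.normal(size=6)
        curve = cross_validate(X, y, 0)
        assert len(curve.sep) == 1
        # LOO mean-only predictions
        preds = np.array([np.delete(y, i).mean() for i in range(6)])
        assert curve.sep[0] == pytest.approx(sep(y, preds))

    def test_duplicated_samples_remain_finite(self, rng):
        X, y = rng.normal(size=(6, 5)), rng.normal(size=6)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        curve = cross_validate(X2, y2, 4)
        assert np.isfinite(curve.sep).all()

    def test_kfold_requires_seed_and_is_deterministic(self, rng):
        X, y = rng.normal(size=(20, 6)), rng.normal(size=20)
        with pytest.raises(NumericError):
            cross_validate(X, y, 3, scheme="kfold", k=5)
        a = cross_validate(X, y, 3, scheme="kfold", k=5, seed=7)
        b = cross_validate(X, y, 3, scheme="kfold", k=5, seed=7)
        np.testing.assert_array_equal(a.sep, b.sep)

    def test_max_lv_too_large_rejected(self, rng):
        X, y = rng.normal(size=(6, 10)), rng.normal(size=6)
        with pytest.raises(NumericError):
            cross_validate(X, y, 5)


class TestSelectOptimalLv:
    def test_argmin(self):
        curve = SEPCurve(np.arange(5), np.array([5.0, 3, 1, 2, 4]), "LOO")
        assert select_optimal_lv(curve) == 2

    def test_tie_breaks_toward_fewer(self):
        curve = SEPCurve(np.arange(3), np.array([3.0, 1.0, 1.0]), "LOO")
        assert select_optimal_lv(curve) == 1


class TestCalibrateAnalyte:
    def test_noiseless_design_recovers_rank_three(self, noiseless_set):
        spectra, reference = noiseless_set
        for analyte in ("daidzin", "genistin", "glycitin"):
            model, report = calibrate_analyte(
                spectra, reference, analyte, LINEAR_RECIPE, max_lv=6
            )
            assert report.n_lv == 3
            assert report.sep < 1e-6
            assert report.variance == pytest.approx(100.0, abs=1e-6)
            assert report.r == pytest.approx(1.0, abs=1e-8)
            assert report.qc == QC_QUANTIFY

    def test_equal_reference_values_rejected(self, noiseless_set):
        spectra, reference = noiseless_set
        flat = reference.data.copy()
        flat["genistin"] = 0.05
        flat["total"] = flat[["daidzin", "genistin", "glycitin"]].sum(axis=1)
        from ftirquant.spectra_io import ReferenceTable

        with pytest.raises(NumericError, match="variance"):
            calibrate_analyte(
                spectra,
                ReferenceTable(flat.reset_index(), source="SIMULATED"),
                "genistin",
                LINEAR_RECIPE,
            )

    def test_deterministic_reports(self, noiseless_set):
        spectra, reference = noiseless_set
        _, a = calibrate_analyte(spectra, reference, "total", LINEAR_RECIPE, max_lv=5)
        _, b = calibrate_analyte(spectra, reference, "total", LINEAR_RECIPE, max_lv=5)
        assert a.to_dict() == b.to_dict()

    def test_too_few_joined_samples_rejected(self, noiseless_set):
        spectra, reference = noiseless_set
        from ftirquant.spectra_io import SpectraSet

        small = SpectraSet(
            spectra.grid, spectra.matrix[:3], tuple(spectra.sample_ids[:3])
        )
        with pytest.raises(DataError, match=">= 5"):
            calibrate_analyte(small, reference, "total", LINEAR_RECIPE)
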