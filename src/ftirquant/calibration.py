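"""Model selection and quality metrics for PLS calibration.

The central accuracy statistic is the standard error of prediction

    SEP = sqrt( Σ (ŷᵢ − yᵢ)² / n )

computed on cross-validated (held-out) predictions, in the response's own
units (mg per 500 µl).  The denominator is n, not n−1; the convention is
pinned here so reported values are unambiguous.  A model is fit for
quantification when SEP is below 15 % of the mean of the property
(``QUANTIFY``); at or above that limit it may still serve for rough
estimation (``ESTIMATE_ONLY``).

:func:`cross_validate` traces SEP against the number of latent variables
(the classic under-/overfitting trade-off curve) and
:func:`select_optimal_lv` picks the smallest count attaining the minimal
SEP.  Explained variance (R²·100) and the Pearson correlation r are, by
default, computed on the cross-validated predictions rather than training
reconstructions — the honest figure for predictive use — with training
metrics available on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .exceptions import DataError, NumericError
from .pls_model import PLS1Regression
from .preprocess import PreprocessRecipe, apply_recipe
from .spectra_io import ReferenceTable, SpectraSet

QC_QUANTIFY = "QUANTIFY"
QC_ESTIMATE = "ESTIMATE_ONLY"
SEP_PERCENT_LIMIT = 15.0  # quantification gate: SEP must be under 15 % of mean(y)


# ---------------------------------------------------------------------------
# Metrics


def sep(y_true, y_pred) -> float:
    """Standard error of prediction: sqrt(mean squared error), units of y."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise DataError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise DataError("sep needs at least one value")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def sep_percent(sep_value: float, y_reference) -> float:
    """SEP as a percentage of the mean reference concentration."""
    mean = float(np.mean(np.asarray(y_reference, dtype=float)))
    if mean <= 0:
        raise NumericError(f"sep_percent undefined for mean(y)={mean:g} <= 0")
    return 100.0 * float(sep_value) / mean


def qc_verdict(sep_percent_value: float) -> str:
    """QUANTIFY iff SEP% is strictly under the 15 % limit."""
    return QC_QUANTIFY if sep_percent_value < SEP_PERCENT_LIMIT else QC_ESTIMATE


def variance_explained(y_true, y_pred) -> float:
    """Explained variance 100·(1 − SSres/SStot), i.e. R² × 100.

    Can be negative when predictions are worse than the mean.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise NumericError("variance_explained undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def correlation_r(y_true, y_pred) -> float:
    """Pearson correlation between reference and predicted values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise NumericError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class SEPCurve:
    """SEP as a function of the latent-variable count.

    ``predictions[k]`` holds the pooled held-out predictions with k latent
    variables, sample-aligned with the training y.
    """

    n_lv: np.ndarray
    sep: np.ndarray
    scheme: str
    predictions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if (np.asarray(self.sep) < 0).any():
            raise NumericError("SEP values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_lv": self.n_lv, "sep": self.sep})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _folds(n: int, scheme: str, k: int | None, seed: int | None):
    scheme = scheme.lower()
    if scheme == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)], "LOO"
    if scheme == "kfold":
        if k is None or seed is None:
            raise NumericError("k-fold cross-validation requires k and a seed")
        splitter = KFold(n_splits=int(k), shuffle=True, random_state=int(seed))
        return list(splitter.split(np.arange(n))), f"KFOLD(k={k}, seed={seed})"
    raise NumericError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X,
    y,
    max_lv: int,
    scheme: str = "loo",
    k: int | None = None,
    seed: int | None = None,
) -> SEPCurve:
    """SEP for every latent-variable count 0..max_lv.

    For each fold one NIPALS fit at ``max_lv`` provides the predictions at
    every smaller count (components are nested under deflation, so these
    are bit-identical to refitting at each count).  Held-out predictions
    are pooled over folds and SEP computed once per count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise NumericError("cross-validation needs at least 3 samples")
    if max_lv > min(n - 2, X.shape[1]):
        raise NumericError(
            f"max_lv={max_lv} exceeds min(n_samples-2, n_variables)="
            f"{min(n - 2, X.shape[1])}"
        )
    folds, label = _folds(n, scheme, k, seed)
    ks = np.arange(max_lv + 1)
    preds = np.empty((max_lv + 1, n))
    for train, test in folds:
        model = PLS1Regression(n_components=max_lv).fit(X[train], y[train])
        preds[:, test] = model.predict_with_components(X[test], ks)
    seps = np.array([sep(y, preds[i]) for i in ks])
    return SEPCurve(n_lv=ks, sep=seps, scheme=label, predictions=preds)


def select_optimal_lv(curve: SEPCurve) -> int:
    """Smallest LV count attaining the minimal SEP (ties favor fewer LVs,
    guarding against overfitting)."""
    seps = np.asarray(curve.sep)
    if seps.size == 0:
        raise NumericError("empty SEP curve")
    return int(np.asarray(curve.n_lv)[int(np.argmin(seps))])


# ---------------------------------------------------------------------------
# Full per-analyte calibration


@dataclass(frozen=True)
class CalibrationReport:
    """Quality summary for one analyte's calibrated model."""

    analyte: str
    n_lv: int
    sep: float
    sep_percent: float
    variance: float
    r: float
    qc: str
    curve: SEPCurve = field(repr=False, default=None)
    n_samples: int = 0
    training_variance: float | None = None
    training_r: float | None = None

    def to_dict(self) -> dict:
        d = {
            "analyte": self.analyte,
            "n_lv": int(self.n_lv),
            "sep_mg_per_500ul": float(self.sep),
            "sep_percent": float(self.sep_percent),
            "variance_percent": float(self.variance),
            "r": float(self.r),
            "qc": self.qc,
            "n_samples": int(self.n_samples),
        }
        if self.training_variance is not None:
            d["training_variance_percent"] = float(self.training_variance)
            d["training_r"] = float(self.training_r)
        return d


def calibrate_analyte(
    spectra_set: SpectraSet,
    reference: ReferenceTable,
    analyte: str,
    recipe: PreprocessRecipe,
    max_lv: int = 10,
    scheme: str = "loo",
    k: int | None = None,
    seed: int | None = None,
    training_metrics: bool = False,
) -> tuple[PLS1Regression, CalibrationReport]:
    """The full model-building loop for one analyte.

    Joins spectra with reference concentrations, applies the preprocessing
    recipe, traces the cross-validated SEP curve, picks the optimal LV
    count, refits on all samples, and reports SEP, SEP%, explained
    variance, r (all on cross-validated predictions) and the QC verdict.
    """
    common = [s for s in spectra_set.sample_ids if s in set(reference.sample_ids)]
    if len(common) < 5:
        raise DataError(
            f"only {len(common)} samples join spectra and reference; need >= 5"
        )
    idx = [spectra_set.sample_ids.index(s) for s in common]
    subset = SpectraSet(spectra_set.grid, spectra_set.matrix[idx], tuple(common))
    y = reference.concentrations(analyte).loc[list(common)].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise NumericError(f"{analyte}: reference concentrations have zero variance")

    X, subgrid = apply_recipe(subset, recipe)
    max_lv_eff = min(max_lv, len(common) - 2, X.shape[1])
    curve = cross_validate(X, y, max_lv_eff, scheme=scheme, k=k, seed=seed)
    n_lv = select_optimal_lv(curve)

    model = PLS1Regression(n_components=n_lv).fit(X, y)
    model.analyte_ = analyte
    model.grid_ = subgrid
    model.recipe_ = recipe

    y_cv = curve.predictions[n_lv]
    sep_val = float(curve.sep[n_lv])
    sp = sep_percent(sep_val, y)
    report = CalibrationReport(
        analyte=analyte,
        n_lv=n_lv,
        sep=sep_val,
        sep_percent=sp,
        variance=variance_explained(y, y_cv),
        r=correlation_r(y, y_cv),
        qc=qc_verdict(sp),
        curve=curve,
        n_samples=len(common),
        training_variance=(
            variance_explained(y, model.predict(X)) if training_metrics else None
        ),
        training_r=(correlation_r(y, model.predict(X)) if training_metrics else None),
    )
    return model, report
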