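"""From-scratch PLS1 (NIPALS) regression for spectral calibration.

Partial least squares with a single response projects the (mean-centered)
spectral matrix X onto latent variables chosen to maximize covariance with
the concentration vector y, then regresses y on those scores.  With one
response the NIPALS weight per component is closed-form (the normalized
covariance direction X'y), so fitting is exact and fully deterministic —
no random initialization and no iteration tolerance anywhere.

Columns are mean-centered but not variance-scaled: spectra share units
and SNV has already normalized the rows, so column autoscaling would only
inflate noise channels — the standard chemometric convention for spectral
PLS.

:class:`PLS1Regression` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``get_params``), so it composes with sklearn
pipelines and model selection; fitted state lives in trailing-underscore
attributes and can be persisted to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .exceptions import DataError, NumericError
from .preprocess import PreprocessRecipe

#: Components whose residual covariance ||X'y|| has collapsed below this
#: fraction of the first component's are frozen (the response is exhausted);
#: they would only amplify round-off noise.
_RANK_TOL = 1e-12


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Univariate-response partial least squares via NIPALS deflation.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent variables.  0 gives the intercept-only model
        (predicts the training mean).  Must not exceed
        ``min(n_samples - 1, n_features)``.

    Attributes
    ----------
    x_mean_ : ndarray (n_features,)
        Column means used for centering.
    y_mean_ : float
        Response mean (the model intercept).
    x_weights_ : ndarray (n_features, k)
        NIPALS weight vectors W, unit norm, one per component.
    x_loadings_ : ndarray (n_features, k)
        Loadings P from regressing X on each score.
    y_loadings_ : ndarray (k,)
        Regression of y on each score.
    coef_ : ndarray (n_features,)
        Regression vector b in centered variable space:
        ``ŷ = y_mean_ + (X - x_mean_) @ coef_``.
    n_components_ : int
        Components actually extracted (may be fewer than requested when
        the response is exactly exhausted, e.g. noiseless low-rank data).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise DataError("X must be 2-D (samples x variables)")
        n, p = X.shape
        if len(y) != n:
            raise DataError(f"X has {n} rows but y has {len(y)} values")
        if n < 2:
            raise NumericError("PLS1 needs at least 2 samples")
        a = int(self.n_components)
        if a < 0 or a > min(n - 1, p):
            raise NumericError(
                f"n_components={a} exceeds min(n_samples-1, n_features)="
                f"{min(n - 1, p)}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if a >= 1 and np.allclose(yc, 0.0):
            raise NumericError("y has zero variance; cannot fit latent variables")

        W = np.zeros((p, a))
        P = np.zeros((p, a))
        q = np.zeros(a)
        scores = np.zeros((n, a))
        Xd, yd = Xc.copy(), yc.copy()
        cov0 = None
        k = 0
        for _ in range(a):
            s = Xd.T @ yd
            norm = np.linalg.norm(s)
            if cov0 is None:
                cov0 = norm
            if norm <= _RANK_TOL * cov0 or norm == 0.0:
                break  # response exhausted: further components are round-off
            w = s / norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0.0:
                break
            pvec = Xd.T @ t / tt
            qk = float(yd @ t) / tt
            Xd -= np.outer(t, pvec)
            yd -= qk * t
            W[:, k], P[:, k], q[k] = w, pvec, qk
            scores[:, k] = t
            k += 1
        self.x_weights_ = W[:, :k]
        self.x_loadings_ = P[:, :k]
        self.y_loadings_ = q[:k]
        self.scores_ = scores[:, :k]
        self.n_components_ = k
        self.coef_ = self._coef_for(k)
        self.n_features_in_ = p
        return self

    def _coef_for(self, k: int) -> np.ndarray:
        """Regression vector using the first k extracted components.

        b = W_k (P_k' W_k)^{-1} q_k — identical to what a fresh fit with
        ``n_components=k`` produces, which makes incremental
        cross-validation over component counts exactly reproducible.
        """
        if k == 0:
            return np.zeros(self.x_mean_.shape[0])
        # contiguous copies: BLAS results must not depend on whether the
        # slice views a wider array (keeps incremental CV bit-identical to
        # refitting at each component count)
        Wk = np.ascontiguousarray(self.x_weights_[:, :k])
        Pk = np.ascontiguousarray(self.x_loadings_[:, :k])
        qk = np.ascontiguousarray(self.y_loadings_[:k])
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    # -- prediction -------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise NotFittedError("PLS1Regression is not fitted")

    def predict(self, X):
        """ŷ = y_mean + (X − x_mean)·b.

        Negative concentrations are returned as-is (clipping would bias
        error statistics); use :func:`below_zero_flags` to flag them.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"X has {X.shape[1]} columns but the model was fitted on "
                f"{self.n_features_in_}"
            )
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict_with_components(self, X, ks) -> np.ndarray:
        """Predictions for several component counts from one fit.

        Returns an array of shape ``(len(ks), n_samples)``; entry for k
        is bit-identical to ``PLS1Regression(k).fit(...).predict(X)``.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean_
        out = np.empty((len(ks), X.shape[0]))
        for i, k in enumerate(ks):
            k_eff = min(int(k), self.n_components_)
            out[i] = self.y_mean_ + Xc @ self._coef_for(k_eff)
        return out

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        d = {
            "n_components": int(self.n_components),
            "n_components_": int(self.n_components_),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
        }
        for attr in ("analyte_", "grid_", "recipe_"):
            if hasattr(self, attr):
                val = getattr(self, attr)
                if attr == "grid_":
                    val = np.asarray(val).tolist()
                elif attr == "recipe_":
                    val = val.to_dict()
                d[attr.rstrip("_")] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLS1Regression":
        model = cls(n_components=int(d["n_components"]))
        model.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        model.y_mean_ = float(d["y_mean"])
        model.x_weights_ = np.asarray(d["x_weights"], dtype=float).reshape(
            len(model.x_mean_), -1
        )
        model.x_loadings_ = np.asarray(d["x_loadings"], dtype=float).reshape(
            len(model.x_mean_), -1
        )
        model.y_loadings_ = np.asarray(d["y_loadings"], dtype=float).ravel()
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.n_components_ = int(d["n_components_"])
        model.n_features_in_ = len(model.x_mean_)
        if "analyte" in d:
            model.analyte_ = d["analyte"]
        if "grid" in d:
            model.grid_ = np.asarray(d["grid"], dtype=float)
        if "recipe" in d:
            model.recipe_ = PreprocessRecipe.from_dict(d["recipe"])
        return model

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "PLS1Regression":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Functional wrappers and diagnostics


def fit_pls1(X, y, n_lv: int) -> PLS1Regression:
    """Fit a mean-centered NIPALS PLS1 model with ``n_lv`` latent variables."""
    return PLS1Regression(n_components=n_lv).fit(X, y)


def predict(model: PLS1Regression, X_new) -> np.ndarray:
    return model.predict(X_new)


def below_zero_flags(predictions) -> np.ndarray:
    """Boolean mask of physically impossible (negative) concentration
    predictions; they are reported, not clipped."""
    return np.asarray(predictions, dtype=float) < 0


def regression_vector(model: PLS1Regression):
    """The regression vector b, annotated by wavenumber when available.

    Returns a pandas Series indexed by the design-column wavenumbers if the
    model stores its grid, otherwise the raw vector.
    """
    model._check_fitted()
    if hasattr(model, "grid_"):
        import pandas as pd

        return pd.Series(model.coef_, index=np.asarray(model.grid_), name="b")
    return model.coef_.copy()
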