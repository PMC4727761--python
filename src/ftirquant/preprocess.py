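"""Spectral preprocessing operators as composable sklearn-style transforms.

The chemometric corrections applied before PLS calibration:

* offset correction — subtract each spectrum's mean intensity from every
  point of that spectrum (a whole-spectrum baseline offset removal),
* linear baseline subtraction through user-chosen anchor wavenumbers (a
  documented, deterministic stand-in for interactive baseline tools),
* Savitzky-Golay smoothing / first / second derivatives over a sliding
  window (default 9 points, cubic), scaled to per-cm⁻¹ units,
* standard normal variate (SNV) — per-spectrum standardization that
  removes multiplicative scatter from particle-size / dispersion effects,
* wavenumber-region selection — restriction to informative windows such
  as 2000–650, 1500–980 or 1500–900 cm⁻¹.

Each operator is a stateless transformer with an sklearn ``fit`` /
``transform`` surface so recipes compose with sklearn pipelines; the
module-level functions (:func:`offset_correct`, :func:`savgol`, ...) are
thin wrappers.  A :class:`PreprocessRecipe` is the serializable list of
steps that a calibrated model stores so prediction replays exactly the
same transform chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DataError, NumericError
from .spectra_io import SpectraSet

KNOWN_OPS = ("offset", "baseline_linear", "savgol", "snv", "select_regions")


def _as_matrix(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise DataError("preprocessing input contains non-finite values")
    return X


class OffsetCorrector(TransformerMixin, BaseEstimator):
    """Subtract each row's mean intensity from every value of that row.

    Shifts every spectrum to mean zero, removing constant baseline offsets
    even when only a small spectral region is retained downstream.
    Idempotent and invariant to adding a per-row constant.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return X - X.mean(axis=1, keepdims=True)


class LinearBaseline(TransformerMixin, BaseEstimator):
    """Subtract a per-row piecewise-linear baseline through anchor points.

    Parameters
    ----------
    grid : array-like
        Wavenumber axis of the matrix columns, cm⁻¹ ascending.
    anchors : sequence of float
        ≥2 wavenumbers at which the baseline is pinned to the row's value;
        each anchor is snapped to the nearest grid point.  After the
        transform every row is exactly 0 at the anchors.
    """

    def __init__(self, grid=None, anchors=None):
        self.grid = grid
        self.anchors = anchors

    def fit(self, X, y=None):
        if self.grid is None or self.anchors is None:
            raise ConfigError("LinearBaseline requires grid and anchors")
        grid = np.asarray(self.grid, dtype=float)
        anchors = np.sort(np.asarray(self.anchors, dtype=float))
        if len(anchors) < 2:
            raise ConfigError("LinearBaseline needs at least 2 anchors")
        if anchors[0] < grid[0] - 1e-9 or anchors[-1] > grid[-1] + 1e-9:
            raise ConfigError(
                f"baseline anchors {anchors.tolist()} outside grid "
                f"[{grid[0]:g}, {grid[-1]:g}] cm-1"
            )
        self.anchor_idx_ = np.unique(np.abs(grid[None, :] - anchors[:, None]).argmin(axis=1))
        if len(self.anchor_idx_) < 2:
            raise ConfigError("anchors collapse onto fewer than 2 grid points")
        self.grid_ = grid
        return self

    def transform(self, X):
        X = _as_matrix(X)
        grid = self.grid_
        idx = self.anchor_idx_
        out = np.empty_like(X)
        for i, row in enumerate(X):
            base = np.interp(grid, grid[idx], row[idx])
            out[i] = row - base
        return out


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing or differentiation on a uniform grid.

    Local least-squares polynomial fits over a sliding ``window`` (odd,
    default 9 points); ``deriv`` ∈ {0, 1, 2} selects smoothing, first or
    second derivative.  Derivatives are scaled to physical units (per
    cm⁻¹) by the grid spacing.  Edge points are computed from asymmetric
    polynomial fits at the spectrum ends rather than truncated; the
    half-window of columns at each end is flagged in ``edge_mask_`` so a
    recipe can exclude edge artifacts from calibration without silently
    changing the matrix width.
    """

    def __init__(self, window: int = 9, polyorder: int = 3, deriv: int = 0, grid=None):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.grid = grid

    def _validate(self, n_cols: int) -> float:
        if self.deriv not in (0, 1, 2):
            raise ConfigError("savgol deriv must be 0, 1 or 2")
        if self.window % 2 != 1 or self.window < 3:
            raise ConfigError("savgol window must be an odd integer >= 3")
        if not (self.deriv <= self.polyorder < self.window):
            raise ConfigError(
                "savgol polyorder must satisfy deriv <= polyorder < window"
            )
        if self.window > n_cols:
            raise ConfigError(
                f"savgol window {self.window} exceeds the {n_cols} grid points"
            )
        if self.grid is None:
            raise ConfigError("SavitzkyGolay requires the wavenumber grid")
        grid = np.asarray(self.grid, dtype=float)
        spacing = np.diff(grid)
        if len(spacing) == 0:
            raise ConfigError("grid must have at least 2 points")
        if not np.allclose(spacing, spacing[0], rtol=1e-9, atol=0.0):
            raise NumericError(
                "savgol requires a uniform wavenumber grid; align the spectra "
                "to a regular grid first"
            )
        return float(spacing[0])

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.spacing_ = self._validate(X.shape[1])
        half = self.window // 2
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[:half] = True
        mask[X.shape[1] - half :] = True
        self.edge_mask_ = mask
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if not hasattr(self, "spacing_"):
            self.fit(X)
        return scipy.signal.savgol_filter(
            X,
            window_length=self.window,
            polyorder=self.polyorder,
            deriv=self.deriv,
            delta=self.spacing_,
            axis=1,
            mode="interp",
        )


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-row standardization.

    Subtracts each row's mean and divides by its sample standard deviation
    (n−1 denominator), removing multiplicative scatter differences between
    spectra.  Constant rows cannot be scaled and raise an error.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X, sample_ids: Sequence[str] | None = None):
        X = _as_matrix(X)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        flat = np.flatnonzero(sd.ravel() == 0)
        if flat.size:
            names = (
                [sample_ids[i] for i in flat] if sample_ids is not None else flat.tolist()
            )
            raise NumericError(
                f"SNV undefined for constant spectra (zero spread): {names}"
            )
        return (X - X.mean(axis=1, keepdims=True)) / sd


class RegionSelector(TransformerMixin, BaseEstimator):
    """Keep the grid columns falling in a union of wavenumber windows.

    ``regions`` is a list of ``(high, low)`` cm⁻¹ intervals (IR convention:
    high wavenumber first); bounds are inclusive, overlapping regions are
    unioned, and original column order is preserved.  Fitted attributes:
    ``mask_`` (boolean column keep-mask) and ``subgrid_``.
    """

    def __init__(self, grid=None, regions=None):
        self.grid = grid
        self.regions = regions

    def fit(self, X=None, y=None):
        if self.grid is None or not self.regions:
            raise ConfigError("RegionSelector requires grid and >=1 region")
        grid = np.asarray(self.grid, dtype=float)
        mask = np.zeros(len(grid), dtype=bool)
        for region in self.regions:
            high, low = float(region[0]), float(region[1])
            if high <= low:
                raise ConfigError(f"region must be (high, low) with high > low: {region}")
            hit = (grid >= low) & (grid <= high)
            if not hit.any():
                raise ConfigError(
                    f"region ({high:g}, {low:g}) cm-1 contains no grid points "
                    f"(grid spans [{grid[0]:g}, {grid[-1]:g}])"
                )
            mask |= hit
        self.mask_ = mask
        self.subgrid_ = grid[mask]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if not hasattr(self, "mask_"):
            self.fit(X)
        if X.shape[1] != len(self.mask_):
            raise DataError(
                f"matrix has {X.shape[1]} columns but the grid has {len(self.mask_)}"
            )
        return X[:, self.mask_]


# ---------------------------------------------------------------------------
# Functional wrappers (the classic chemometric operator names)


def offset_correct(matrix) -> np.ndarray:
    """Row-wise mean subtraction (whole-spectrum offset correction)."""
    return OffsetCorrector().fit_transform(matrix)


def baseline_linear(matrix, grid, anchors) -> np.ndarray:
    """Subtract a per-row linear/piecewise-linear baseline through anchors."""
    return LinearBaseline(grid=grid, anchors=anchors).fit_transform(matrix)


def savgol(matrix, grid, window: int = 9, polyorder: int = 3, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay filter/derivative scaled per cm⁻¹ (see class docs)."""
    return SavitzkyGolay(window=window, polyorder=polyorder, deriv=deriv, grid=grid).fit_transform(matrix)


def snv(matrix, sample_ids=None) -> np.ndarray:
    """Standard normal variate row standardization (sample SD, n−1)."""
    return SNV().fit(matrix).transform(matrix, sample_ids=sample_ids)


def select_regions(matrix, grid, regions) -> tuple[np.ndarray, np.ndarray]:
    """Return (submatrix, subgrid) for the union of (high, low) windows."""
    sel = RegionSelector(grid=grid, regions=regions).fit(matrix)
    return sel.transform(matrix), sel.subgrid_


# ---------------------------------------------------------------------------
# Recipes


@dataclass(frozen=True)
class PreprocessRecipe:
    """Ordered, serializable preprocessing chain.

    ``steps`` is a list of ``(op, params)`` pairs with op in
    ``{"offset", "baseline_linear", "savgol", "snv", "select_regions"}``.
    The default chemometric order is baseline/offset → derivative → SNV →
    region selection: derivatives amplify noise that SNV then renormalizes,
    and cutting regions last keeps window edges clean.  ``drop_edges``
    removes Savitzky-Golay edge-flagged columns from the final design
    matrix (they are fitted with asymmetric windows and can carry
    artifacts).
    """

    steps: tuple = ()
    drop_edges: bool = True

    def __post_init__(self):
        norm = []
        for step in self.steps:
            if isinstance(step, str):
                op, params = step, {}
            else:
                op, params = step[0], dict(step[1] or {})
            if op not in KNOWN_OPS:
                raise ConfigError(f"unknown preprocessing op {op!r}; known: {KNOWN_OPS}")
            if op == "savgol":
                window = int(params.get("window", 9))
                polyorder = int(params.get("polyorder", 3))
                deriv = int(params.get("deriv", 0))
                if deriv not in (0, 1, 2):
                    raise ConfigError("savgol deriv must be 0, 1 or 2")
                if window % 2 != 1:
                    raise ConfigError("savgol window must be odd")
                if not (deriv <= polyorder < window):
                    raise ConfigError("need deriv <= polyorder < window")
                params = {"window": window, "polyorder": polyorder, "deriv": deriv}
            if op == "select_regions":
                regions = params.get("regions")
                if not regions:
                    raise ConfigError("select_regions step needs non-empty regions")
                regions = tuple((float(h), float(l)) for h, l in regions)
                for h, l in regions:
                    if h <= l:
                        raise ConfigError(f"region must satisfy high > low: ({h}, {l})")
                params = {"regions": regions}
            if op == "baseline_linear":
                anchors = params.get("anchors")
                if anchors is not None:
                    params = {"anchors": tuple(float(a) for a in anchors)}
            norm.append((op, params))
        object.__setattr__(self, "steps", tuple(norm))

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"op": op, **{k: (list(map(list, v)) if k == "regions" else list(v) if isinstance(v, tuple) else v) for k, v in params.items()}}
                for op, params in self.steps
            ],
            "drop_edges": self.drop_edges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        steps = []
        for step in d.get("steps", []):
            step = dict(step)
            op = step.pop("op")
            steps.append((op, step))
        return cls(steps=tuple(steps), drop_edges=bool(d.get("drop_edges", True)))


def apply_recipe(spectra_set: SpectraSet, recipe: PreprocessRecipe) -> tuple[np.ndarray, np.ndarray]:
    """Apply a preprocessing recipe to a SpectraSet.

    Steps run in listed order on the absorbance matrix; the wavenumber
    grid and a Savitzky-Golay edge mask are carried along so that region
    selection subsets them consistently.  Returns ``(matrix, subgrid)``
    — the design matrix handed to PLS and the wavenumbers of its columns.
    Pure function: identical inputs give bit-identical outputs.
    """
    X = spectra_set.matrix.copy()
    grid = spectra_set.grid.copy()
    edge = np.zeros(len(grid), dtype=bool)
    for op, params in recipe.steps:
        if op == "offset":
            X = offset_correct(X)
        elif op == "baseline_linear":
            anchors = params.get("anchors") or (grid[0], grid[-1])
            X = baseline_linear(X, grid, anchors)
        elif op == "savgol":
            sg = SavitzkyGolay(grid=grid, **params).fit(X)
            X = sg.transform(X)
            edge |= sg.edge_mask_
        elif op == "snv":
            X = snv(X, sample_ids=spectra_set.sample_ids)
        elif op == "select_regions":
            sel = RegionSelector(grid=grid, regions=params["regions"]).fit(X)
            X = sel.transform(X)
            grid = sel.subgrid_
            edge = edge[sel.mask_]
    if recipe.drop_edges and edge.any():
        X = X[:, ~edge]
        grid = grid[~edge]
    return X, grid


#: Recipe used throughout the worked examples: offset correction, 9-point
#: cubic Savitzky-Golay first derivative, SNV, and the 1500-900 cm-1 window.
def default_recipe(regions=((1500.0, 900.0),), deriv: int = 1) -> PreprocessRecipe:
    return PreprocessRecipe(
        steps=(
            ("offset", {}),
            ("savgol", {"window": 9, "polyorder": 3, "deriv": deriv}),
            ("snv", {}),
            ("select_regions", {"regions": tuple(regions)}),
        )
    )
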