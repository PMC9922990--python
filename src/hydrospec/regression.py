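"""Multiple linear regression on selected bands, and the shared metrics.

Chemometrics convention: Rc/RMSEC are the Pearson correlation and
root-mean-square error between predicted and measured moisture on the
calibration set, Rp/RMSEP the same on the prediction set. RMSE carries the
units of the modelled response (dry-basis moisture %, or the unit interval
if the optional min-max response scaling is enabled upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr


def pearson_r(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ZeroVarianceError("correlation undefined: zero variance input")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(np.sqrt(np.mean((a - b) ** 2)))


class ZeroVarianceError(ValueError):
    """Pearson correlation requested on a constant vector."""


@dataclass
class FitMetrics:
    """Correlation/RMSE pair for one evaluation set. ``r_defined`` is False
    when either vector was constant (r is then NaN, never silently 0)."""

    r: float
    rmse: float
    set: str
    r_defined: bool = True


@dataclass
class LinearModel:
    """Ordinary-least-squares moisture model on a handful of selected
    frequency bands of one optical dimension."""

    intercept: float
    coefficients: np.ndarray
    selected_frequencies: np.ndarray
    dimension: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.selected_frequencies = np.asarray(self.selected_frequencies, dtype=float)
        if self.coefficients.size != self.selected_frequencies.size:
            raise ValueError("one coefficient per selected frequency required")
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise ValueError("model parameters must be finite")

    def predict(self, x_sel) -> np.ndarray:
        x_sel = np.atleast_2d(np.asarray(x_sel, dtype=float))
        return self.intercept + x_sel @ self.coefficients


def mlr_fit(x_sel, y, selected_frequencies=None, dimension: str = "") -> LinearModel:
    """Ordinary least squares with intercept.

    Requires more samples than parameters and a full-rank design; a
    rank-deficient design raises with the indices of the collinear columns
    (identified by pivoted QR).
    """
    x = np.atleast_2d(np.asarray(x_sel, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise ValueError("y length must match the number of rows")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        _, _, piv = qr(design, mode="economic", pivoting=True)
        # pivots beyond the numerical rank point at dependent columns
        bad = sorted(int(j) - 1 for j in piv[rank:] if j > 0)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    freqs = (
        np.asarray(selected_frequencies, dtype=float)
        if selected_frequencies is not None
        else np.full(p, np.nan)
    )
    return LinearModel(float(beta[0]), beta[1:], freqs, dimension)


def evaluate(model: LinearModel, x_sel, y, set_tag: str) -> FitMetrics:
    """Rc/RMSEC or Rp/RMSEP for a fitted model on one evaluation set."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(x_sel)
    err = rmse(yhat, y)
    try:
        r = pearson_r(yhat, y)
        return FitMetrics(r, err, set_tag)
    except ZeroVarianceError:
        return FitMetrics(float("nan"), err, set_tag, r_defined=False)


def single_dimension_report(models: dict, features: dict, splits: dict, y) -> pd.DataFrame:
    """Four-by-three table (Rc, RMSEC, Rp, RMSEP) x (power, absorbance,
    transmittance) mirroring the single-dimension model comparison.

    ``features[dim]`` is the full n x p_selected matrix for that dimension
    and ``splits[dim]`` the corresponding calibration/prediction split.
    """
    y = np.asarray(y, dtype=float)
    cols: dict[str, list] = {}
    for dim, model in models.items():
        name = getattr(dim, "value", str(dim))
        x = features[dim]
        split = splits[dim]
        try:
            cal = evaluate(model, x[split.calibration_indices], y[split.calibration_indices], "calibration")
            pred = evaluate(model, x[split.prediction_indices], y[split.prediction_indices], "prediction")
            cols[name] = [cal.r, cal.rmse, pred.r, pred.rmse]
        except Exception:
            cols[name] = [np.nan] * 4
    return pd.DataFrame(cols, index=["Rc", "RMSEC", "Rp", "RMSEP"])


def minmax_scale_response(y):
    """Optional response scaling to [0, 1]; returns (scaled, inverse)."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("constant response cannot be min-max scaled")
    return (y - lo) / (hi - lo), lambda z: np.asarray(z) * (hi - lo) + lo
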