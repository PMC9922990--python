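"""Three-channel feature fusion: normalization, PCA at a 95 % cumulative
variance rule, and epsilon-SVR with an RBF kernel tuned by cross-validated
grid search.

Selected bands from the power, absorbance and transmittance channels are
concatenated column-wise (the channels live on incommensurate scales, so
each fused feature is z-scored with calibration statistics first), PCA
reduces the standardized block to the smallest component count whose
cumulative contribution reaches the threshold, and an epsilon-SVR with
Gaussian kernel ``K(u, v) = exp(-g * ||u - v||^2)`` maps the scores to
moisture. Every statistic — normalizer, loadings, SVR and its grid search
— is fit on the calibration set only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .regression import FitMetrics, ZeroVarianceError, pearson_r, rmse
from .spectra import Dimension, SpectraSet

logger = logging.getLogger(__name__)

#: Fixed channel order for fused blocks.
FUSION_ORDER = (Dimension.POWER, Dimension.ABSORBANCE, Dimension.TRANSMITTANCE)


@dataclass
class FusedFeatures:
    """Concatenated selected-band matrix with (channel, THz) column labels."""

    values: np.ndarray
    columns: list  # (dimension value, frequency THz) pairs

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("one label per fused column required")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("fused column labels must be unique (dimension, THz) pairs")


def fuse_features(bands: dict, spectra: dict) -> FusedFeatures:
    """Column-wise concatenation of each channel's selected bands, in the
    fixed order power, absorbance, transmittance.

    ``bands[dim]`` is a list of THz frequencies, resolved on that
    channel's grid by nearest-neighbour matching within half a grid step;
    a frequency off the grid raises naming it. The same frequency selected
    in two channels yields two distinct columns. An empty band list is
    tolerated with a warning.
    """
    blocks, labels = [], []
    for dim in FUSION_ORDER:
        if dim not in bands:
            continue
        freqs = np.atleast_1d(np.asarray(bands[dim], dtype=float))
        sset: SpectraSet = spectra[dim]
        if freqs.size == 0:
            warnings.warn(f"empty band list for {dim.value}", stacklevel=2)
            continue
        idx = sset.grid.match_frequencies(freqs)
        blocks.append(sset.values[:, idx])
        labels.extend((dim.value, float(sset.grid.points[j])) for j in idx)
    if not blocks:
        raise ValueError("no bands to fuse")
    return FusedFeatures(np.hstack(blocks), labels)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Per-feature affine transform fit on calibration data only."""

    center: np.ndarray
    scale: np.ndarray
    method: str = "zscore"


def normalize_fit(x_cal, method: str = "zscore") -> Normalizer:
    """Fit a per-feature z-score (default) or min-max normalizer on the
    calibration matrix. Constant features are centred with scale 1."""
    x = np.atleast_2d(np.asarray(x_cal, dtype=float))
    if method == "zscore":
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
    elif method == "minmax":
        center = x.min(axis=0)
        scale = x.max(axis=0) - x.min(axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    scale = np.where(scale == 0, 1.0, scale)
    return Normalizer(center, scale, method)


def normalize_apply(norm: Normalizer, x) -> np.ndarray:
    return (np.atleast_2d(np.asarray(x, dtype=float)) - norm.center) / norm.scale


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaReduction:
    """Calibration-fitted principal axes plus the retained-component rule."""

    mean: np.ndarray
    loadings: np.ndarray  # components x features
    contributions: np.ndarray  # descending variance fractions, sum 1
    cumulative: np.ndarray
    k: int
    threshold: float = 0.95


def select_components(contributions, threshold: float = 0.95):
    """Smallest k whose running contribution sum reaches the threshold.

    Returns ``(k, cumulative_at_k)``. The contributions must be
    non-negative and sum to at most 1 (within rounding); if even the full
    set falls short of the threshold there is no valid k.
    """
    c = np.asarray(contributions, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if np.any(c < 0):
        raise ValueError("contributions must be non-negative")
    if c.sum() > 1 + 1e-9:
        raise ValueError("contributions sum above 1")
    cum = np.cumsum(c)
    reached = cum >= threshold - 1e-12
    if not reached.any():
        raise ValueError(
            f"total contribution {cum[-1]:.4f} below threshold {threshold}"
        )
    k = int(np.argmax(reached)) + 1
    return k, float(cum[k - 1])


def pca_fit(x_cal_normed, threshold: float = 0.95) -> PcaReduction:
    """PCA of the normalized calibration block via SVD.

    Contributions are squared singular values over their sum; the retained
    count k follows :func:`select_components`.
    """
    x = np.atleast_2d(np.asarray(x_cal_normed, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least two calibration samples")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    contributions = s**2 / np.sum(s**2)
    cumulative = np.cumsum(contributions)
    k, _ = select_components(contributions, threshold)
    return PcaReduction(mean, vt, contributions, cumulative, k, threshold)


def pca_apply(red: PcaReduction, x_normed) -> np.ndarray:
    """Scores on the first k calibration-fitted axes."""
    x = np.atleast_2d(np.asarray(x_normed, dtype=float))
    return (x - red.mean) @ red.loadings[: red.k].T


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------


def default_svr_grid():
    """Log-spaced (g, C, p) candidates; the literature's winning triple
    (8.65, 2.41, 0.01) is included as an explicit grid point."""
    gammas = [2.0**e for e in range(-6, 7)]
    cs = [2.0**e for e in range(-4, 7)]
    losses = [0.001, 0.01, 0.1]
    grid = [(g, c, p) for g in gammas for c in cs for p in losses]
    grid.append((8.65, 2.41, 0.01))
    return grid


@dataclass
class SvrConfig:
    """RBF-SVR hyperparameters: kernel width g, penalty C, epsilon-loss
    width p (on the standardized response), the candidate grid, and the
    cross-validation folds used to pick among them."""

    grid: list = field(default_factory=default_svr_grid)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("grid must be non-empty")
        for g, c, p in self.grid:
            if g <= 0 or c <= 0 or p < 0:
                raise ValueError(f"invalid SVR triple (g={g}, C={c}, p={p})")


@dataclass
class SvrModel:
    """Fitted epsilon-SVR with the response standardization it was trained
    under (coefficients live on the z-scored response scale)."""

    svr: SVR
    y_mean: float
    y_scale: float
    params: tuple  # (g, C, p)

    def predict(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.svr.predict(z) * self.y_scale + self.y_mean


def _fit_single(z, y_std, g, c, p) -> SVR:
    svr = SVR(kernel="rbf", gamma=g, C=c, epsilon=p)
    svr.fit(z, y_std)
    return svr


def svr_fit(z_cal, y_cal, config: SvrConfig = SvrConfig()):
    """Cross-validated grid search over (g, C, p), refit of the winner.

    The selection metric is the cross-validated calibration correlation
    (Rc of pooled out-of-fold predictions); ties break toward smaller C,
    then smaller g. The response is z-scored with calibration statistics
    before fitting so the epsilon widths are on a comparable scale.

    Returns ``(SvrModel, search_table)``; the table carries each triple's
    cross-validated Rc/RMSE and refit calibration Rc.
    """
    z = np.atleast_2d(np.asarray(z_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    if config.cv_folds > z.shape[0]:
        raise ValueError("more CV folds than calibration samples")
    y_mean, y_scale = float(y.mean()), float(y.std())
    if y_scale == 0:
        raise ValueError("constant calibration response")
    y_std = (y - y_mean) / y_scale

    if len(config.grid) == 1:
        g, c, p = config.grid[0]
        model = SvrModel(_fit_single(z, y_std, g, c, p), y_mean, y_scale, (g, c, p))
        table = pd.DataFrame(
            [{"g": g, "C": c, "p": p, "cv_rc": np.nan, "cv_rmse": np.nan,
              "refit_rc": _safe_r(model.predict(z), y), "error": ""}]
        )
        return model, table

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(z))
    rows = []
    failures = []
    for g, c, p in config.grid:
        try:
            yhat = np.empty_like(y_std)
            for train, test in folds:
                svr = _fit_single(z[train], y_std[train], g, c, p)
                yhat[test] = svr.predict(z[test])
            cv_rc = _safe_r(yhat, y_std)
            cv_rmse = rmse(yhat, y_std) * y_scale
            rows.append({"g": g, "C": c, "p": p, "cv_rc": cv_rc,
                         "cv_rmse": cv_rmse, "error": ""})
        except Exception as exc:
            failures.append(((g, c, p), str(exc)))
            rows.append({"g": g, "C": c, "p": p, "cv_rc": np.nan,
                         "cv_rmse": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["cv_rc"])
    if ok.empty:
        raise RuntimeError(f"every SVR grid cell failed: {failures}")
    ok = ok.sort_values(["cv_rc", "C", "g"], ascending=[False, True, True], kind="stable")
    g, c, p = (float(ok.iloc[0]["g"]), float(ok.iloc[0]["C"]), float(ok.iloc[0]["p"]))
    model = SvrModel(_fit_single(z, y_std, g, c, p), y_mean, y_scale, (g, c, p))
    table["refit_rc"] = np.nan
    table.loc[ok.index[0], "refit_rc"] = _safe_r(model.predict(z), y)
    return model, table


def _safe_r(a, b) -> float:
    try:
        return pearson_r(a, b)
    except ZeroVarianceError:
        return float("nan")


# ---------------------------------------------------------------------------
# Full fusion pipeline
# ---------------------------------------------------------------------------


@dataclass
class FusionPipeline:
    """Calibration-fitted normalize -> PCA -> SVR chain."""

    normalizer: Normalizer
    pca: PcaReduction
    svr: SvrModel
    columns: list
    search_table: pd.DataFrame | None = None

    def transform(self, x) -> np.ndarray:
        return pca_apply(self.pca, normalize_apply(self.normalizer, x))

    def predict(self, x) -> np.ndarray:
        return self.svr.predict(self.transform(x))


def fusion_fit(
    fused: FusedFeatures,
    y,
    calibration_indices,
    pca_threshold: float = 0.95,
    svr_config: SvrConfig = SvrConfig(),
    norm_method: str = "zscore",
) -> FusionPipeline:
    """Fit the full fused pipeline on the calibration rows only."""
    y = np.asarray(y, dtype=float)
    cal = np.asarray(calibration_indices, dtype=int)
    x_cal = fused.values[cal]
    norm = normalize_fit(x_cal, norm_method)
    red = pca_fit(normalize_apply(norm, x_cal), pca_threshold)
    z_cal = pca_apply(red, normalize_apply(norm, x_cal))
    svr, table = svr_fit(z_cal, y[cal], svr_config)
    return FusionPipeline(norm, red, svr, list(fused.columns), table)


def fusion_evaluate(pipeline: FusionPipeline, fused: FusedFeatures, split, y):
    """Rc/RMSEC and Rp/RMSEP of the fused pipeline, plus the per-sample
    (measured, predicted) scatter table."""
    y = np.asarray(y, dtype=float)
    out = {}
    scatter = []
    for tag, idx in (
        ("calibration", split.calibration_indices),
        ("prediction", split.prediction_indices),
    ):
        yhat = pipeline.predict(fused.values[idx])
        try:
            r = pearson_r(yhat, y[idx])
            out[tag] = FitMetrics(r, rmse(yhat, y[idx]), tag)
        except ZeroVarianceError:
            out[tag] = FitMetrics(float("nan"), rmse(yhat, y[idx]), tag, r_defined=False)
        scatter.extend(
            {"set": tag, "index": int(i), "measured": float(y[i]), "predicted": float(p)}
            for i, p in zip(idx, yhat)
        )
    return out["calibration"], out["prediction"], pd.DataFrame(scatter)
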