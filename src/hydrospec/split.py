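"""Deterministic calibration/prediction partitioning: Kennard-Stone and
SPXY (sample-set partitioning based on joint x-y distances).

Both algorithms run the same max-min recursion: seed with the pair at
maximal distance, then repeatedly add the sample whose minimum distance to
the already-selected set is largest. SPXY replaces the Euclidean predictor
distance by the sum of predictor- and response-space distances, each
normalised by its maximum, so the calibration set also spans the response.
All ties break toward the lowest sample index — the partition is fully
deterministic without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


@dataclass
class SplitResult:
    """Calibration/prediction index partition."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    method: str
    n_total: int
    calibration_ids: list = field(default_factory=list)
    prediction_ids: list = field(default_factory=list)

    @property
    def ratio(self) -> float:
        return len(self.calibration_indices) / self.n_total

    def with_ids(self, sample_ids) -> "SplitResult":
        ids = list(sample_ids)
        self.calibration_ids = [ids[i] for i in self.calibration_indices]
        self.prediction_ids = [ids[i] for i in self.prediction_indices]
        return self


def n_cal_from_ratio(n: int, ratio: float = 0.75) -> int:
    """Calibration-set size from the ratio, round-half-up (80 x 0.75 = 60)."""
    return int(np.floor(n * ratio + 0.5))


def _maxmin_select(d: np.ndarray, n_cal: int) -> np.ndarray:
    """Kennard-Stone max-min recursion on a precomputed distance matrix.

    Ties break toward the lowest index; on an all-zero matrix the seed pair
    is (0, 1) and subsequent picks are the lowest unselected indices.
    """
    n = d.shape[0]
    # seed: pair at maximal distance, lexicographically first among ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = int(np.argmax(flat))  # argmax returns the first maximum
    selected = [int(iu[0][best]), int(iu[1][best])]
    mask = np.zeros(n, dtype=bool)
    mask[selected] = True
    mind = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        mind_masked = np.where(mask, -np.inf, mind)
        pick = int(np.argmax(mind_masked))
        selected.append(pick)
        mask[pick] = True
        mind = np.minimum(mind, d[pick])
    return np.asarray(selected, dtype=int)


def _finish(selected: np.ndarray, n: int, method: str) -> SplitResult:
    pred = np.setdiff1d(np.arange(n), selected)
    return SplitResult(selected, pred, method, n)


def ks_split(x, n_cal: int) -> SplitResult:
    """Kennard-Stone split on Euclidean distances between predictor rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if not 2 <= n_cal <= n - 1:
        raise ValueError(f"n_cal must be in [2, {n - 1}], got {n_cal}")
    d = squareform(pdist(x, metric="euclidean"))
    return _finish(_maxmin_select(d, n_cal), n, "KS")


def spxy_split(x, y, n_cal: int) -> SplitResult:
    """SPXY split on the joint distance
    d(i,j) = dx(i,j)/max dx + |y_i - y_j|/max dy.

    If exactly one of the two maxima is zero its term is dropped (the split
    degenerates to KS on the other space); both zero means every sample is
    identical and no informative split exists.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.size != n:
        raise ValueError("y length must match the number of rows of x")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if not 2 <= n_cal <= n - 1:
        raise ValueError(f"n_cal must be in [2, {n - 1}], got {n_cal}")
    dx = squareform(pdist(x, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise ValueError("all samples identical in both x and y; cannot split")
    d = np.zeros_like(dx)
    if mx > 0:
        d += dx / mx
    if my > 0:
        d += dy / my
    return _finish(_maxmin_select(d, n_cal), n, "SPXY")


def default_calibration_fit(x_cal, y_cal) -> tuple[float, float]:
    """Full-band PLS calibration fit returning (Rc, RMSEC); used where a
    report needs a quick per-dimension model on all 264 bands."""
    from sklearn.cross_decomposition import PLSRegression

    from .regression import pearson_r, rmse

    x_cal = np.asarray(x_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    ncomp = min(10, x_cal.shape[0] - 1, x_cal.shape[1])
    pls = PLSRegression(n_components=ncomp, scale=True)
    pls.fit(x_cal, y_cal)
    yhat = pls.predict(x_cal).ravel()
    return pearson_r(yhat, y_cal), rmse(yhat, y_cal)


def compare_split_methods(
    spectra: dict,
    y,
    downstream_fit=default_calibration_fit,
    ratio: float = 0.75,
) -> pd.DataFrame:
    """Per (dimension x method) calibration fit after KS and SPXY splits.

    Returns a six-row table (three dimensions x two methods) of Rc and
    RMSEC; per-cell failures are recorded in an ``error`` column while the
    remaining cells are still computed.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for dim, sset in spectra.items():
        n_cal = n_cal_from_ratio(sset.n_samples, ratio)
        for method, splitter in (
            ("KS", lambda X: ks_split(X, n_cal)),
            ("SPXY", lambda X: spxy_split(X, y, n_cal)),
        ):
            row = {"dimension": getattr(dim, "value", str(dim)), "method": method}
            try:
                split = splitter(sset.values)
                rc, rmsec = downstream_fit(
                    sset.values[split.calibration_indices],
                    y[split.calibration_indices],
                )
                row.update({"rc": rc, "rmsec": rmsec, "error": ""})
            except Exception as exc:
                row.update({"rc": np.nan, "rmsec": np.nan, "error": str(exc)})
            rows.append(row)
    return pd.DataFrame(rows)
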