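"""Gravimetric moisture, replicate averaging and Savitzky-Golay smoothing.

Smoothing is applied across frequency within each spectrum (the standard
reading for spectra); window width is chosen by refitting a downstream
calibration model for each candidate width and keeping the width with the
highest calibration correlation, ties to the smaller window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import SpectraSet


def moisture_content(m1, m2):
    """Dry-basis moisture w = (m1 - m2) / m2 * 100 (%).

    ``m1`` is fresh mass and ``m2`` dry mass, both in grams. A fresh mass
    below the dry mass indicates an evaporation or weighing fault and is
    rejected rather than returned as negative moisture.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if np.any(m2 <= 0):
        raise ValueError("dry mass m2 must be positive")
    if np.any(m1 < m2):
        raise ValueError("fresh mass m1 below dry mass m2 (weighing fault)")
    w = (m1 - m2) / m2 * 100.0
    return float(w) if w.ndim == 0 else w


def average_replicates(scans) -> np.ndarray:
    """Columnwise mean of k replicate scans (k x n_freq)."""
    try:
        arr = np.asarray(scans, dtype=float)
    except ValueError as exc:
        raise ValueError("replicate scans have unequal lengths") from exc
    if arr.ndim != 2 or arr.dtype == object:
        raise ValueError("scans must form a k x n_freq matrix")
    if arr.shape[0] < 1:
        raise ValueError("need at least one scan")
    return arr.mean(axis=0)


@dataclass(frozen=True)
class SgConfig:
    """Savitzky-Golay settings: odd window width in points and polynomial
    degree (degree 2 is the usual chemometrics default)."""

    window: int = 5
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.polyorder >= self.window:
            raise ValueError("window must exceed polyorder")


def sg_smooth(spectrum, config: SgConfig = SgConfig()) -> np.ndarray:
    """Savitzky-Golay smoothing of one spectrum.

    Interior points get the centred least-squares polynomial fit; near the
    edges the local polynomial is evaluated at the off-centre positions
    (``mode="interp"``), so the output keeps the full length and the band
    edges at 0.5 and 1.5 THz — where informative bands often sit — are not
    discarded.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectrum must be a 1-D vector")
    if x.size < config.window:
        raise ValueError(
            f"spectrum length {x.size} shorter than window {config.window}"
        )
    return savgol_filter(x, config.window, config.polyorder, mode="interp")


def sg_smooth_set(spectra: SpectraSet, config: SgConfig = SgConfig()) -> SpectraSet:
    """Row-wise smoothing of a whole spectra table.

    Smoothing can push values marginally outside a dimension's physical
    range (e.g. transmittance above 1); values are clipped back so the
    container invariants keep holding.
    """
    smoothed = savgol_filter(
        spectra.values, config.window, config.polyorder, axis=1, mode="interp"
    )
    if spectra.dimension.value == "transmittance":
        smoothed = np.clip(smoothed, np.nextafter(0.0, 1.0), 1.0)
    else:
        smoothed = np.maximum(smoothed, 0.0)
    return SpectraSet(spectra.dimension, spectra.grid, smoothed, list(spectra.sample_ids))


def default_downstream_fit(spectra: SpectraSet, y) -> tuple[float, float]:
    """Calibration-set fit used by the window-selection harness: SPXY split
    at 3:1 followed by a partial-least-squares calibration model (full-band
    ordinary least squares would be singular at 60 samples x 264 bands).

    Returns (Rc, RMSEC).
    """
    from .regression import pearson_r, rmse
    from .split import n_cal_from_ratio, spxy_split
    from sklearn.cross_decomposition import PLSRegression

    y = np.asarray(y, dtype=float)
    n_cal = n_cal_from_ratio(spectra.n_samples, 0.75)
    split = spxy_split(spectra.values, y, n_cal)
    xc = spectra.values[split.calibration_indices]
    yc = y[split.calibration_indices]
    ncomp = min(10, xc.shape[0] - 1, xc.shape[1])
    pls = PLSRegression(n_components=ncomp, scale=True)
    pls.fit(xc, yc)
    yhat = pls.predict(xc).ravel()
    return pearson_r(yhat, yc), rmse(yhat, yc)


def select_sg_window(
    spectra: SpectraSet,
    y,
    candidates=(5, 7, 9, 11),
    downstream=default_downstream_fit,
    polyorder: int = 2,
):
    """Window-width study: smooth with each candidate width, run the
    downstream calibration fit, tabulate Rc/RMSE and return the width with
    the highest Rc (ties broken toward the smaller window).

    Returns ``(chosen_window, report)`` where ``report`` has one row per
    candidate (window, rc, rmse, error).
    """
    rows = []
    for w in candidates:
        cfg = SgConfig(window=int(w), polyorder=polyorder)
        try:
            rc, err = downstream(sg_smooth_set(spectra, cfg), y)
            rows.append({"window": int(w), "rc": rc, "rmse": err, "error": ""})
        except Exception as exc:  # keep other candidates alive
            rows.append(
                {"window": int(w), "rc": np.nan, "rmse": np.nan, "error": str(exc)}
            )
    report = pd.DataFrame(rows)
    ok = report.dropna(subset=["rc"])
    if ok.empty:
        raise RuntimeError("every candidate window failed the downstream fit")
    # candidates within 1e-9 of the best Rc count as tied (float jitter on
    # noiseless data); the smallest tied window wins
    tied = ok[ok["rc"] >= ok["rc"].max() - 1e-9]
    return int(tied["window"].min()), report
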