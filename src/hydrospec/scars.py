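"""Stability competitive adaptive re-weighted sampling (SCARS).

SCARS selects moisture-informative frequency bands by iterating, for a
fixed number of sampling runs:

1. score every currently retained variable by its *stability*
   ``s_j = |mean_b(coef_jb)| / (sd_b(coef_jb) + eps)`` — the regression
   coefficient's mean over Monte-Carlo subsamples of the calibration set
   divided by its spread, so variables whose influence is both large and
   consistent score high;
2. *forced selection*: keep only the top ``ceil(r_i * p)`` variables by
   stability, where the retention ratio ``r_i`` follows an exponentially
   decreasing function (EDF) from 1 down to 2/p across the runs;
3. *adaptive re-weighted sampling*: draw that many variables with
   probability proportional to stability, with replacement, and retain the
   distinct draws — injecting competition among mid-ranked variables;
4. record the K-fold cross-validated RMSE (RMSECV) of the inner regressor
   on the sampled subset.

The forced (EDF-sized) set is what survives into the next run, so the
candidate-pool size follows the EDF schedule exactly; each run's sampled
subset is what gets scored. The run with the smallest RMSECV wins (ties
to the earlier run) and its sampled variable set is the selected band
list. The inner regressor is partial
least squares: at the first runs the retained-variable count exceeds the
calibration-sample count, where ordinary least squares is singular. The
prediction set is never touched during selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .spectra import FrequencyGrid

logger = logging.getLogger(__name__)


@dataclass
class ScarsConfig:
    """SCARS tuning constants.

    ``n_runs`` is the number of sampling cycles (50, at which the
    selection stabilises); ``subsample_fraction``/``n_subsamples`` control
    the Monte-Carlo stability estimate; ``cv_folds`` the RMSECV folds;
    ``n_latent`` caps the inner PLS latent variables.
    """

    n_runs: int = 50
    subsample_fraction: float = 0.8
    n_subsamples: int = 30
    cv_folds: int = 5
    n_latent: int = 10
    stability_epsilon: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ScarsResult:
    """Per-run trajectory plus the winning subset."""

    retained_sets: list  # per-run arrays of retained variable indices
    forced_counts: np.ndarray  # per-run EDF-scheduled counts (post forced selection)
    rmsecv: np.ndarray
    best_run: int  # 0-based index into the run arrays
    selected_indices: np.ndarray
    selected_frequencies: np.ndarray
    stability_trace: list = field(default_factory=list)

    @property
    def n_runs_completed(self) -> int:
        return len(self.retained_sets)


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing retention ratio for run ``i`` (1-based).

    Calibrated through the two boundary conditions r_1 = 1 and
    r_N = 2/p: ``r_i = a * exp(-k * i)`` with ``k = ln(p/2)/(N-1)`` and
    ``a = e^k``.
    """
    if p < 2:
        raise ValueError("need at least two variables")
    if not 1 <= i <= n_runs:
        raise ValueError(f"run index {i} outside [1, {n_runs}]")
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(np.exp(k) * np.exp(-k * i))


def _pls_coefficients(x, y, n_latent: int, rank: int | None = None) -> np.ndarray:
    # components are capped at the design rank: asking NIPALS for more
    # than rank(X) components on collinear data degenerates the deflation
    # and produces astronomically unstable coefficients
    if rank is None:
        rank = int(np.linalg.matrix_rank(x))
    ncomp = max(1, min(n_latent, x.shape[0] - 1, x.shape[1], rank))
    pls = PLSRegression(n_components=ncomp, scale=True)
    pls.fit(x, y)
    return np.asarray(pls.coef_).ravel()


def stability(x_cal, y_cal, config: ScarsConfig, rng) -> np.ndarray:
    """Stability score per retained variable.

    Draws ``n_subsamples`` subsamples of ``ceil(subsample_fraction * n)``
    calibration rows without replacement, fits the inner regressor on
    each, and scores each variable by |mean| / (sd + eps) of its
    coefficient across the draws. Subsamples with constant response are
    redrawn (at most 10x the requested draws in total).
    """
    x = np.atleast_2d(np.asarray(x_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two retained variables")
    m = int(np.ceil(config.subsample_fraction * n))
    rank = int(np.linalg.matrix_rank(x))
    coefs = np.empty((config.n_subsamples, p))
    attempts = 0
    b = 0
    while b < config.n_subsamples:
        if attempts >= 10 * config.n_subsamples:
            raise RuntimeError("could not draw enough non-degenerate subsamples")
        attempts += 1
        idx = rng.choice(n, size=m, replace=False)
        if np.std(y[idx]) == 0:
            continue
        coefs[b] = _pls_coefficients(x[idx], y[idx], config.n_latent, rank=rank)
        b += 1
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0)
    return np.abs(mean) / (sd + config.stability_epsilon)


def _rmsecv(x, y, config: ScarsConfig, fold_seed: int) -> float:
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=fold_seed)
    rank = int(np.linalg.matrix_rank(x))
    yhat = np.empty_like(y)
    for train, test in kf.split(x):
        ncomp = max(1, min(config.n_latent, len(train) - 1, x.shape[1], rank))
        pls = PLSRegression(n_components=ncomp, scale=True)
        pls.fit(x[train], y[train])
        yhat[test] = pls.predict(x[test]).ravel()
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def scars_select(
    x_cal,
    y_cal,
    grid: FrequencyGrid,
    config: ScarsConfig = ScarsConfig(),
    rng=None,
) -> ScarsResult:
    """Run the full SCARS loop on the calibration set.

    Deterministic given ``config.seed`` (or a caller-supplied generator).
    Stops early if fewer than two variables remain.
    """
    x = np.atleast_2d(np.asarray(x_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = x.shape
    if p != len(grid):
        raise ValueError("column count must equal the grid length")
    if p < 2:
        raise ValueError("need at least two initial variables")
    if n < config.cv_folds:
        raise ValueError("fewer calibration samples than CV folds")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))

    # `pool` is the set stability is computed on; the forced (EDF-sized)
    # pool is carried between runs, while each run's deduplicated ARS draw
    # is what the RMSECV is recorded on and what the winner reports. The
    # dedup subset is *not* carried forward — otherwise the ~40 % shrink
    # per draw would compound and the pool would collapse long before the
    # EDF reaches its floor of 2 variables.
    pool = np.arange(p)
    retained_sets: list[np.ndarray] = []
    forced_counts: list[int] = []
    rmsecv: list[float] = []
    stab_trace: list[np.ndarray] = []

    for i in range(1, config.n_runs + 1):
        if pool.size < 2:
            logger.info("SCARS stopped early at run %d (<2 variables left)", i)
            break
        s = stability(x[:, pool], y, config, rng)
        stab_trace.append(s)

        # forced selection: top ceil(r_i * p) variables by stability
        n_keep = min(int(np.ceil(edf_ratio(i, config.n_runs, p) * p)), pool.size)
        order = np.argsort(-s, kind="stable")  # ties keep lower index first
        keep = np.sort(order[:n_keep])
        forced, s_forced = pool[keep], s[keep]
        forced_counts.append(n_keep)

        # adaptive re-weighted sampling among the forced survivors
        if s_forced.sum() > 0:
            prob = s_forced / s_forced.sum()
        else:
            prob = np.full(forced.size, 1.0 / forced.size)
        draws = rng.choice(forced.size, size=n_keep, replace=True, p=prob)
        subset = forced[np.unique(draws)]
        retained_sets.append(subset.copy())
        pool = forced

        if subset.size < 2:
            rmsecv.append(np.inf)
            logger.info("SCARS degenerate subset at run %d", i)
            continue
        rmsecv.append(_rmsecv(x[:, subset], y, config, fold_seed))

    rmsecv_arr = np.asarray(rmsecv)
    best = int(np.argmin(rmsecv_arr))  # first minimum wins ties
    sel = np.sort(retained_sets[best])
    return ScarsResult(
        retained_sets=retained_sets,
        forced_counts=np.asarray(forced_counts),
        rmsecv=rmsecv_arr,
        best_run=best,
        selected_indices=sel,
        selected_frequencies=grid.points[sel],
        stability_trace=stab_trace,
    )


def scars_select_repeated(
    x_cal, y_cal, grid, config: ScarsConfig = ScarsConfig(), n_repeats: int = 1
) -> ScarsResult:
    """Repeat the whole SCARS procedure and keep the repetition with the
    smallest minimum RMSECV (ties to the earlier repetition)."""
    rng = np.random.default_rng(config.seed)
    best: ScarsResult | None = None
    for _ in range(n_repeats):
        sub = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        res = scars_select(x_cal, y_cal, grid, config, rng=sub)
        if best is None or res.rmsecv[res.best_run] < best.rmsecv[best.best_run]:
            best = res
    return best


def selection_report(results: dict, grid: FrequencyGrid) -> pd.DataFrame:
    """One row per optical dimension: winning run (1-based), selected-band
    count, minimum RMSECV, and the ascending band list at 2-decimal THz.
    Degenerate (early-stopped, empty) selections are flagged."""
    rows = []
    for dim, res in results.items():
        name = getattr(dim, "value", str(dim))
        if res.selected_indices.size == 0 or not np.isfinite(res.rmsecv[res.best_run]):
            rows.append(
                {
                    "model": name,
                    "times": res.best_run + 1,
                    "select": 0,
                    "min_rmsecv": np.nan,
                    "frequency_points_thz": "",
                    "degenerate": True,
                }
            )
            continue
        freqs = np.sort(res.selected_frequencies)
        rows.append(
            {
                "model": name,
                "times": res.best_run + 1,
                "select": int(res.selected_indices.size),
                "min_rmsecv": float(res.rmsecv[res.best_run]),
                "frequency_points_thz": ", ".join(f"{f:.2f}" for f in freqs),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
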