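"""End-to-end analysis: simulate -> smooth -> split -> select bands ->
per-channel MLR -> fused PCA+SVR, with a reproducibility manifest.

One global seed drives every stochastic stage through spawned
sub-sequences, so two runs of the same configuration produce identical
manifests (content hashes included).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fusion import (
    FusionPipeline,
    SvrConfig,
    fuse_features,
    fusion_evaluate,
    fusion_fit,
)
from .preprocess import SgConfig, sg_smooth_set
from .regression import mlr_fit, single_dimension_report
from .scars import ScarsConfig, ScarsResult, scars_select, selection_report
from .spectra import Dimension, write_labels, write_spectra
from .split import compare_split_methods, ks_split, n_cal_from_ratio, spxy_split
from .synth import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

_DIMS = (Dimension.POWER, Dimension.ABSORBANCE, Dimension.TRANSMITTANCE)


@dataclass
class PipelineConfig:
    """Configuration for a full run. ``seed`` is mandatory: it reseeds the
    simulator, the band selector and the SVR search."""

    seed: int
    sim: SimConfig = field(default_factory=SimConfig)
    sg: SgConfig = field(default_factory=SgConfig)
    split_method: str = "spxy"
    split_ratio: float = 0.75
    scars: ScarsConfig = field(default_factory=ScarsConfig)
    svr: SvrConfig = field(default_factory=SvrConfig)
    pca_threshold: float = 0.95
    # cap on the selected-band count of the winning SCARS run so the
    # downstream OLS stays overdetermined (see best_feasible_run)
    max_mlr_bands: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed is mandatory")
        if self.split_method not in ("ks", "spxy"):
            raise ValueError("split_method must be 'ks' or 'spxy'")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")


def best_feasible_run(result: ScarsResult, max_vars: int):
    """Winning SCARS run restricted to sets small enough for a determined
    ordinary-least-squares fit: argmin RMSECV over runs with at most
    ``max_vars`` retained variables (ties to the earlier run)."""
    sizes = np.array([len(s) for s in result.retained_sets])
    feasible = np.flatnonzero((sizes <= max_vars) & (sizes >= 1) & np.isfinite(result.rmsecv))
    if feasible.size == 0:
        raise RuntimeError(f"no SCARS run retained <= {max_vars} variables")
    best = int(feasible[np.argmin(result.rmsecv[feasible])])
    return best, np.sort(result.retained_sets[best])


def _split(method, x, y, n_cal):
    return spxy_split(x, y, n_cal) if method == "spxy" else ks_split(x, n_cal)


def _df_records(df: pd.DataFrame):
    return json.loads(df.to_json(orient="records", double_precision=12))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(obj):
    if dataclasses.is_dataclass(obj):
        out = {}
        for f_ in dataclasses.fields(obj):
            out[f_.name] = _config_dict(getattr(obj, f_.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "points"):  # FrequencyGrid
        return {"start": obj.start, "stop": obj.stop, "step": obj.step, "n": len(obj)}
    if isinstance(obj, (list, tuple)):
        return [_config_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the whole chain and return the manifest dictionary.

    Stage order: simulate the dataset; Savitzky-Golay smooth each channel;
    compare KS/SPXY splits per channel; per channel, split, run SCARS on
    the calibration set only and fit MLR on the winning bands; fuse the
    three band lists, split the fused block, and fit the normalize ->
    PCA -> RBF-SVR pipeline. The manifest records the configuration, all
    report tables, and content hashes of any files written.
    """
    ss = np.random.SeedSequence(config.seed)
    sim_seed, scars_seed, svr_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )

    # 1. simulate
    sim_cfg = replace(config.sim, seed=sim_seed)
    spectra, labels = simulate_dataset(sim_cfg)
    y = labels["moisture_pct"].to_numpy()

    # 2. smooth
    smoothed = {d: sg_smooth_set(spectra[d], config.sg) for d in _DIMS}

    # 3. split-method comparison (calibration-fit table)
    split_table = compare_split_methods(smoothed, y, ratio=config.split_ratio)

    # 4. per-channel band selection + MLR
    n = labels.shape[0]
    n_cal = n_cal_from_ratio(n, config.split_ratio)
    max_bands = config.max_mlr_bands if config.max_mlr_bands is not None else n_cal // 2
    scars_results: dict = {}
    models: dict = {}
    features: dict = {}
    splits: dict = {}
    bands: dict = {}
    for j, dim in enumerate(_DIMS):
        sset = smoothed[dim]
        split = _split(config.split_method, sset.values, y, n_cal)
        splits[dim] = split.with_ids(sset.sample_ids)
        cal = split.calibration_indices
        res = scars_select(
            sset.values[cal],
            y[cal],
            sset.grid,
            replace(config.scars, seed=scars_seed + j),
        )
        best, sel = best_feasible_run(res, max_bands)
        res.best_run = best
        res.selected_indices = sel
        res.selected_frequencies = sset.grid.points[sel]
        scars_results[dim] = res
        bands[dim] = sset.grid.points[sel]
        features[dim] = sset.values[:, sel]
        models[dim] = mlr_fit(
            features[dim][cal], y[cal], bands[dim], dimension=dim.value
        )

    bands_table = selection_report(scars_results, config.sim.grid)
    single_table = single_dimension_report(models, features, splits, y)

    # 5. fusion on the concatenated selected features
    fused = fuse_features(bands, smoothed)
    fusion_split = _split(config.split_method, fused.values, y, n_cal)
    pipeline = fusion_fit(
        fused,
        y,
        fusion_split.calibration_indices,
        pca_threshold=config.pca_threshold,
        svr_config=replace(config.svr, seed=svr_seed),
    )
    cal_m, pred_m, scatter = fusion_evaluate(pipeline, fused, fusion_split, y)

    manifest = {
        "package": "hydrospec",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "tables": {
            "split_comparison": _df_records(split_table),
            "band_selection": _df_records(bands_table),
            "single_dimension": {
                "index": list(single_table.index),
                "columns": {c: [round(float(v), 12) for v in single_table[c]]
                            for c in single_table.columns},
            },
            "pca": {
                "contributions": [round(float(c), 12) for c in pipeline.pca.contributions],
                "cumulative": [round(float(c), 12) for c in pipeline.pca.cumulative],
                "k": pipeline.pca.k,
            },
            "svr": {
                "params": {"g": pipeline.svr.params[0], "C": pipeline.svr.params[1],
                           "p": pipeline.svr.params[2]},
            },
            "fusion_metrics": {
                "Rc": round(cal_m.r, 12), "RMSEC": round(cal_m.rmse, 12),
                "Rp": round(pred_m.r, 12), "RMSEP": round(pred_m.rmse, 12),
            },
        },
        "files": {},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for dim in _DIMS:
            write_spectra(spectra[dim], out / f"{dim.value}.csv")
        write_labels(labels, out / "labels.csv")
        scatter.to_csv(out / "scatter.csv", index=False, float_format="%.12g")
        metrics = pd.DataFrame(
            {
                "metric": ["Rc", "RMSEC", "Rp", "RMSEP"],
                "fusion": [cal_m.r, cal_m.rmse, pred_m.r, pred_m.rmse],
                **{d.value: list(single_table[d.value]) for d in _DIMS},
            }
        )
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.12g")
        for p in sorted(out.glob("*.csv")):
            manifest["files"][p.name] = _hash_file(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest
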