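"""Synthetic THz leaf-spectra generator.

The study design being emulated: tomato plants grown under four irrigation
levels (20/40/60/80 % of a standard dose), twenty leaves sampled per level
(80 samples), each leaf scanned at ten points and the scans averaged, with
spectra collected over 0.5-1.5 THz at a 0.0038 THz sampling interval.

The generative model is deliberately simple but reproduces the sign
structure a water-stress experiment shows in this band:

* absorbance rises with frequency and with leaf moisture
  (``A*(f) = a0(f) + beta(f) * w`` with ``beta > 0`` increasing in ``f``),
* transmittance ``T = 10**(-A)`` therefore falls with both,
* detected power is an affine gain on the background reference that grows
  with moisture, so better-watered leaves sit higher — including above the
  background, as transmission measurements on fresh leaves often do. A
  ``physical_power`` switch instead derives power as ``reference * T`` for
  users wanting strictly self-consistent channels.

Replicate-scan noise is i.i.d. Gaussian per frequency point, averaged over
scans exactly as the instrument averages its sampling points. On top of
it, each leaf carries structural nuisance that no amount of scan averaging
removes: a random baseline offset and tilt in absorbance (leaf thickness
and scattering vary from leaf to leaf) and a random gain error in the
power channel. These terms carry no moisture information, lie in the same
affine-in-frequency space as the moisture signal (so a single channel
cannot simply regress them away), and are independent between the
absorbance and power channels — which is precisely why fusing channels
predicts moisture better than any single channel, as it does on real leaf
data.

A second mode, ``planted_bands``, concentrates the entire moisture signal
on a known handful of frequencies, switches the leaf-level nuisance off
(all non-planted variables become exchangeable noise) and so provides an
exact ground-truth support for scoring band-selection algorithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import (
    Dimension,
    FrequencyGrid,
    ReferenceSpectrum,
    SpectraSet,
    default_grid,
)

logger = logging.getLogger(__name__)

#: Grid indices carrying signal in planted-band mode (6 of 264, spread
#: across the window).
DEFAULT_PLANTED_INDICES = (20, 60, 100, 150, 200, 245)


@dataclass
class SimConfig:
    """Study-design constants plus generative-model coefficients.

    Moisture is dry-basis percent, ``w = (m1 - m2)/m2 * 100``. Per-level
    moisture means rise with the irrigation fraction; the defaults give
    clearly separated but overlapping levels, as no measured summary
    statistics exist to calibrate against.
    """

    n_levels: int = 4
    irrigation_fractions: tuple = (0.2, 0.4, 0.6, 0.8)
    leaves_per_level: int = 20
    scans_per_leaf: int = 10
    grid: FrequencyGrid = field(default_factory=default_grid)
    moisture_means: tuple = (120.0, 180.0, 240.0, 300.0)
    moisture_sd: float = 15.0
    # absorbance baseline a0(f) = a0_intercept + a0_slope * f  (f in THz)
    baseline_absorbance: tuple = (0.1, 0.2)
    # moisture coefficient beta(f) = b_intercept + b_slope * f, per % moisture
    water_coefficient: tuple = (0.002, 0.004)
    scan_noise_sd: float = 0.02
    # per-leaf structural nuisance: absorbance offset u ~ N(0, leaf_offset_sd)
    # and tilt v ~ N(0, leaf_tilt_sd) added as u + v * f; power gain error
    # ~ N(0, power_gain_sd). Moisture-free, hence the per-channel accuracy
    # ceiling.
    leaf_offset_sd: float = 0.12
    leaf_tilt_sd: float = 0.12
    power_gain_sd: float = 0.15
    # power gain: power = reference(f) * (c0 + c1 * w / 100)
    power_gain: tuple = (1.0, 0.5)
    planted_bands: tuple | None = None  # THz frequencies; None = smooth beta(f)
    planted_beta: float = 0.004  # per % moisture at each planted frequency
    physical_power: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.irrigation_fractions) != self.n_levels:
            raise ValueError("irrigation_fractions length must equal n_levels")
        if len(self.moisture_means) != self.n_levels:
            raise ValueError("moisture_means length must equal n_levels")
        if np.any(np.diff(self.moisture_means) <= 0):
            raise ValueError("moisture_means must increase with irrigation")
        b0, b1 = self.water_coefficient
        beta = b0 + b1 * self.grid.points
        if self.planted_bands is None and (np.any(beta <= 0) or b1 <= 0):
            raise ValueError("beta(f) must be positive and increasing in f")
        if self.power_gain[1] <= 0:
            raise ValueError("power gain slope c1 must be positive")

    def beta(self) -> np.ndarray:
        """Per-frequency moisture coefficient (absorbance per % moisture)."""
        if self.planted_bands is not None:
            beta = np.zeros(len(self.grid))
            beta[self.grid.match_frequencies(self.planted_bands)] = self.planted_beta
            return beta
        b0, b1 = self.water_coefficient
        return b0 + b1 * self.grid.points

    def a0(self) -> np.ndarray:
        i, s = self.baseline_absorbance
        return i + s * self.grid.points


def planted_config(seed: int = 0, **overrides) -> SimConfig:
    """Planted-band configuration: moisture signal only at 6 known
    frequencies; every other variable is exchangeable noise (the leaf-level
    structured nuisance is switched off so the non-planted columns are
    i.i.d.)."""
    grid = overrides.pop("grid", default_grid())
    bands = tuple(grid.points[list(DEFAULT_PLANTED_INDICES)])
    overrides.setdefault("leaf_offset_sd", 0.0)
    overrides.setdefault("leaf_tilt_sd", 0.0)
    overrides.setdefault("power_gain_sd", 0.0)
    return SimConfig(grid=grid, planted_bands=bands, seed=seed, **overrides)


def reference_power(grid: FrequencyGrid) -> ReferenceSpectrum:
    """Background power: smoothly decaying with frequency, strictly positive."""
    p = 10.0 * np.exp(-1.5 * (grid.points - grid.start))
    return ReferenceSpectrum(grid, p)


@dataclass
class MoistureRecord:
    """Gravimetric moisture of one leaf: fresh mass m1, dry mass m2, and
    dry-basis moisture w = (m1 - m2)/m2 * 100 (%), held exactly."""

    sample_id: str
    stress_level: int
    m1: float
    m2: float
    w: float

    def __post_init__(self) -> None:
        if not (self.m1 >= self.m2 > 0):
            raise ValueError("need m1 >= m2 > 0")


def draw_moisture(config: SimConfig, level: int, n: int, rng) -> list[MoistureRecord]:
    """Draw ``n`` leaves for one stress level.

    Moisture ~ Normal(level mean, moisture_sd) truncated below at 0; the
    dry mass is Uniform(0.5, 2.0) g and the fresh mass is back-computed so
    the gravimetric formula inverts exactly.
    """
    if not 0 <= level < config.n_levels:
        raise ValueError(f"level {level} out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    records = []
    for i in range(n):
        w = rng.normal(config.moisture_means[level], config.moisture_sd)
        w = max(w, 0.0)
        m2 = rng.uniform(0.5, 2.0)
        m1 = m2 * (1.0 + w / 100.0)
        records.append(
            MoistureRecord(f"L{level + 1}-{i + 1:02d}", level, m1, m2, w)
        )
    return records


def simulate_leaf(w: float, config: SimConfig, rng):
    """Simulate one leaf's averaged (power, absorbance, transmittance).

    Each of ``scans_per_leaf`` replicate scans adds independent Gaussian
    noise to the noiseless absorbance core before averaging; negative
    averaged absorbances are floored at 0 (count logged). Power carries
    its own replicate noise on the gain.
    """
    if w < 0:
        raise ValueError("moisture must be non-negative")
    n_f = len(config.grid)
    k = config.scans_per_leaf
    f = config.grid.points
    u = rng.normal(0.0, config.leaf_offset_sd) if config.leaf_offset_sd > 0 else 0.0
    v = rng.normal(0.0, config.leaf_tilt_sd) if config.leaf_tilt_sd > 0 else 0.0
    a_core = config.a0() + config.beta() * w + u + v * f
    noise = rng.normal(0.0, config.scan_noise_sd, size=(k, n_f)) if config.scan_noise_sd > 0 else np.zeros((k, n_f))
    a = (a_core + noise).mean(axis=0)
    n_neg = int(np.sum(a < 0))
    if n_neg:
        logger.warning("floored %d negative averaged absorbance values at 0", n_neg)
        a = np.maximum(a, 0.0)
    t = np.power(10.0, -a)

    ref = reference_power(config.grid).power
    if config.physical_power:
        p = ref * t
    else:
        c0, c1 = config.power_gain
        gain = c0 + c1 * w / 100.0
        if config.power_gain_sd > 0:
            gain = gain + rng.normal(0.0, config.power_gain_sd)
        gnoise = rng.normal(0.0, config.scan_noise_sd, size=(k, n_f)) if config.scan_noise_sd > 0 else np.zeros((k, n_f))
        p = (ref * (gain + gnoise)).mean(axis=0)
        p = np.maximum(p, 0.0)
    return p, a, t


def simulate_dataset(config: SimConfig):
    """Full study-scale dataset: one SpectraSet per optical dimension plus
    a labels table. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records: list[MoistureRecord] = []
    for level in range(config.n_levels):
        records.extend(draw_moisture(config, level, config.leaves_per_level, rng))

    n = len(records)
    power = np.empty((n, len(config.grid)))
    absorb = np.empty_like(power)
    transm = np.empty_like(power)
    for i, rec in enumerate(records):
        power[i], absorb[i], transm[i] = simulate_leaf(rec.w, config, rng)

    ids = [r.sample_id for r in records]
    spectra = {
        Dimension.POWER: SpectraSet(Dimension.POWER, config.grid, power, ids),
        Dimension.ABSORBANCE: SpectraSet(Dimension.ABSORBANCE, config.grid, absorb, ids),
        Dimension.TRANSMITTANCE: SpectraSet(
            Dimension.TRANSMITTANCE, config.grid, transm, ids
        ),
    }
    labels = pd.DataFrame(
        {
            "sample_id": ids,
            "stress_level": [r.stress_level for r in records],
            "m1_g": [r.m1 for r in records],
            "m2_g": [r.m2 for r in records],
            "moisture_pct": [r.w for r in records],
        }
    )
    return spectra, labels


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
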