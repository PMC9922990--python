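"""Core domain types for frequency-domain terahertz spectra.

A THz time-domain spectrometer reports, per leaf sample, three linked
"optical dimensions" on a common frequency axis: the detected power
spectrum, the transmittance (sample power over background power), and the
absorbance (decadic log-attenuation). This module holds the shared grid
and matrix containers plus the conversions between the three channels;
everything downstream (smoothing, splitting, band selection, modelling)
operates on these types.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Instrument sampling interval in THz.
DEFAULT_STEP = 0.0038
#: Analysis window used throughout: water-sensitive 0.5-1.5 THz band.
DEFAULT_START = 0.5
DEFAULT_STOP = 1.5


class Dimension(str, enum.Enum):
    """Optical dimension of a spectra table."""

    POWER = "power"
    ABSORBANCE = "absorbance"
    TRANSMITTANCE = "transmittance"


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform, strictly increasing frequency axis in THz."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("frequency grid needs at least two points")
        diffs = np.diff(pts)
        if np.any(diffs <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
            raise ValueError("frequency grid must be uniformly spaced")
        object.__setattr__(self, "points", pts)

    @property
    def start(self) -> float:
        return float(self.points[0])

    @property
    def stop(self) -> float:
        return float(self.points[-1])

    @property
    def step(self) -> float:
        return float(self.points[1] - self.points[0])

    def __len__(self) -> int:
        return self.points.size

    @classmethod
    def from_range(
        cls,
        start: float = DEFAULT_START,
        stop: float = DEFAULT_STOP,
        step: float = DEFAULT_STEP,
    ) -> "FrequencyGrid":
        """Grid covering ``[start, stop]`` at spacing ``step`` (last point
        never exceeds ``stop``)."""
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return cls(start + step * np.arange(n))

    def restrict_to_window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of points inside the closed window ``[lo, hi]``."""
        return (self.points >= lo - 1e-12) & (self.points <= hi + 1e-12)

    def match_frequencies(self, freqs) -> np.ndarray:
        """Indices of the grid points nearest each requested frequency.

        Matching tolerance is half a grid step; a frequency further than
        that from every grid point raises ``ValueError`` naming it.
        """
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        idx = np.empty(freqs.size, dtype=int)
        half = self.step / 2
        for k, f in enumerate(freqs):
            j = int(np.argmin(np.abs(self.points - f)))
            if abs(self.points[j] - f) > half + 1e-12:
                raise ValueError(
                    f"frequency {f:.4f} THz is not on the grid "
                    f"(nearest point {self.points[j]:.4f} THz, "
                    f"tolerance {half:.4f})"
                )
            idx[k] = j
        return idx


def default_grid() -> FrequencyGrid:
    """The 0.5-1.5 THz analysis grid at the instrument step (264 points)."""
    return FrequencyGrid.from_range()


@dataclass
class SpectraSet:
    """Samples x frequencies matrix for one optical dimension.

    ``values`` is always row-major sample x frequency. Transmittance lives
    in (0, 1]; absorbance and power are finite and non-negative.
    """

    dimension: Dimension
    grid: FrequencyGrid
    values: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample x frequency matrix")
        if self.values.shape[1] != len(self.grid):
            raise ValueError(
                f"{self.values.shape[1]} columns but grid has {len(self.grid)} points"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must equal the row count")
        self.dimension = Dimension(self.dimension)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.dimension.value} values must be finite")
        if self.dimension is Dimension.TRANSMITTANCE:
            if np.any(v <= 0) or np.any(v > 1 + 1e-12):
                raise ValueError("transmittance values must lie in (0, 1]")
        else:
            if np.any(v < 0):
                raise ValueError(f"{self.dimension.value} values must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def restrict_to_window(self, lo: float, hi: float) -> "SpectraSet":
        mask = self.grid.restrict_to_window(lo, hi)
        return SpectraSet(
            self.dimension,
            FrequencyGrid(self.grid.points[mask]),
            self.values[:, mask],
            list(self.sample_ids),
        )


@dataclass
class ReferenceSpectrum:
    """Background power collected with no sample in the beam path."""

    grid: FrequencyGrid
    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.grid),):
            raise ValueError("reference power must match the grid length")
        if np.any(self.power <= 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("reference power must be strictly positive and finite")


def power_to_transmittance(sample_power, reference_power) -> np.ndarray:
    """Elementwise sample/background power ratio, clipped into (0, 1].

    Real leaf measurements can exceed the background at some frequencies
    (detector drift, standing waves); such ratios are clipped to 1.0 with
    a logged warning rather than rejected, so absorbance stays >= 0.
    """
    s = np.asarray(sample_power, dtype=float)
    r = np.asarray(reference_power, dtype=float)
    if s.shape != r.shape:
        raise ValueError("sample and reference spectra are on different grids")
    if np.any(r <= 0):
        raise ValueError("reference power must be strictly positive")
    if np.any(s < 0):
        raise ValueError("sample power must be non-negative")
    t = s / r
    n_over = int(np.sum(t > 1.0))
    if n_over:
        logger.warning(
            "clipped %d transmittance values above 1 (sample power exceeded background)",
            n_over,
        )
        warnings.warn(
            f"{n_over} transmittance values above 1 clipped to 1.0", stacklevel=2
        )
        t = np.minimum(t, 1.0)
    return t


def transmittance_to_absorbance(t) -> np.ndarray:
    """Decadic absorbance A = -log10(T); inverts exactly via T = 10**(-A)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or np.any(t > 1 + 1e-12):
        raise ValueError("transmittance must lie in (0, 1]")
    return -np.log10(t)


def absorbance_to_transmittance(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be >= 0")
    return np.power(10.0, -a)


# ---------------------------------------------------------------------------
# CSV I/O. Wide format: sample_id, f_0.5000, f_0.5038, ... one file per
# optical dimension, frequencies in THz to 4 decimals.
# ---------------------------------------------------------------------------

_FREQ_PREFIX = "f_"


def _freq_header(f: float) -> str:
    return f"{_FREQ_PREFIX}{f:.4f}"


def write_spectra(spectra: SpectraSet, path) -> None:
    cols = [_freq_header(f) for f in spectra.grid.points]
    df = pd.DataFrame(spectra.values, columns=cols)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra(path, dimension) -> SpectraSet:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column must be 'sample_id'")
    freq_cols = list(df.columns[1:])
    freqs = []
    for c in freq_cols:
        name = c[len(_FREQ_PREFIX):] if c.startswith(_FREQ_PREFIX) else c
        try:
            freqs.append(float(name))
        except ValueError as exc:
            raise ValueError(f"column {c!r} is not parseable as a frequency") from exc
    freqs = np.asarray(freqs)
    diffs = np.diff(freqs)
    if np.any(diffs <= 0):
        bad = freq_cols[int(np.argmax(diffs <= 0)) + 1]
        raise ValueError(f"frequency columns not strictly increasing at {bad!r}")
    if not np.allclose(diffs, diffs[0], rtol=1e-4, atol=1e-12):
        bad = freq_cols[int(np.argmax(~np.isclose(diffs, diffs[0], rtol=1e-4))) + 1]
        raise ValueError(f"non-uniform frequency spacing at column {bad!r}")
    vals = df[freq_cols].to_numpy(dtype=float)
    if np.any(pd.isna(vals)):
        r, c = np.argwhere(pd.isna(vals))[0]
        raise ValueError(
            f"missing value at row {int(r)} (sample {df.iloc[int(r), 0]!r}), "
            f"column {freq_cols[int(c)]!r}"
        )
    return SpectraSet(dimension, FrequencyGrid(freqs), vals, list(df["sample_id"]))


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False, float_format="%.12g")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "stress_level", "m1_g", "m2_g", "moisture_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labels file missing columns: {sorted(missing)}")
    return df
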