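"""Observation model for two-band near-infrared skin imaging.

Under near-infrared illumination skin reflectance is modelled with two
absorbing components: hemoglobin (in the dermis, pulsating with blood
volume) and shade (illumination/geometry, affecting both wavelength bands
equally and assumed constant in time).  In density space — the negative
logarithm of normalized pixel values — the components combine linearly:

    v = F r + n

where ``v`` is the 2-vector of band densities per frame, ``r`` the
2-vector of (hemoglobin, shade) component values, ``F`` the 2x2 system
matrix lumping spectral transmittance, illumination radiance and sensor
sensitivity, and ``n`` additive sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "BandSeries",
    "DensitySeries",
    "PigmentSeries",
    "SystemMatrix",
    "to_density",
    "from_density",
    "forward_observe",
    "build_forward_matrix",
]

#: condition number above which a 2x2 system matrix is treated as singular
SINGULARITY_COND = 1e12


@dataclass(frozen=True)
class BandSeries:
    """Per-band mean pixel value over time at a fixed frame rate.

    ``values`` has shape (n_frames, 2): one column per selected wavelength
    band, in camera counts within [0, max_value].
    """

    values: np.ndarray
    frame_rate: float
    band_ids: tuple[str, str]
    max_value: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ConfigurationError(
                f"BandSeries requires exactly two bands, got shape {values.shape}"
            )
        if len(self.band_ids) != 2:
            raise ConfigurationError("exactly two band_ids required")
        if self.max_value <= 0:
            raise InputError(f"max_value must be positive, got {self.max_value}")
        if self.frame_rate <= 0:
            raise InputError(f"frame_rate must be positive, got {self.frame_rate}")
        if np.any(values < 0) or np.any(values > self.max_value):
            raise InputError("pixel values must lie in [0, max_value]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DensitySeries:
    """Two-component density observation v(t), one 2-vector per frame."""

    vectors: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        if vectors.ndim != 2 or vectors.shape[1] != 2:
            raise ConfigurationError(
                f"DensitySeries vectors must have shape (n, 2), got {vectors.shape}"
            )
        if not np.all(np.isfinite(vectors)):
            raise InputError("density vectors must be finite")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class PigmentSeries:
    """Two-component pigment estimate r(t) = (hemoglobin, shade) per frame.

    The hemoglobin column carries the raw pulse-wave signal.
    """

    vectors: np.ndarray
    frame_rate: float
    method_tag: str  # conventional | wiener | ground_truth

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        if vectors.ndim != 2 or vectors.shape[1] != 2:
            raise ConfigurationError(
                f"PigmentSeries vectors must have shape (n, 2), got {vectors.shape}"
            )
        if not np.all(np.isfinite(vectors)):
            raise InputError("pigment vectors must be finite")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")

    @property
    def hemoglobin(self) -> np.ndarray:
        return self.vectors[:, 0]

    @property
    def shade(self) -> np.ndarray:
        return self.vectors[:, 1]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class SystemMatrix:
    """2x2 matrix F mapping (hemoglobin, shade) to the two band densities."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.shape != (2, 2):
            raise ConfigurationError(f"SystemMatrix must be 2x2, got {entries.shape}")
        if not np.all(np.isfinite(entries)):
            raise InputError("SystemMatrix entries must be finite")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.entries))

    def require_invertible(self) -> None:
        cond = self.condition_number
        if not np.isfinite(cond) or cond > SINGULARITY_COND:
            raise ConfigurationError(
                f"system matrix is singular (condition number {cond:.3e})"
            )


def to_density(bands: BandSeries, floor_count: float = 1.0) -> DensitySeries:
    """Convert band pixel values to densities: -log(count / max_value).

    Counts are clipped to [floor_count, max_value] so zero counts map to a
    finite maximum density rather than infinity.
    """
    if floor_count < 1:
        raise InputError(f"floor_count must be >= 1, got {floor_count}")
    clipped = np.clip(bands.values, floor_count, bands.max_value)
    vectors = -np.log(clipped / bands.max_value)
    return DensitySeries(vectors=vectors, frame_rate=bands.frame_rate)


def from_density(
    density: DensitySeries,
    max_value: float,
    band_ids: tuple[str, str] = ("band0", "band1"),
    quantize: bool = True,
) -> BandSeries:
    """Map densities back to camera counts: max_value * exp(-v).

    Inverse of :func:`to_density` (up to quantization when ``quantize``).
    """
    if max_value <= 0:
        raise InputError("max_value must be positive")
    counts = max_value * np.exp(-density.vectors)
    if quantize:
        counts = np.rint(counts)
    counts = np.clip(counts, 0.0, max_value)
    return BandSeries(
        values=counts,
        frame_rate=density.frame_rate,
        band_ids=band_ids,
        max_value=max_value,
    )


def forward_observe(
    F: SystemMatrix,
    r: PigmentSeries,
    noise_sigma: float,
    seed: int | np.random.Generator | None = None,
) -> DensitySeries:
    """Simulate the observation v = F r + n with i.i.d. Gaussian sensor noise.

    ``noise_sigma`` is the per-component noise standard deviation in density
    units; zero gives the noise-free model exactly.
    """
    if noise_sigma < 0:
        raise InputError(f"noise_sigma must be >= 0, got {noise_sigma}")
    v = r.vectors @ F.entries.T
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma, size=v.shape)
    return DensitySeries(vectors=v, frame_rate=r.frame_rate)


def build_forward_matrix(
    hb_column: Sequence[float],
    shade_column: Sequence[float] = (1.0, 1.0),
) -> SystemMatrix:
    """Assemble F from per-band relative absorbances of the two components.

    The hemoglobin column holds the relative effective absorbance of blood at
    the two selected bands; the shade column defaults to (1, 1) because an
    illumination/geometry change scales both bands equally.
    """
    entries = np.column_stack(
        [np.asarray(hb_column, dtype=float), np.asarray(shade_column, dtype=float)]
    )
    F = SystemMatrix(entries=entries)
    F.require_invertible()
    return F
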