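"""Sensor-noise estimation from an artificial-skin-patch region.

The patch is a static object imaged alongside the face: its surface does
not change, so any temporal fluctuation of its ROI-mean pixel value is
sensor (thermal) noise.  The per-band standard deviation of that series —
the larger of the two bands is kept — sets the scale of the Gaussian
noise model, and the noise autocorrelation matrix Rnn = <n n^T> follows
either analytically (sigma^2 I for i.i.d. zero-mean noise) or by sampling
generated noise, reproducing the empirical procedure.

Sigma is estimated on the density-transformed patch series by default so
that Rnn shares units with the density-space observation v = F r + n; a
raw-count mode is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .estimators import AutocorrelationMatrix
from .forward_model import BandSeries, to_density

__all__ = ["NoiseEstimate", "patch_noise_sigma", "build_noise_autocorrelation"]


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-band patch noise sigmas and the selected (larger) value."""

    sigma_per_band: tuple[float, float]
    sigma_selected: float
    source: str
    space: str  # density | count

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_per_band):
            raise InputError("noise sigmas must be >= 0")
        if self.sigma_selected != max(self.sigma_per_band):
            raise InputError("sigma_selected must be the max over bands")


def patch_noise_sigma(
    patch_bands: BandSeries,
    space: str = "density",
    floor_count: float = 1.0,
    source: str = "patch",
) -> NoiseEstimate:
    """Sample standard deviation of the patch ROI-mean series, per band.

    Uses the n-1 denominator; the larger of the two band sigmas is
    selected for the noise model.
    """
    if patch_bands.n_frames < 2:
        raise InputError(
            f"need >= 2 frames to estimate noise, got {patch_bands.n_frames}"
        )
    if space == "density":
        series = to_density(patch_bands, floor_count=floor_count).vectors
    elif space == "count":
        series = patch_bands.values
    else:
        raise InputError(f"unknown noise space {space!r}")
    sigmas = series.std(axis=0, ddof=1)
    return NoiseEstimate(
        sigma_per_band=(float(sigmas[0]), float(sigmas[1])),
        sigma_selected=float(sigmas.max()),
        source=f"{source}[0:{patch_bands.n_frames}]",
        space=space,
    )


def build_noise_autocorrelation(
    sigma: float,
    mode: str = "analytic",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> AutocorrelationMatrix:
    """Noise autocorrelation Rnn = <n n^T> for i.i.d. N(0, sigma^2) noise.

    ``analytic`` returns the exact second moment sigma^2 I; ``sampled``
    draws n_samples noise 2-vectors and averages n n^T, mirroring the
    generate-then-average procedure used with measured patch sigmas.
    """
    if sigma < 0:
        raise InputError(f"sigma must be >= 0, got {sigma}")
    if mode == "analytic":
        return AutocorrelationMatrix(
            entries=sigma**2 * np.eye(2), role="noise", provenance="analytic"
        )
    if mode == "sampled":
        if n_samples < 2:
            raise InputError("sampled mode requires n_samples >= 2")
        rng = np.random.default_rng(seed)
        n = rng.normal(0.0, sigma, size=(n_samples, 2))
        entries = n.T @ n / n_samples
        entries = 0.5 * (entries + entries.T)
        return AutocorrelationMatrix(
            entries=entries,
            role="noise",
            provenance=f"sampled({n_samples}, seed={seed})",
        )
    raise InputError(f"unknown mode {mode!r}")
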