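"""Synthetic two-band NIR session generator.

Emulates the statistical structure the separation method assumes: a
hemoglobin component pulsating periodically around a baseline (plus an
optional slow drift), a temporally fixed shade component, the linear
density-space observation v = F r + n with i.i.d. Gaussian sensor noise,
integer-quantized camera counts, a constant-reflectance artificial-skin
patch carrying noise of the same magnitude, and a clean pulse-meter
reference sampled on its own clock.

Default calibration (density units): hemoglobin baseline 0.30 with pulse
amplitude 0.005, shade 0.50, sensor noise sigma 0.0025.  With the default
weak-contrast system matrix (hemoglobin column (0.77, 0.65), determinant
0.12) the conventional (matrix-inverse) raw pulse is swamped by amplified
noise — its heart rate becomes unusable — while the Wiener estimate
retains a dominant cardiac spectral peak and supports reliable peak-based
heart-rate estimation: the regime the method is designed for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError, InputError
from .forward_model import (
    BandSeries,
    DensitySeries,
    PigmentSeries,
    SystemMatrix,
    build_forward_matrix,
    forward_observe,
    from_density,
)
from .io import RoiSpec

__all__ = [
    "DriftSpec",
    "SyntheticConfig",
    "SyntheticSession",
    "pulse_waveform",
    "synthesize_session",
    "synthesize_frames",
    "default_forward_matrix",
]


def default_forward_matrix() -> SystemMatrix:
    """Placeholder system matrix for the 800/930 nm band pair.

    Hemoglobin column (0.77, 0.65): relative effective blood absorbance at
    the two bands, deliberately weakly contrasted as in the near-infrared
    range; shade column (1, 1).
    """
    return build_forward_matrix((0.77, 0.65), (1.0, 1.0))


@dataclass(frozen=True)
class DriftSpec:
    """Slow sinusoidal baseline drift added to the hemoglobin component."""

    amplitude: float = 0.01  # density units
    frequency_hz: float = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    duration_s: float = 30.0
    frame_rate: float = 66.5
    f0: float = 1.2  # pulse fundamental, Hz (72 bpm)
    harmonic_amps: tuple[float, ...] = (1.0, 0.35)
    hb_baseline: float = 0.30
    hb_pulse_amp: float = 0.005
    shade_value: float = 0.50
    drift: DriftSpec | None = DriftSpec()
    noise_sigma: float = 0.0025
    F: SystemMatrix = field(default_factory=default_forward_matrix)
    max_value: float = 65535.0
    band_ids: tuple[str, str] = ("800nm", "930nm")
    patch_density: float = 0.60
    reference_rate: float = 256.0
    invert_reference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0 or self.f0 <= 0:
            raise ConfigurationError("duration_s, frame_rate and f0 must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.max_value <= 0:
            raise ConfigurationError("max_value must be positive")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s * self.frame_rate))

    @property
    def truth_hr(self) -> float:
        return 60.0 * self.f0

    def hb_fluctuation_range(self) -> tuple[float, float]:
        """Ground-truth range of the pulsatile hemoglobin fluctuation.

        Deliberately excludes the slow drift: the pigment prior describes
        the cardiac-band fluctuation the estimator must preserve, while
        sub-cardiac drift is removed downstream by detrending.  Folding
        the drift into the prior inflates the assumed hemoglobin variance
        and makes the estimator admit noise to track a component that is
        discarded anyway.
        """
        return (
            self.hb_baseline - self.hb_pulse_amp,
            self.hb_baseline + self.hb_pulse_amp,
        )


@dataclass(frozen=True)
class SyntheticSession:
    """A generated session: observations, patch, truth and reference."""

    bands: BandSeries
    patch_bands: BandSeries
    truth_pigments: PigmentSeries
    reference_signal: np.ndarray
    reference_rate: float
    truth_hr: float
    config: SyntheticConfig


def pulse_waveform(
    t: np.ndarray, f0: float, harmonic_amps: tuple[float, ...] = (1.0, 0.35)
) -> np.ndarray:
    """Periodic pulse stand-in: harmonic sine sum, unit peak amplitude.

    w(t) = sum_k a_k sin(2 pi k f0 t), normalized by its peak absolute
    value over one period so the output has unit amplitude and period 1/f0.
    """
    if f0 <= 0:
        raise InputError("f0 must be positive")
    amps = np.asarray(harmonic_amps, dtype=float)
    if amps.size == 0 or np.all(amps == 0):
        raise InputError("at least one nonzero harmonic amplitude required")
    t = np.asarray(t, dtype=float)

    def _raw(tt: np.ndarray) -> np.ndarray:
        out = np.zeros_like(tt)
        for k, a in enumerate(amps, start=1):
            out += a * np.sin(2.0 * np.pi * k * f0 * tt)
        return out

    # normalize on a dense one-period grid so the scale is t-independent
    dense = np.linspace(0.0, 1.0 / f0, 4096, endpoint=False)
    peak = np.abs(_raw(dense)).max()
    return _raw(t) / peak


def synthesize_session(cfg: SyntheticConfig) -> SyntheticSession:
    """Generate a full session, reproducible from ``cfg.seed``."""
    n = cfg.n_frames
    t = np.arange(n) / cfg.frame_rate
    rng = np.random.default_rng(cfg.seed)

    hb = cfg.hb_baseline + cfg.hb_pulse_amp * pulse_waveform(t, cfg.f0, cfg.harmonic_amps)
    if cfg.drift is not None:
        hb = hb + cfg.drift.amplitude * np.sin(
            2.0 * np.pi * cfg.drift.frequency_hz * t
        )
    truth = PigmentSeries(
        vectors=np.column_stack([hb, np.full(n, cfg.shade_value)]),
        frame_rate=cfg.frame_rate,
        method_tag="ground_truth",
    )

    v = forward_observe(cfg.F, truth, cfg.noise_sigma, seed=rng)
    bands = from_density(v, cfg.max_value, band_ids=cfg.band_ids, quantize=True)

    # static patch: constant density plus sensor noise of the same magnitude
    patch_density = np.full((n, 2), cfg.patch_density)
    if cfg.noise_sigma > 0:
        patch_density = patch_density + rng.normal(0.0, cfg.noise_sigma, size=(n, 2))
    patch_bands = from_density(
        DensitySeries(vectors=patch_density, frame_rate=cfg.frame_rate),
        cfg.max_value,
        band_ids=cfg.band_ids,
        quantize=True,
    )

    n_ref = int(np.floor(cfg.duration_s * cfg.reference_rate))
    t_ref = np.arange(n_ref) / cfg.reference_rate
    reference = pulse_waveform(t_ref, cfg.f0, cfg.harmonic_amps)
    if cfg.invert_reference:
        reference = -reference

    return SyntheticSession(
        bands=bands,
        patch_bands=patch_bands,
        truth_pigments=truth,
        reference_signal=reference,
        reference_rate=cfg.reference_rate,
        truth_hr=cfg.truth_hr,
        config=cfg,
    )


def synthesize_frames(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    image_size: tuple[int, int] = (64, 64),
    roi_layout: dict[str, RoiSpec] | None = None,
    spatial_noise_sigma: float = 0.0,
) -> Path:
    """Write a session as per-band multi-page 16-bit TIFFs plus a manifest.

    The face ROI carries the session's band pixel series (plus optional
    i.i.d. spatial noise per pixel); the patch ROI carries the patch
    series.  Reading back through the ROI-mean extraction reproduces the
    in-memory series up to spatial-averaging and quantization error.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = image_size
    if roi_layout is None:
        roi_layout = {
            "face": RoiSpec("face", 4, 4, w // 2 - 8, h - 8),
            "patch": RoiSpec("patch", w // 2 + 4, 4, w - (w // 2 + 4) - 4, h - 8),
        }
    for roi in roi_layout.values():
        roi.check_inside((h, w))

    session = synthesize_session(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5A7]))
    n = session.bands.n_frames
    background = cfg.max_value * 0.25

    band_files: dict[str, str] = {}
    for j, band in enumerate(cfg.band_ids):
        frames = np.full((n, h, w), background, dtype=float)
        face, patch = roi_layout["face"], roi_layout["patch"]
        frames[:, face.y0 : face.y0 + face.height, face.x0 : face.x0 + face.width] = (
            session.bands.values[:, j][:, None, None]
        )
        frames[
            :, patch.y0 : patch.y0 + patch.height, patch.x0 : patch.x0 + patch.width
        ] = session.patch_bands.values[:, j][:, None, None]
        if spatial_noise_sigma > 0:
            frames = frames + rng.normal(0.0, spatial_noise_sigma, size=frames.shape)
        counts = np.clip(np.rint(frames), 0, cfg.max_value).astype(np.uint16)
        fname = f"band_{band}.tif"
        tifffile.imwrite(out_dir / fname, counts)
        band_files[band] = fname

    ref_csv = "reference.csv"
    t_ref = np.arange(session.reference_signal.size) / session.reference_rate
    np.savetxt(
        out_dir / ref_csv,
        np.column_stack([t_ref, session.reference_signal]),
        delimiter=",",
        header="time_s,value",
        comments="",
    )

    manifest = {
        "frame_rate": cfg.frame_rate,
        "max_value": cfg.max_value,
        "bands": band_files,
        "rois": {name: roi.to_dict() for name, roi in roi_layout.items()},
        "reference": {"file": ref_csv, "rate": session.reference_rate},
        "truth_hr": session.truth_hr,
        "seed": cfg.seed,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
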