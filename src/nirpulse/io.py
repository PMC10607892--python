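"""Frame-stack reading and ROI extraction.

Input is a JSON manifest describing a two-band frame stack: per band
either a single multi-page TIFF or an ordered list of per-frame image
files, plus the frame rate, sensor full scale and ROI layout.  ROI
coordinates are 0-based with half-open extents [x0, x0+width) x
[y0, y0+height).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError, InputError
from .forward_model import BandSeries

__all__ = [
    "RoiSpec",
    "read_manifest",
    "read_frame_stack",
    "extract_roi_mean",
    "band_series_from_frames",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, 0-based, half-open extents."""

    name: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError(
                f"ROI {self.name!r} must have width, height >= 1"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ConfigurationError(f"ROI {self.name!r} origin must be >= 0")

    @property
    def area(self) -> int:
        return self.width * self.height

    def check_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ConfigurationError(
                f"ROI {self.name!r} ({self.x0},{self.y0},{self.width},{self.height}) "
                f"exceeds frame bounds {w}x{h}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "x0": self.x0,
            "y0": self.y0,
            "width": self.width,
            "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            name=d["name"], x0=d["x0"], y0=d["y0"], width=d["width"], height=d["height"]
        )


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    with open(path) as fh:
        manifest = json.load(fh)
    for key in ("frame_rate", "max_value", "bands"):
        if key not in manifest:
            raise InputError(f"manifest missing required key {key!r}")
    return manifest


def _read_band(entry, base: Path) -> np.ndarray:
    """Read one band as an (n_frames, H, W) array."""
    if isinstance(entry, str):
        path = base / entry
        if not path.exists():
            raise InputError(f"band file not found: {path}")
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return np.asarray(frames)
    # ordered list of per-frame files
    stack = []
    shape = None
    for name in entry:
        path = base / name
        if not path.exists():
            raise InputError(f"frame file not found: {path}")
        frame = tifffile.imread(path)
        if frame.ndim != 2:
            raise InputError(f"frame {path} is not a single 2-D image")
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise InputError(
                f"frame {path} has dimensions {frame.shape}, expected {shape}"
            )
        stack.append(frame)
    if not stack:
        raise InputError("band has no frames")
    return np.stack(stack)


def read_frame_stack(
    manifest_path: str | Path, bands: tuple[str, str] | None = None
) -> tuple[dict[str, np.ndarray], dict]:
    """Read the two selected bands of a frame stack.

    Returns ``(frames_by_band, manifest)`` where each band maps to an
    (n_frames, H, W) array.  Frame order is the manifest order (per-frame
    file lists are taken as already ordered).
    """
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    available = list(manifest["bands"])
    if bands is None:
        if len(available) != 2:
            raise ConfigurationError(
                f"manifest has {len(available)} bands; select exactly two"
            )
        bands = tuple(available)
    if len(bands) != 2:
        raise ConfigurationError("exactly two bands must be selected")
    frames_by_band: dict[str, np.ndarray] = {}
    shape = None
    n = None
    for band in bands:
        if band not in manifest["bands"]:
            raise InputError(f"band {band!r} not in manifest (have {available})")
        frames = _read_band(manifest["bands"][band], base)
        if shape is None:
            shape, n = frames.shape[1:], frames.shape[0]
        elif frames.shape[1:] != shape or frames.shape[0] != n:
            raise InputError(
                f"band {band!r} has shape {frames.shape}, expected ({n}, *{shape})"
            )
        frames_by_band[band] = frames
    return frames_by_band, manifest


def extract_roi_mean(frames: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Per-frame arithmetic mean of pixel values inside the ROI."""
    roi.check_inside(frames.shape[1:])
    block = frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return block.mean(axis=(1, 2), dtype=float)


def band_series_from_frames(
    frames_by_band: dict[str, np.ndarray],
    rois: list[RoiSpec],
    frame_rate: float,
    max_value: float,
    band_ids: tuple[str, str] | None = None,
) -> BandSeries:
    """Area-weighted ROI-mean series for two bands.

    Several ROIs (e.g. nose + both cheeks) are combined by weighting each
    per-frame mean with its pixel area, which equals the mean over the
    union of the (disjoint) ROIs.
    """
    if not rois:
        raise ConfigurationError("at least one ROI required")
    if band_ids is None:
        band_ids = tuple(frames_by_band)
    if len(band_ids) != 2:
        raise ConfigurationError("exactly two bands required")
    total_area = sum(r.area for r in rois)
    columns = []
    for band in band_ids:
        means = [extract_roi_mean(frames_by_band[band], roi) for roi in rois]
        weighted = sum(m * roi.area for m, roi in zip(means, rois)) / total_area
        columns.append(weighted)
    return BandSeries(
        values=np.column_stack(columns),
        frame_rate=frame_rate,
        band_ids=band_ids,
        max_value=max_value,
    )
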