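"""Image-stack I/O with acquisition metadata.

High-speed ciliary videos and bead time-lapse movies are both handled as plain
grayscale TIFF stacks. Acquisition metadata the files themselves rarely carry
(frame rate in Hz, pixel size in um) travels in a JSON sidecar written next to
the stack; explicit arguments always win over file-derived values because all
downstream frequencies and speeds scale with them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VideoStack", "LayerMask", "read_stack", "write_stack", "read_mask"]

_SIDECAR_SUFFIX = ".json"


@dataclass
class VideoStack:
    """An ordered grayscale frame stack with acquisition metadata.

    frames are float intensities in [0, 1], shaped (time, rows, cols);
    integer input is normalized by its dtype maximum on load.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float = 1.0
    origin_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, rows, cols), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("stack must have at least 2 frames")
        if not (self.frame_rate_hz > 0):
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("intensities must lie in [0, 1] after normalization")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class LayerMask:
    """Boolean mask delimiting the tissue layer ROIs may occupy."""

    mask: np.ndarray
    label: str = "ependymal layer"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={self.mask.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())


def _normalize_frames(arr: np.ndarray) -> np.ndarray:
    """Scale integer data by its dtype maximum; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    out = arr.astype(np.float64)
    return out


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    # multi-channel frames reduced by channel mean; single-channel untouched
    if arr.ndim == 4:
        return arr.mean(axis=-1)
    return arr


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def read_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> VideoStack:
    """Read a multi-page TIFF (or a directory of same-shaped single-page
    TIFFs in lexicographic order) into a :class:`VideoStack`.

    Metadata precedence: explicit argument > JSON sidecar > nothing. A missing
    frame rate is fatal; a missing pixel size defaults to 1 um with a warning.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shape across {path}: {sorted(shapes)}")
        raw = np.stack(pages)
        sidecar = _sidecar_path(files[0])
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        raw = tifffile.imread(path)
        sidecar = _sidecar_path(path)

    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if frame_rate_hz is None:
        frame_rate_hz = meta.get("frame_rate_hz")
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if frame_rate_hz is None:
        raise ValueError(
            f"frame rate for {path} is unknown: pass frame_rate_hz or provide a JSON sidecar"
        )
    if pixel_size_um is None:
        warnings.warn(f"pixel size for {path} unknown; defaulting to 1.0 um/px")
        pixel_size_um = 1.0

    raw = _to_grayscale(np.asarray(raw))
    if raw.ndim == 2:
        raise ValueError(f"{path} holds a single frame; a stack needs at least 2")
    frames = np.clip(_normalize_frames(raw), 0.0, 1.0)
    return VideoStack(
        frames=frames,
        frame_rate_hz=float(frame_rate_hz),
        pixel_size_um=float(pixel_size_um),
        origin_path=str(path),
    )


def write_stack(stack: VideoStack, path: str | Path) -> Path:
    """Write a stack as multi-page 16-bit TIFF plus a metadata sidecar.

    Intensities are quantized to uint16, so a round trip through
    :func:`read_stack` preserves each pixel to within 1/65535.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(stack.frames * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {"frame_rate_hz": stack.frame_rate_hz, "pixel_size_um": stack.pixel_size_um},
            indent=2,
        )
    )
    return path


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> LayerMask:
    """Read a single-page image as a boolean layer mask (nonzero = inside)."""
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"mask image must be 2-D, got shape {arr.shape}")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"mask shape {arr.shape} does not match expected {tuple(expected_shape)}")
    mask = arr != 0
    if not mask.any():
        warnings.warn(f"mask {path} has no true pixels; ROI sampling will fail on it")
    return LayerMask(mask=mask)


def write_mask(mask: LayerMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255, photometric="minisblack")
    return path
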