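"""ROI grid placement and brightness-trace extraction.

CBF analysis samples 16-20 windows of 11x11 pixels whose centers sit at least
30 pixels apart, every window confined entirely to the ependymal-layer mask.
Placement is seeded and deterministic: the mask-valid centers (those whose
whole footprint is mask-true and in bounds) are enumerated, permuted with the
seed, and consumed greedily, accepting each candidate whose center is >=
min_sep (Euclidean, pixels) from all accepted centers. ROI sets can be
round-tripped through CSV so manually chosen placements are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter

from .video_io import LayerMask, VideoStack

__all__ = ["RoiSpec", "RoiTrace", "sample_rois", "extract_trace", "rois_to_csv", "rois_from_csv"]

#: attempt budget multiplier: at most this many candidates examined per requested ROI
ATTEMPT_BUDGET_PER_ROI = 10_000


@dataclass(frozen=True)
class RoiSpec:
    """An odd square window: 0-based center and edge length in pixels."""

    center_row: int
    center_col: int
    size: int = 11

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"ROI size must be odd and >=3, got {self.size}")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2

    def bounds(self) -> tuple[int, int, int, int]:
        """(row_lo, row_hi, col_lo, col_hi), half-open slices."""
        h = self.half
        return (self.center_row - h, self.center_row + h + 1,
                self.center_col - h, self.center_col + h + 1)

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        r0, r1, c0, c1 = self.bounds()
        return r0 >= 0 and c0 >= 0 and r1 <= shape[0] and c1 <= shape[1]


@dataclass
class RoiTrace:
    """Per-frame mean brightness of one ROI."""

    roi: RoiSpec
    values: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.size


def _valid_centers(mask: np.ndarray, size: int) -> np.ndarray:
    """Centers whose full size x size footprint is mask-true and in bounds.

    Erosion with a size x size square marks exactly those pixels; the
    separable minimum filter computes it in O(pixels), and the constant
    zero border rejects footprints leaving the frame.
    """
    eroded = minimum_filter(mask.astype(np.uint8), size=size, mode="constant", cval=0)
    return np.argwhere(eroded.astype(bool))


def sample_rois(
    mask: LayerMask,
    n_min: int = 16,
    n_max: int = 20,
    size: int = 11,
    min_sep: float = 30.0,
    seed: int = 0,
) -> list[RoiSpec]:
    """Place up to ``n_max`` non-overlapping ROIs inside the layer mask.

    Returns between ``n_min`` and ``n_max`` ROIs when feasible. If fewer than
    ``n_min`` placements fit within the attempt budget the shorter list is
    returned with an "under-sampled" warning; zero feasible placements is an
    error. Deterministic for a fixed (mask, parameters, seed).
    """
    if n_min > n_max:
        raise ValueError(f"n_min ({n_min}) must be <= n_max ({n_max})")
    if not mask.mask.any():
        raise ValueError("empty mask: no true pixels to sample ROIs from")

    candidates = _valid_centers(mask.mask, size)
    if len(candidates) == 0:
        raise ValueError(f"no feasible placement: no {size}x{size} footprint fits the mask")

    rng = np.random.default_rng(seed)
    budget = ATTEMPT_BUDGET_PER_ROI * n_max
    order = rng.permutation(len(candidates))[:budget]
    pts = candidates[order].astype(np.float64)

    # greedy scan in permuted order; accepting a center eliminates every
    # later candidate within min_sep, so the next survivor is the next accept
    alive = np.ones(len(pts), dtype=bool)
    accepted: list[np.ndarray] = []
    cursor = 0
    min_sep_sq = float(min_sep) ** 2
    while len(accepted) < n_max:
        survivors = np.flatnonzero(alive[cursor:])
        if survivors.size == 0:
            break
        j = cursor + int(survivors[0])
        accepted.append(pts[j])
        alive &= np.sum((pts - pts[j]) ** 2, axis=1) >= min_sep_sq
        cursor = j + 1

    if len(accepted) < n_min:
        warnings.warn(
            f"under-sampled: only {len(accepted)} ROI placements found "
            f"(requested {n_min}-{n_max})"
        )
    return [RoiSpec(int(r), int(c), size) for r, c in accepted]


def extract_trace(stack: VideoStack, roi: RoiSpec) -> RoiTrace:
    """Mean brightness over the ROI footprint, one value per frame."""
    if not roi.in_bounds(stack.frame_shape):
        raise ValueError(
            f"ROI footprint {roi.bounds()} exceeds frame bounds {stack.frame_shape}"
        )
    r0, r1, c0, c1 = roi.bounds()
    values = stack.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return RoiTrace(roi=roi, values=values, frame_rate_hz=stack.frame_rate_hz)


def rois_to_csv(rois: list[RoiSpec], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "roi_id": range(len(rois)),
            "center_row": [r.center_row for r in rois],
            "center_col": [r.center_col for r in rois],
            "size": [r.size for r in rois],
        }
    )
    df.to_csv(path, index=False)
    return path


def rois_from_csv(path: str | Path) -> list[RoiSpec]:
    df = pd.read_csv(path)
    required = {"center_row", "center_col", "size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV {path} missing columns: {sorted(missing)}")
    return [
        RoiSpec(int(row.center_row), int(row.center_col), int(row.size))
        for row in df.itertuples()
    ]
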