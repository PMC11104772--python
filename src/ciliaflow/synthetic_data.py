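"""Ground-truth generators for every pipeline stage.

Three simulators with known truth:

* ciliary-beating video — a sinusoidally oscillating intensity field with a
  linear spatial phase gradient (the metachronal wave), a smooth static
  amplitude field supported on a band-shaped ependymal layer, additive
  Gaussian noise, clipped to [0, 1];
* bead-flow movie — point-like Gaussian spots advected at constant commanded
  velocity with per-frame positional jitter over a noisy background;
* grouped CBF samples — truncated-normal draws with controlled group means,
  for exercising the permutation test directly.

Every generator is a pure function of its parameters (seed included), so
identical parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .group_stats import GroupSample
from .video_io import LayerMask, VideoStack

__all__ = [
    "CiliaSimParams",
    "BeadSimParams",
    "simulate_cilia_video",
    "simulate_bead_movie",
    "simulate_cbf_groups",
    "WT_LIKE_CBF_HZ",
    "KO_LIKE_CBF_HZ",
    "cilia_preset",
]

# Named scenario presets. These CBF values are arbitrary fixtures in the
# physiological range for murine ependymal cilia, chosen to give a clear
# 6 Hz group contrast; they are not measurements.
WT_LIKE_CBF_HZ = 28.0
KO_LIKE_CBF_HZ = 34.0


@dataclass
class CiliaSimParams:
    """Parameters of the ciliary-beating video simulator.

    The intensity model is
    ``I(r, c, t) = baseline + A(r, c) * sin(2*pi*cbf_hz*t/rate + k.(r, c)) + eps``
    with A a seeded smooth random amplitude field supported on the ependymal
    band (zero outside), k the metachronal wave vector in rad/px, and
    eps ~ N(0, noise_sigma^2), clipped to [0, 1].
    """

    frame_count: int = 1000
    frame_rate_hz: float = 1000.0
    shape: tuple[int, int] = (160, 160)
    cbf_hz: float = 28.0
    amplitude: float = 0.2
    baseline: float = 0.5
    noise_sigma: float = 0.05
    wave_vector: tuple[float, float] = (0.15, 0.10)
    band: tuple[int, int] = (20, 140)
    texture_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if not (0 < self.cbf_hz < self.frame_rate_hz / 2):
            raise ValueError(
                f"cbf_hz must lie in (0, Nyquist={self.frame_rate_hz / 2}), got {self.cbf_hz}"
            )
        if not (0 <= self.band[0] < self.band[1] <= self.shape[0]):
            raise ValueError(f"band {self.band} must lie within rows 0..{self.shape[0]}")
        if self.amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude and noise_sigma must be >= 0")
        headroom = self.baseline + self.amplitude + 3 * self.noise_sigma
        if headroom > 1.0 + 1e-9 or self.baseline - self.amplitude - 3 * self.noise_sigma < -1e-9:
            raise ValueError(
                "baseline +- (amplitude + 3*noise_sigma) must stay within [0, 1] "
                f"to keep clipping negligible (got headroom {headroom:.3f})"
            )


@dataclass
class BeadSimParams:
    """Parameters of the bead-flow movie simulator.

    Each bead's center advances ``speed * frame_interval / pixel_size`` pixels
    per frame along its direction, plus N(0, jitter_sigma_px^2) per axis, and
    is rendered as a Gaussian spot on a noisy constant background. Beads that
    leave the frame stop being rendered; the truth table marks the exit.
    """

    frame_count: int = 20
    frame_interval_s: float = 0.2
    shape: tuple[int, int] = (256, 512)
    pixel_size_um: float = 0.4
    speeds_um_s: Sequence[float] = (30.0,)
    directions: Sequence[tuple[float, float]] | None = None  # unit vectors (drow, dcol)
    start_positions: Sequence[tuple[float, float]] | None = None
    jitter_sigma_px: float = 0.3
    spot_sigma_px: float = 2.0
    spot_amplitude: float = 0.8
    background: float = 0.1
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if any(s < 0 for s in self.speeds_um_s):
            raise ValueError("speeds must be >= 0")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.speeds_um_s)


def _amplitude_field(params: CiliaSimParams, rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth random amplitude in [amplitude/2, amplitude] on the band."""
    rough = rng.standard_normal(params.shape)
    smooth = gaussian_filter(rough, params.texture_scale)
    lo, hi = smooth.min(), smooth.max()
    unit = (smooth - lo) / (hi - lo) if hi > lo else np.full(params.shape, 0.5)
    amp = params.amplitude * (0.5 + 0.5 * unit)
    field = np.zeros(params.shape)
    field[params.band[0] : params.band[1], :] = amp[params.band[0] : params.band[1], :]
    return field


def simulate_cilia_video(params: CiliaSimParams) -> tuple[VideoStack, LayerMask, dict]:
    """Simulate a ciliary-beating video with its layer mask and truth record."""
    rng = np.random.default_rng(params.seed)
    amp = _amplitude_field(params, rng)

    rows = np.arange(params.shape[0])[:, None]
    cols = np.arange(params.shape[1])[None, :]
    phase = params.wave_vector[0] * rows + params.wave_vector[1] * cols

    t = np.arange(params.frame_count, dtype=np.float64)
    omega_t = 2 * np.pi * params.cbf_hz * t / params.frame_rate_hz

    frames = np.empty((params.frame_count,) + params.shape, dtype=np.float32)
    # frame-by-frame keeps peak memory at one float64 frame
    for i in range(params.frame_count):
        frames[i] = params.baseline + amp * np.sin(omega_t[i] + phase)
    if params.noise_sigma > 0:
        frames += rng.normal(0.0, params.noise_sigma, frames.shape).astype(np.float32)
    np.clip(frames, 0.0, 1.0, out=frames)

    mask = np.zeros(params.shape, dtype=bool)
    mask[params.band[0] : params.band[1], :] = True

    truth = {
        "cbf_hz": params.cbf_hz,
        "amplitude_map": amp,
        "wave_vector": params.wave_vector,
        "noise_sigma": params.noise_sigma,
        "seed": params.seed,
    }
    stack = VideoStack(
        frames=frames.astype(np.float64),
        frame_rate_hz=params.frame_rate_hz,
        origin_path=f"synthetic:cilia(seed={params.seed})",
    )
    return stack, LayerMask(mask=mask), truth


def simulate_bead_movie(params: BeadSimParams) -> tuple[VideoStack, pd.DataFrame]:
    """Simulate a bead-flow movie; truth is a per-bead per-frame position table.

    Returns the stack and a DataFrame with columns
    (bead_id, frame, row, col, in_frame, speed_um_s).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_beads
    nrows, ncols = params.shape

    if params.directions is None:
        directions = [(0.0, 1.0)] * n
    else:
        directions = [tuple(d / np.linalg.norm(d)) for d in np.asarray(params.directions, float)]
    if params.start_positions is None:
        # spread beads down the rows, starting near the left edge
        margin = max(4 * params.spot_sigma_px, 8)
        if n == 0:
            row_positions = np.empty(0)
        elif n == 1:
            row_positions = np.array([nrows / 2])
        else:
            row_positions = np.linspace(margin, nrows - margin, n)
        starts = [(float(r), float(margin)) for r in row_positions]
    else:
        starts = [tuple(map(float, p)) for p in params.start_positions]
    if len(directions) != n or len(starts) != n:
        raise ValueError("directions and start_positions must match the number of beads")

    step_px = [s * params.frame_interval_s / params.pixel_size_um for s in params.speeds_um_s]

    truth_rows = []
    positions = np.array(starts, dtype=np.float64).reshape(n, 2)
    frames = np.empty((params.frame_count, nrows, ncols), dtype=np.float64)
    rr = np.arange(nrows)[:, None]
    cc = np.arange(ncols)[None, :]
    for t in range(params.frame_count):
        img = np.full((nrows, ncols), params.background)
        for b in range(n):
            r, c = positions[b]
            in_frame = (0 <= r < nrows) and (0 <= c < ncols)
            if in_frame:
                img += params.spot_amplitude * np.exp(
                    -((rr - r) ** 2 + (cc - c) ** 2) / (2 * params.spot_sigma_px**2)
                )
            truth_rows.append(
                {
                    "bead_id": b,
                    "frame": t,
                    "row": r,
                    "col": c,
                    "in_frame": in_frame,
                    "speed_um_s": params.speeds_um_s[b],
                }
            )
        if params.noise_sigma > 0:
            img += rng.normal(0.0, params.noise_sigma, img.shape)
        frames[t] = img
        # advance for the next frame: drift + positional jitter
        drift = np.array([[step_px[b] * directions[b][0], step_px[b] * directions[b][1]]
                          for b in range(n)]).reshape(n, 2)
        jitter = (
            rng.normal(0.0, params.jitter_sigma_px, (n, 2))
            if params.jitter_sigma_px > 0
            else np.zeros((n, 2))
        )
        positions = positions + drift + jitter

    np.clip(frames, 0.0, 1.0, out=frames)
    stack = VideoStack(
        frames=frames,
        frame_rate_hz=1.0 / params.frame_interval_s,
        pixel_size_um=params.pixel_size_um,
        origin_path=f"synthetic:beads(seed={params.seed})",
    )
    truth = pd.DataFrame(
        truth_rows, columns=["bead_id", "frame", "row", "col", "in_frame", "speed_um_s"]
    )
    return stack, truth


def simulate_cbf_groups(
    n_a: int,
    n_b: int,
    mean_a: float,
    mean_b: float,
    sd: float,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[GroupSample, GroupSample]:
    """Seeded normal CBF draws (truncated at 0) for two groups."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    a = np.maximum(rng.normal(mean_a, sd, n_a), 0.0)
    b = np.maximum(rng.normal(mean_b, sd, n_b), 0.0)
    return (
        GroupSample(label=labels[0], values=a, unit="Hz"),
        GroupSample(label=labels[1], values=b, unit="Hz"),
    )


def cilia_preset(name: str, seed: int = 0, **overrides) -> CiliaSimParams:
    """Named scenario presets: "wt_like" (28 Hz) and "ko_like" (34 Hz)."""
    presets = {"wt_like": WT_LIKE_CBF_HZ, "ko_like": KO_LIKE_CBF_HZ}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return CiliaSimParams(cbf_hz=presets[name], seed=seed, **overrides)
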