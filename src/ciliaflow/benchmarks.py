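"""Parameter-recovery benchmarks run against the synthetic generators.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and returns the measured recovery quantities. They double as the
package's acceptance checks and as a template for validating the pipeline on
new acquisition settings. Problem sizes follow the simulated study
conditions: 1,000-frame videos at 1,000 Hz for CBF, 20-frame movies at 0.2 s
intervals for beads, 10,000-iteration permutation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bead_tracking import analyze_bead_movie
from .cbf_spectral import analyze_video, power_spectrum
from .config import AnalysisConfig, LinkingConfig, PermutationConfig
from .group_stats import GroupSample, compare_cbf_tables, permutation_test
from .roi_sampling import RoiSpec, RoiTrace, sample_rois
from .synthetic_data import (
    BeadSimParams,
    CiliaSimParams,
    cilia_preset,
    simulate_bead_movie,
    simulate_cilia_video,
)
from .video_io import LayerMask

__all__ = [
    "naive_dft_power",
    "cbf_recovery_grid",
    "spectral_oracle_deviation",
    "type_i_error_rate",
    "effect_detection",
    "roi_constraint_violations",
    "bead_speed_recovery",
    "pneumolysin_contrast",
]

CBF_GRID_HZ = tuple(float(f) for f in range(10, 61, 5))
NOISE_GRID = (0.0, 0.05, 0.1)
SPEED_GRID_UM_S = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def naive_dft_power(values: np.ndarray, window: np.ndarray) -> np.ndarray:
    """O(N^2) one-sided power spectrum, independent of any FFT routine.

    Same normalization convention as :func:`ciliaflow.cbf_spectral.power_spectrum`:
    ``P[k] = s_k |sum_n y_n w_n e^{-2 pi i k n / N}|^2 / sum(w^2)``.
    """
    y = np.asarray(values, dtype=np.float64) * window
    n = y.size
    k = np.arange(n // 2 + 1)
    angles = -2j * np.pi * np.outer(k, np.arange(n)) / n
    coeffs = np.exp(angles) @ y
    power = np.abs(coeffs) ** 2 / np.sum(window**2)
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return power * scale


def cbf_recovery_grid(
    seed: int = 0,
    cbf_values: tuple[float, ...] = CBF_GRID_HZ,
    noise_sigmas: tuple[float, ...] = NOISE_GRID,
    frame_count: int = 1000,
    frame_rate_hz: float = 1000.0,
) -> pd.DataFrame:
    """Frequency recovery over a true-CBF x noise grid of simulated videos.

    One video per grid cell (1,000 frames at 1,000 Hz by default, so the bin
    width is 1 Hz and every grid frequency is bin-centered). Returns one row
    per QC-passing ROI with the absolute estimation error.
    """
    rows = []
    for i, cbf in enumerate(cbf_values):
        for j, sigma in enumerate(noise_sigmas):
            params = CiliaSimParams(
                frame_count=frame_count,
                frame_rate_hz=frame_rate_hz,
                cbf_hz=cbf,
                noise_sigma=sigma,
                seed=seed + 1000 * i + j,
            )
            stack, mask, _ = simulate_cilia_video(params)
            config = AnalysisConfig(seed=seed + 1000 * i + j)
            table = analyze_video(stack, mask, config)
            qc = table[table["passed_qc"]]
            for est in qc["cbf_hz"]:
                rows.append(
                    {
                        "true_cbf_hz": cbf,
                        "noise_sigma": sigma,
                        "estimated_cbf_hz": est,
                        "abs_error_hz": abs(est - cbf),
                    }
                )
    return pd.DataFrame(rows)


def spectral_oracle_deviation(seed: int = 0, n_traces: int = 50, max_n: int = 2048) -> float:
    """Max relative bin-wise deviation between the FFT periodogram and the
    naive O(N^2) DFT, over random traces of assorted lengths."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_traces):
        n = int(rng.integers(16, max_n + 1))
        values = rng.standard_normal(n)
        for window in ("rect", "hann"):
            trace = RoiTrace(roi=RoiSpec(5, 5, 11), values=values, frame_rate_hz=1000.0)
            spec = power_spectrum(trace, window=window)
            if window == "rect":
                w = np.ones(n)
            else:
                w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
            ref = naive_dft_power(values, w)
            denom = max(ref.max(), 1e-300)
            worst = max(worst, float(np.max(np.abs(spec.power - ref)) / denom))
    return worst


def type_i_error_rate(
    seed: int = 0,
    n_replicates: int = 400,
    n_per_group: int = 50,
    n_iterations: int = 10_000,
    alpha: float = 0.05,
) -> float:
    """Fraction of null replicates (both groups from the same unit normal)
    rejected at ``alpha`` by the Monte-Carlo permutation test."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        a = GroupSample("a", rng.standard_normal(n_per_group))
        b = GroupSample("b", rng.standard_normal(n_per_group))
        res = permutation_test(
            a, b, n_iterations=n_iterations, seed=seed + rep + 1, exhaustive_limit=0
        )
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def _cohort_table(preset: str, n_videos: int, seed: int, frame_count: int) -> pd.DataFrame:
    tables = []
    for v in range(n_videos):
        params = cilia_preset(preset, seed=seed + v, frame_count=frame_count)
        stack, mask, _ = simulate_cilia_video(params)
        config = AnalysisConfig(seed=seed + v)
        tables.append(analyze_video(stack, mask, config, video_id=f"{preset}_{v}"))
    return pd.concat(tables, ignore_index=True)


def effect_detection(
    seed: int = 0, n_videos: int = 10, frame_count: int = 1000, n_iterations: int = 10_000
) -> dict:
    """Detect the wt_like (28 Hz) vs ko_like (34 Hz) cohort contrast.

    Simulates ``n_videos`` videos per cohort, runs the full CBF pipeline, and
    compares the per-ROI tables with the permutation test. Returns the
    p-value, the estimated and true mean differences, and per-group ns.
    """
    table_wt = _cohort_table("wt_like", n_videos, seed, frame_count)
    table_ko = _cohort_table("ko_like", n_videos, seed + 500, frame_count)
    result, summary = compare_cbf_tables(
        table_ko,
        table_wt,
        PermutationConfig(n_iterations=n_iterations),
        seed=seed,
        label_a="ko_like",
        label_b="wt_like",
    )
    return {
        "p_value": result.p_value,
        "observed_mean_diff_hz": result.observed,
        "true_mean_diff_hz": 34.0 - 28.0,
        "n_rois": [g["n_rois"] for g in summary["groups"]],
        "summary": summary,
    }


def roi_constraint_violations(
    seed: int = 0, n_samplings: int = 1000, shape: tuple[int, int] = (160, 160)
) -> dict:
    """Exhaustively audit seeded ROI samplings on random band masks.

    Each sampling uses a random horizontal band mask (random extent and
    offset); every returned ROI set is checked for footprint-in-mask,
    in-bounds, and pairwise center separation >= 30 px. Returns violation
    counts (all should be zero) and the number of samplings run.
    """
    rng = np.random.default_rng(seed)
    size, min_sep = 11, 30.0
    half = (size - 1) // 2
    violations = {"footprint": 0, "bounds": 0, "separation": 0}
    n_rois_total = 0
    for s in range(n_samplings):
        lo = int(rng.integers(0, shape[0] // 3))
        hi = int(rng.integers(lo + 60, shape[0] + 1))
        mask_arr = np.zeros(shape, dtype=bool)
        mask_arr[lo:hi, :] = True
        rois = sample_rois(LayerMask(mask=mask_arr), seed=seed + s)
        n_rois_total += len(rois)
        centers = np.array([(r.center_row, r.center_col) for r in rois], dtype=float)
        for roi in rois:
            r0, r1, c0, c1 = roi.bounds()
            if not roi.in_bounds(shape):
                violations["bounds"] += 1
            elif not mask_arr[r0:r1, c0:c1].all():
                violations["footprint"] += 1
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < min_sep:
                    violations["separation"] += 1
    return {
        "n_samplings": n_samplings,
        "n_rois": n_rois_total,
        "violations": violations,
        "total_violations": sum(violations.values()),
    }


def _bead_config() -> AnalysisConfig:
    # gate must exceed the fastest per-frame displacement (30 px at 60 um/s)
    return AnalysisConfig(linking=LinkingConfig(max_disp_px=40.0))


def bead_speed_recovery(
    seed: int = 0,
    speeds: tuple[float, ...] = SPEED_GRID_UM_S,
    jitter_sigma_px: float = 0.3,
) -> pd.DataFrame:
    """Track-speed recovery on constant-velocity movies, one per commanded speed.

    Each movie carries three beads at the same commanded speed; recovered
    per-track speeds are matched to the command and reported with relative
    errors.
    """
    rows = []
    for i, speed in enumerate(speeds):
        params = BeadSimParams(
            speeds_um_s=(speed,) * 3,
            shape=(192, 704),
            jitter_sigma_px=jitter_sigma_px,
            seed=seed + i,
        )
        stack, _ = simulate_bead_movie(params)
        tables = analyze_bead_movie(stack, _bead_config())
        for est in tables["speeds"]["speed_um_s"]:
            rows.append(
                {
                    "commanded_um_s": speed,
                    "estimated_um_s": est,
                    "rel_error": abs(est - speed) / speed,
                }
            )
    return pd.DataFrame(rows)


def pneumolysin_contrast(
    seed: int = 0,
    control_speed_um_s: float = 30.0,
    suppression: float = 0.3,
    n_movies: int = 6,
    n_iterations: int = 10_000,
) -> dict:
    """Detect a toxin-like flow suppression: a treated cohort whose commanded
    speeds are ``suppression`` times control. Returns the one-sided
    (control > treated) permutation p-value and the group means."""
    rng = np.random.default_rng(seed)

    def cohort(scale: float, seed0: int) -> np.ndarray:
        out = []
        for m in range(n_movies):
            speeds = tuple(
                max(float(rng.normal(control_speed_um_s * scale, 3.0 * scale)), 1.0)
                for _ in range(4)
            )
            params = BeadSimParams(speeds_um_s=speeds, shape=(192, 704), seed=seed0 + m)
            stack, _ = simulate_bead_movie(params)
            tables = analyze_bead_movie(stack, _bead_config())
            out.extend(tables["speeds"]["speed_um_s"].tolist())
        return np.asarray(out)

    control = cohort(1.0, seed + 10_000)
    treated = cohort(suppression, seed + 20_000)
    result = permutation_test(
        GroupSample("control", control, unit="um/s"),
        GroupSample("treated", treated, unit="um/s"),
        n_iterations=n_iterations,
        seed=seed,
        alternative="greater",
    )
    return {
        "p_value": result.p_value,
        "control_mean_um_s": float(control.mean()),
        "treated_mean_um_s": float(treated.mean()),
        "n_control": control.size,
        "n_treated": treated.size,
    }
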