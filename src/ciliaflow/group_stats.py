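"""Two-group permutation testing for per-ROI CBF and per-track bead speed.

The null distribution of the group-difference statistic is built by randomly
reassigning the pooled measurements to groups of the original sizes. Small
problems — where the number of distinct reassignments is below an exhaustive
limit — are enumerated completely and yield an exact rational p-value; larger
ones use Monte-Carlo resampling (default 10,000 iterations) with add-one
smoothing so the estimated p is never zero. The default exchange unit is the
individual measurement (ROI or track); an optional hierarchical mode permutes
whole videos instead, for data where within-video correlation matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import PermutationConfig

__all__ = ["GroupSample", "PermutationResult", "permutation_test", "compare_cbf_tables"]

#: enumerate all reassignments when C(n_a+n_b, n_a) is at most this
EXHAUSTIVE_LIMIT = 200_000


@dataclass
class GroupSample:
    """Labelled measurement vector for one experimental group."""

    label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError(f"group {self.label!r} has no values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    p_value: float
    n_iterations: int
    mode: str  # "exhaustive" or "monte_carlo"
    seed: int | None
    null_quantiles: tuple[float, float, float]  # 2.5%, 50%, 97.5%

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "mode": self.mode,
            "seed": self.seed,
            "null_quantiles": list(self.null_quantiles),
        }

    def summary_line(self) -> str:
        return (
            f"{self.statistic_name}: observed={self.observed:.4g}, "
            f"p={self.p_value:.4g} ({self.mode}, {self.n_iterations} iterations)"
        )


_STATS = {
    "mean_diff": np.mean,
    "median_diff": np.median,
}


def _tail_count(null: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if alternative == "greater":
        return int(np.sum(null >= observed - 1e-12))
    if alternative == "less":
        return int(np.sum(null <= observed + 1e-12))
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_test(
    a: GroupSample,
    b: GroupSample,
    statistic: str = "mean_diff",
    n_iterations: int = 10_000,
    seed: int = 0,
    alternative: str = "two_sided",
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> PermutationResult:
    """Two-group permutation test of ``statistic(a) - statistic(b)``.

    Exhaustive when C(n_a+n_b, n_a) <= ``exhaustive_limit`` (exact p, no
    smoothing); Monte-Carlo otherwise, with p = (1 + hits)/(1 + iterations).
    Deterministic for a fixed seed.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATS)}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    stat = _STATS[statistic]
    observed = float(stat(a.values) - stat(b.values))
    pooled = np.concatenate([a.values, b.values])
    n_a, n_total = a.n, a.n + b.n

    n_combos = math.comb(n_total, n_a)
    if n_combos <= exhaustive_limit:
        total = pooled.sum()
        null = np.empty(n_combos)
        for i, idx in enumerate(combinations(range(n_total), n_a)):
            sel = pooled[list(idx)]
            if statistic == "mean_diff":
                null[i] = sel.mean() - (total - sel.sum()) / b.n
            else:
                rest = np.delete(pooled, list(idx))
                null[i] = stat(sel) - stat(rest)
        hits = _tail_count(null, observed, alternative)
        p = hits / n_combos
        mode, n_iter_used, used_seed = "exhaustive", n_combos, None
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(pooled, (n_iterations, n_total)), axis=1)
        ga, gb = perms[:, :n_a], perms[:, n_a:]
        if statistic == "mean_diff":
            null = ga.mean(axis=1) - gb.mean(axis=1)
        else:
            null = np.median(ga, axis=1) - np.median(gb, axis=1)
        hits = _tail_count(null, observed, alternative)
        p = (1 + hits) / (1 + n_iterations)
        mode, n_iter_used, used_seed = "monte_carlo", n_iterations, seed

    q = np.quantile(null, [0.025, 0.5, 0.975])
    return PermutationResult(
        statistic_name=statistic,
        observed=observed,
        p_value=float(p),
        n_iterations=n_iter_used,
        mode=mode,
        seed=used_seed,
        null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
    )


def compare_cbf_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: PermutationConfig | None = None,
    seed: int = 0,
    label_a: str = "A",
    label_b: str = "B",
    exchange_unit: str = "roi",
) -> tuple[PermutationResult, dict]:
    """Compare two per-ROI CBF tables (QC-passing rows only).

    ``exchange_unit="roi"`` (default) permutes individual ROI values, matching
    the per-ROI reporting grain; ``"video"`` permutes per-video mean CBFs
    instead, a conservative alternative when within-video correlation is a
    concern. Returns the permutation result and a summary dict with per-group
    n, video count, and mean +- SEM.
    """
    if config is None:
        config = PermutationConfig()
    if exchange_unit not in ("roi", "video"):
        raise ValueError(f"exchange_unit must be 'roi' or 'video', got {exchange_unit!r}")

    def _group(table: pd.DataFrame, label: str) -> tuple[GroupSample, dict]:
        qc = table[table["passed_qc"].astype(bool)]
        if qc.empty:
            raise ValueError(f"group {label!r} has no QC-passing ROIs")
        if exchange_unit == "video" and "video_id" in qc:
            vals = qc.groupby("video_id")["cbf_hz"].mean().to_numpy(dtype=np.float64)
        else:
            vals = qc["cbf_hz"].to_numpy(dtype=np.float64)
        summary = {
            "label": label,
            "n_rois": int(len(qc)),
            "n_videos": int(qc["video_id"].nunique()) if "video_id" in qc else 1,
            "mean_cbf_hz": float(vals.mean()),
            "sem_cbf_hz": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
        }
        return GroupSample(label=label, values=vals, unit="Hz"), summary

    ga, sa = _group(table_a, label_a)
    gb, sb = _group(table_b, label_b)
    result = permutation_test(
        ga,
        gb,
        statistic=config.statistic,
        n_iterations=config.n_iterations,
        seed=seed,
        alternative=config.alternative,
        exhaustive_limit=config.exhaustive_limit,
    )
    summary = {
        "groups": [sa, sb],
        "mean_difference_hz": sa["mean_cbf_hz"] - sb["mean_cbf_hz"],
        "p_value": result.p_value,
    }
    return result, summary
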