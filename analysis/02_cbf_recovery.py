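"""Frequency-recovery sweep: how well does the ROI/FFT estimator recover a
known ciliary beat frequency across beat rates and noise levels?

Simulates one 1,000-frame video (1,000 Hz) per cell of a true-CBF (10-60 Hz)
x noise-sigma (0, 0.05, 0.1) grid, runs the full pipeline on each, and writes
per-ROI errors to results/cbf_recovery.csv with a per-cell summary printed.
Run from the repository root:  python analysis/02_cbf_recovery.py
"""

from pathlib import Path

from ciliaflow.benchmarks import cbf_recovery_grid

SEED = 0
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = cbf_recovery_grid(seed=SEED)
    grid.to_csv(OUT / "cbf_recovery.csv", index=False)

    summary = grid.groupby(["true_cbf_hz", "noise_sigma"])["abs_error_hz"].agg(
        ["count", "median", "max"]
    )
    print(summary.to_string())
    print(f"\noverall median |error|: {grid['abs_error_hz'].median():.3f} Hz "
          f"(bin width 1.0 Hz) over {len(grid)} QC-passing ROIs")
    clean = grid[grid["noise_sigma"] == 0.0]
    print(f"noise-free max |error|: {clean['abs_error_hz'].max():.3f} Hz")
    print(f"wrote {OUT / 'cbf_recovery.csv'}")


if __name__ == "__main__":
    main()
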