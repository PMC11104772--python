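"""Generate the example synthetic scenarios used throughout the analysis.

Writes one wt_like (28 Hz) and one ko_like (34 Hz) ciliary-beating video with
their ependymal-layer masks, and one five-bead flow movie, under
scratch/scenarios/ (TIFF stacks are bulky, so they live outside results/).
Run from the repository root:  python analysis/01_simulate_scenarios.py
"""

import json
from pathlib import Path

from ciliaflow import BeadSimParams, simulate_bead_movie, simulate_cilia_video
from ciliaflow.synthetic_data import cilia_preset
from ciliaflow.video_io import write_mask, write_stack

SEED = 0
OUT = Path("scratch/scenarios")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for preset in ("wt_like", "ko_like"):
        params = cilia_preset(preset, seed=SEED)
        stack, mask, truth = simulate_cilia_video(params)
        write_stack(stack, OUT / f"{preset}.tif")
        write_mask(mask, OUT / f"{preset}_mask.tif")
        (OUT / f"{preset}_truth.json").write_text(
            json.dumps({k: v for k, v in truth.items() if k != "amplitude_map"}, default=list)
        )
        print(f"{preset}: {stack.n_frames} frames @ {stack.frame_rate_hz:.0f} Hz, "
              f"true CBF {truth['cbf_hz']} Hz -> {OUT / (preset + '.tif')}")

    bead_params = BeadSimParams(speeds_um_s=(10.0, 20.0, 30.0, 40.0, 50.0), seed=SEED)
    bead_stack, bead_truth = simulate_bead_movie(bead_params)
    write_stack(bead_stack, OUT / "beads.tif")
    bead_truth.to_csv(OUT / "beads_truth.csv", index=False)
    print(f"beads: {bead_stack.n_frames} frames @ {1/bead_stack.frame_rate_hz:.1f} s interval, "
          f"commanded speeds {bead_params.speeds_um_s} um/s -> {OUT / 'beads.tif'}")


if __name__ == "__main__":
    main()
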