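# ciliaflow

Quantification of ependymal ciliary beating and near-wall cerebrospinal-fluid
(CSF) flow from microscopy video.

Ependymal cells lining the brain ventricles carry motile cilia whose
coordinated beating propels CSF; changes in ciliary beat frequency (CBF) or in
the flow they drive are central read-outs in hydrocephalus and ciliopathy
studies. `ciliaflow` implements the two standard video assays behind such
read-outs, plus the statistics to compare groups:

* **CBF from high-speed video.** Beating cilia modulate pixel brightness at
  the beat frequency. The pipeline places 16–20 regions of interest (ROIs) of
  11×11 pixels, centers ≥30 px apart, confined to an ependymal-layer mask;
  extracts each ROI's mean-brightness trace x(t); and estimates

  CBF = argmax_{f ∈ (f_lo, f_hi]} P(f),  P(f) = one-sided periodogram of the
  detrended, Hann-windowed trace,

  with a peak/median signal-to-noise QC flag per ROI. With a ~1,000 fps
  acquisition and N = 1,000 frames the frequency resolution is 1 Hz.
* **Bead-flow speed.** Fluorescent microbeads advected over the ventricular
  wall (frames at 0.2 s intervals, i.e. 5 fps) are detected per frame
  (Gaussian smoothing, relative-threshold local maxima, sub-pixel centroids),
  linked into tracks by mutual nearest neighbours, and each track's speed is
  the mean frame-to-frame displacement × pixel size / frame interval (μm/s).
* **Permutation test.** Two groups of per-ROI CBFs (or per-track speeds) are
  compared by randomly reassigning the pooled values to groups of the original
  sizes (default 10,000 iterations; exact enumeration on small inputs).

Because such studies rarely deposit raw video, the package ships first-class
synthetic generators — metachronal beating videos and constant-velocity bead
movies with known ground truth — so every stage is validated by parameter
recovery.

## Worked example

```bash
# simulate a beating video (true CBF 28 Hz, 1000 frames @ 1000 fps)
ciliaflow simulate --scenario wt_like --out-dir scene --seed 3
# run the CBF pipeline on it
ciliaflow cbf scene/cilia.tif scene/mask.tif --out-dir run --seed 1
```

prints

```
wrote wt_like scenario to scene
18/18 ROIs passed QC; table in run/cbf_table.csv
```

Eighteen ROIs were placed inside the ependymal band, all passed the
spectral-quality check, and `run/cbf_table.csv` holds one row per ROI with
`cbf_hz` (here 28.0 for every ROI — the simulated truth), its peak power and
SNR, and the 1 Hz frequency resolution. `run/run_manifest.json` records the
config hash, seed and input checksums needed to reproduce the run
byte-for-byte.

Comparing two cohorts end-to-end (10 simulated videos per group at 28 vs
34 Hz — `python analysis/04_group_comparison.py`) prints:

```
ko_like: 34.00 +- 0.000 Hz (n = 172 ROIs from 10 videos)
wt_like: 28.00 +- 0.000 Hz (n = 168 ROIs from 10 videos)
observed mean difference: 6.00 Hz (true 6.00 Hz), permutation p = 0.0001
```

The same library surface is importable (`ciliaflow.analyze_video`,
`ciliaflow.analyze_bead_movie`, `ciliaflow.permutation_test`, ...); the
numbered scripts under `analysis/` are thin drivers that run each study stage
and write tables under `results/`.

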