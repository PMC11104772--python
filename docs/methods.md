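# Methods

## Signal model for CBF estimation

A field of beating cilia modulates the brightness of the pixels it overlies
approximately sinusoidally at the beat frequency, with a spatially varying
amplitude and a phase that drifts linearly across the field (the metachronal
wave). The estimator therefore treats each ROI's mean-brightness trace as a
noisy sinusoid and reads the beat frequency off the dominant peak of its
power spectrum. Averaging over an 11×11-pixel window attenuates uncorrelated
sensor noise by the window size (√121 = 11-fold in SD) while the coherent
oscillation survives, because the metachronal phase varies slowly on that
scale: a linear phase gradient k across a window of side s multiplies the
averaged oscillation amplitude by a product of Dirichlet-kernel factors
(≈0.85 at |k| ≈ 0.18 rad/px, s = 11) but never changes its frequency.

Pipeline per video: ROI placement → trace extraction → detrend → windowed
periodogram → band-limited peak pick with QC.

### ROI placement

Valid centers (those whose full footprint lies inside the layer mask and the
frame) are computed by square-window erosion of the mask; a seeded permutation
of those centers is consumed greedily, accepting every candidate ≥ `min_sep`
(Euclidean, center-to-center) from all previously accepted ones, until
`n_max` are placed or the attempt budget (10,000 per requested ROI) is spent.
Sampling candidates without replacement bounds the runtime on dense masks
while keeping acceptance deterministic for a fixed seed. If fewer than
`n_min` placements fit, the shorter set is returned with an "under-sampled"
warning; zero placements is an error. Center-to-center separation is the
stricter and simpler reading of "windows apart" (edge-to-edge would allow
closer centers); the knob `separation_mode` records the choice. User-supplied
ROI CSVs bypass the sampler so manual placements remain reproducible.

### Spectral estimation

* **Detrend** (default `linear`): removes the least-squares line, killing DC
  and slow photobleaching/illumination drift that would otherwise leak into
  the low-frequency bins.
* **Window** (default `hann`, periodic): bounds spectral leakage for beat
  frequencies that do not fall on a bin center. The rectangular window is
  retained because its periodogram obeys Parseval's identity exactly, which
  the tests exploit.
* **Periodogram**: one-sided, `P[k] = s_k |F[k]|² / Σw²` with `s_k = 2`
  except at DC and Nyquist. Under this normalization a rect-windowed
  unit-amplitude bin-centered sinusoid of length N concentrates its energy
  N/2 in one bin, and total power equals trace energy.
* **Peak pick**: maximum power among bins with `f_lo < f ≤ f_hi`
  (default 5–100 Hz: murine ependymal CBF sits well inside, while DC drift
  and mains/camera flicker sit outside). Ties break toward the lower
  frequency. No zero padding: the resolution `frame_rate/N` is reported with
  every estimate rather than interpolated away.
* **QC**: `snr = peak / median(in-band power)`, flagged pass at
  `snr ≥ snr_min` (default 20). The null here is a flat noise spectrum, whose
  periodogram bins are approximately i.i.d. exponential; the max/median of
  ~100 such bins concentrates near ln(100)/ln 2 ≈ 6.6, so a threshold of 3
  would pass nearly every non-beating ROI. 20 rejects noise-only ROIs with
  pass probability ~10⁻⁴ while genuine beating peaks exceed the median floor
  by 3–5 orders of magnitude. Failed ROIs are reported with a flag, never
  silently dropped.

## Bead tracking

* **Detection**: Gaussian smoothing at the expected spot scale `sigma_px`
  (default 2 px, matching a ~2 μm bead imaged near that scale); the median of
  the smoothed frame is taken as background, and local maxima of the excess
  above `max(threshold_rel × peak excess, 8 robust SDs)` are kept. The
  relative threshold makes detection invariant to global intensity rescaling;
  the 8·MAD floor (the expected maximum of ~10⁵ smoothed-noise pixels is
  ≈5 SDs) keeps empty frames empty. Centroids are refined by an
  intensity-weighted mean of the background-subtracted excess over a
  (2⌈σ⌉+1)² neighbourhood — subtracting background first matters, as a flat
  offset drags every centroid toward the window center and biases speeds low.
* **Linking**: mutual nearest neighbours between consecutive frames within a
  displacement gate, ambiguities broken by smaller displacement then lower
  index; unmatched detections open new tracks; tracks shorter than `min_len`
  (default 3) are discarded; no gap closing. Greedy mutual-NN is chosen over
  global assignment because bead preparations are sparse and the simple rule
  is deterministic and auditable.
* **Speed** (default `path` mode): mean consecutive Euclidean displacement ×
  pixel size / frame interval — the automated analogue of manual
  frame-by-frame tracking. `net` mode (end-to-end displacement over elapsed
  time) is available; it is lower on jittered tracks since path length is
  convex in the noise.

Positional jitter inflates path speed by ≈ σ²_eff/d per step (d = true
displacement in px, σ²_eff the per-axis variance of the step noise); at the
default jitter (0.3 px) and the slowest benchmark speed the bias is ~2%,
which bounds the recovery error claimed below.

## Permutation testing

Observed statistic: `stat(a) − stat(b)` with `mean_diff` (default) or
`median_diff`. When the number of distinct group reassignments C(n_a+n_b, n_a)
is ≤ 200,000 the null is enumerated completely and p is exact (k/m, no
smoothing); otherwise 10,000 Monte-Carlo reassignments with add-one smoothing,
p = (1 + #{null ≥ observed}) / (1 + iterations), so p is never zero and the
estimator is slightly conservative. Two-sided comparison uses |statistic|.
The default exchange unit is the individual measurement (ROI or track),
matching the per-ROI reporting grain; a video-level mode (permuting per-video
means) is provided because ROI-level exchange ignores within-video
correlation — with it, simulated per-video frequencies are identical within a
video, the most extreme case of such correlation. No multiple-testing
correction is applied (one test per comparison).

## Synthetic generators and what they do (not) show

* **Cilia video**: `I = baseline + A(r,c)·sin(2π·f·t/rate + k·(r,c)) + ε`,
  A a seeded Gaussian-smoothed random field rescaled to
  [amplitude/2, amplitude] on the band and zero outside, ε Gaussian, clipped
  to [0,1]. Defaults: 1,000 frames at 1,000 Hz, 160×160 px, band rows 20–140
  (room for ~20 ROIs at 30 px separation), baseline 0.5, amplitude 0.2,
  noise σ 0.05, wave vector (0.15, 0.10) rad/px, texture scale 8 px. The
  parameter guard `baseline ± (amplitude + 3σ) ⊂ [0,1]` keeps clipping
  probability ≈ 0.3%, so spectra stay interpretable. All pixels share one
  frequency: sufficient to exercise the estimator, not a model of
  per-cell frequency scatter, waveform asymmetry, drift, or focus changes —
  recovery results bound estimator error under the stated model, not
  biological variability.
* **Bead movie**: spots advance `speed·interval/pixel_size` px per frame plus
  per-axis N(0, jitter²), rendered as Gaussian spots (σ 2 px, amplitude 0.8)
  on background 0.1 with sensor noise σ 0.01; beads leaving the frame stop
  rendering and the truth table marks the exit. Default pixel size 0.4 μm at
  0.2 s intervals keeps the slowest benchmark speed (10 μm/s) at 5 px/frame,
  where the jitter-induced path-length bias stays under the 5% recovery
  bound. Not modelled: flow heterogeneity, bead aggregation, defocus,
  photobleaching, crossing trajectories.
* **CBF group draws**: seeded normals truncated at 0, for exercising the
  permutation machinery directly.
* Scenario presets `wt_like` (28 Hz) and `ko_like` (34 Hz) are fixtures in
  the physiological range chosen to give a clear 6 Hz contrast; they are not
  measurements.

## Benchmark problem sizes

The recovery benchmarks (in `ciliaflow.benchmarks`, driven by `analysis/` and
`scripts/acceptance.py`) use: one video per cell of the 11×3 CBF×noise grid;
10 videos per cohort for the effect-detection contrast; 400 replicates for
the type-I-error estimate; 1,000 seeded samplings for the ROI-constraint
audit; 6 speed levels × 3 beads for speed recovery; 6 movies × 4 beads per
arm for the toxin contrast. These sizes give stable estimates (hundreds of
ROIs/tracks per quantity) at desk scale.

## Determinism and numerics

Every generator and every sampler is a pure function of its parameters
including the seed; pipeline stages draw their seeds from the single config
seed through a stage-name-keyed SHA-256 hash, so each stage is independently
reproducible. CSV/JSON outputs are byte-identical across reruns of the same
config and seed. Degenerate inputs are handled explicitly: all-zero traces
fail QC with `cbf_hz = NaN`; empty masks and all-QC-failed groups raise;
empty bead movies yield empty tables with headers. 16-bit TIFF round-trips
quantize intensities to ≤1/65535 per pixel, below every tolerance used.

## Known limitations

No image registration or drift correction (ROIs are static); no gap closing
or crossing resolution in linking; ROI-level permutation understates
within-video correlation in real data (use the video-level mode when that
matters); the frequency estimator reports one dominant peak per ROI and will
track the stronger component if two frequencies genuinely coexist in a
window.
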