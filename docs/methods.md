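# Methods

This note describes the models implemented by `chemotax`, the meaning and
defaults of every parameter, the numerical choices, and the limitations of
the synthetic data generator.

## 1. Device geometry (`geometry.py`)

The device is modelled as a flat 2-D field partitioned into half-open
axis-aligned rectangles `[x0, x1) × [y0, y1)`, so every point belongs to
exactly one region: `CENTER` (the loading chamber), `CHAMBER_LEFT` /
`CHAMBER_RIGHT` (chemoattractant chambers), `CHANNEL_LEFT` /
`CHANNEL_RIGHT` (migration channels) and `BACKGROUND` (walls between
channels). Coordinates outside the field raise `DomainError` rather than
silently mapping to background. `DeviceGeometry.validate()` returns a list
of violations (overlaps, channels not abutting both chambers, channels
taller than the field) instead of raising, so configurations can be linted.

Defaults (µm unless noted): 10 channels per side, channel length 500,
channel width 12, chamber width 200 (each of the three chambers), field
height 700, pixel size 0.65 µm/px. Channels are evenly spaced at pitch
`H/(n+1)`. These match the scale of a typical two-chemoattractant chip:
channels long and narrow enough that migration through them is committed
and quasi-one-dimensional.

## 2. Synthetic motility and imaging (`synthdata.py`)

### Biased persistent random walk

Each cell takes one step per frame interval. Its heading is drawn from a
von Mises distribution whose mean direction is the normalized sum of

* `persistence ·` (previous unit heading), and
* a drift of magnitude `bias_right − bias_left` along +x (toward the LTB4
  side when positive),

with concentration `turn_kappa` (`inf` = noise-free heading). Step length
is `N(speed_mean, speed_sd) · frame_interval`, truncated at zero. Inside a
channel, motion collapses to the channel axis (quasi-1-D). Walls are
reflective; a cell in the center chamber crosses a channel mouth only with
probability `channel_entry_prob` per attempted crossing (reflection
candidates never tunnel into channels), which models the entry barrier of
a 12-µm constriction.

Motility defaults: `n_cells=100`, `speed_mean=6.5` µm/min, `speed_sd=1.5`,
`persistence=0.6`, `bias_left=0.05`, `bias_right=0.3`, `turn_kappa=4.0`,
`channel_entry_prob=0.2`, cell radius `N(3.0, 0.4)` µm. The bias and entry
defaults were calibrated once, against the qualitative pattern expected of
the assay (strong LTB4-side migration ≈ 20 %, weak fMLP-side migration
≈ 1 %, near-zero unbiased control) — not against any test threshold.

### Rendering

Each cell becomes an isotropic Gaussian blob. The blob width combines the
optics and the cell size: `σ = hypot(psf_sigma, r / (2·pixel_size))` (px).
Total integrated intensity is `intensity_per_um2 · πr² / pixel_size²`
counts, so the peak amplitude is that total over `2πσ²`. Images add a
constant `background_level`, optional Poisson shot noise on the expected
counts, and Gaussian read noise of standard deviation `gaussian_sd`.
Acquisition defaults: 4-min frame interval, 240-min duration (61 frames),
`psf_sigma=2` px, `background_level=100`, `intensity_per_um2=300`,
`gaussian_sd=3`, shot noise on.

### What the generator does and does not emulate

It reproduces the features the analysis chain must be robust to: realistic
blob SNR, cell-size variability, crowding in the loading chamber, biased
and persistent motion, channel confinement, and frame-rate aliasing of
curved paths. It does **not** model cell division or death, cell–cell
adhesion or volume exclusion, intensity photobleaching, focus drift, or
the chemoattractant field feeding back on motility (bias is constant in
time, consistent with the near-steady gradients of the real device after
the first minutes).

## 3. Detection (`detect.py`)

Frames are filtered with a Laplacian-of-Gaussian (`scipy.ndimage.
gaussian_laplace`) at `log_sigma=3` px, chosen near the expected blob
scale (σ ≈ 3.6 px for a 3-µm cell at 0.65 µm/px). Bright blobs give a
negative LoG basin; cell interiors are pixels with response below
`−zc_amplitude_threshold`, delimited by the zero-crossing contour of the
response. Connected components outside `[min_area, max_area] = [9, 400]`
px² are rejected. Sub-pixel centers are intensity-weighted centroids of
the background-subtracted image over each component; each detection is
labelled with its device region, and detections in `BACKGROUND` are
discarded.

The default `zc_amplitude_threshold=1.0` was set from first principles:
the LoG at σ=3 attenuates white noise by a measured gain ≈ 0.015, so with
read noise 3 counts the filtered noise floor is ≈ 0.05 counts and the
threshold sits far above it, while a default blob (peak ≈ 216 counts,
basin depth ≈ 0.054 × peak ≈ 12 counts) clears it comfortably.

## 4. Tracking (`track.py`)

Detections in consecutive frames are linked greedily by nearest neighbour
in the feature space `(x, y, area_weight · √area)` — the area term (in µm
via `√(px²)`) preserves identity when differently sized cells pass close
by. Pairs beyond `gate_radius` (spatial distance) are forbidden; the
greedy order is by ascending feature distance with deterministic
tie-breaking. The unit suite proves the greedy solution equals the
exhaustive optimal matching in the intended low-density regime (per-frame
displacement below half the inter-cell spacing). `max_gap` allows
bridging frames with a missed detection, with a proportionally widened
gate. Defaults: `gate_radius=20` µm, `area_weight=1.0`, `max_gap=0`.
The gate must exceed the expected per-frame displacement
(`speed · frame_interval`); the acceptance script sets it to 40 µm for
the default 6.5 µm/min speed at 4-min frames.

Per-track velocity is total path length over elapsed time; straightness is
net displacement over path length. Tracks with fewer than two points or
zero path length are excluded from the metrics table (counted in
`attrs["n_excluded"]`).

## 5. Migration statistics (`metrics.py`)

`count_by_region` tallies region-labelled detections per frame; the
denominator `n_total` of all percentages is the center-chamber count at
frame 0. `percent_migrated` uses chamber + channels at the last frame.
`accumulation_rate` fits an OLS line to the chamber-only percentage over
every contiguous frame-aligned window of exactly `window` minutes (default
60) and returns the maximum slope in %/h with the earliest window start
achieving it. `migration_ratio` is fMLP-% over LTB4-%, reported as missing
(`None`) when the denominator is zero — never infinity. `group_summary`
reports mean ± SEM per experimental group with one-way ANOVA and Tukey HSD
(`scipy.stats.f_oneway` / `tukey_hsd`, α = 0.05); groups with n < 2 are
excluded and flagged, and the degenerate zero-within-variance case is
reported as F = ∞, p = 0.

## 6. Gradient model (`gradient.py`)

Chemoattractant transport along a channel is modelled as 1-D diffusion
with fixed Dirichlet boundaries (source chamber at `source_concentration`,
default 100 nM; sink at 0), solved by an explicit finite-difference scheme.
The CFL number `D·Δt/Δx²` must be ≤ 0.5; violations raise `StabilityError`
naming the required `time_step`. Defaults: `diffusivity=300` µm²/s,
`channel_length=500` µm, `grid_spacing=5` µm, `time_step=0.02` s. The
solver is verified against the closed-form Fourier-series transient
(RMS error < 0.01 % of the boundary concentration) and the steady state
`C(x) = C0 + (CL − C0)·x/L`, whose slope is diffusivity-independent —
which is why equal loading concentrations of fMLP and LTB4 yield equal
steady gradients despite different molecular weights. Diffusivities scale
as `D ∝ MW^(−1/3)` (Stokes–Einstein with radius ∝ MW^(1/3)) via
`diffusivity_from_mw`, anchored to a reference species (default 10-kDa
dextran). `quantify_gradient` fits a line (slope, intercept, R²) to a
profile, or to an image averaged across a channel ROI.

## 7. Pipeline and reproducibility (`pipeline.py`, `cli.py`)

`run_pipeline(config, out_dir, seed)` validates the configuration
(`validate_config` returns dotted-path violations and never raises on
content), then runs simulate → render → detect → track → metrics →
gradient, writing every artifact plus `run_manifest.json` with the package
version, seed, a SHA-256 parameter hash, and per-stage counts. The same
config + seed is byte-identical across runs. Group/sex motility presets
(`GROUP_PRESETS`) are synthetic demonstration bundles ordering the
readouts qualitatively; they encode no measured animal data.

## 8. Problem sizes

* Unit tests use a 3-channel device (120-µm channels, 200-µm field) and
  16-frame acquisitions; the full suite runs in ≈ 4 min.
* Acceptance tests use devices up to 600–800 µm chambers at 1 µm/px with
  61-frame protocols; ≈ 2.5 min.
* `scripts/acceptance.py` uses a 4-channel, 150-µm-channel device, 60
  cells, 61 frames, plus an unbiased control and the gradient model;
  ≈ 90 s single-threaded.

## 9. Limitations

* The walk model has no cell–cell interactions, so crowded loading
  chambers under-represent merged detections relative to real data.
* Detection assumes approximately circular cells; strongly elongated
  cells in channels are localized by their intensity centroid only.
* Greedy linking is optimal only in the low-density regime; dense scenes
  with displacements comparable to cell spacing need a global assignment
  solver, which is out of scope here.
* The gradient model is 1-D and source/sink-clamped; chamber depletion
  and flow transients are not modelled.
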