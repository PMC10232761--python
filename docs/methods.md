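# Methods

## Acquisition model

An excitation-multiplexed recording cycles through C laser lines while a
single InGaAs detector collects all emission behind one long-pass filter.
The model assumes **zero inter-frame dead time**: the cycle period is the sum
of the per-channel exposures, `frame_period_ms` defaults to `exposure_ms`,
and the merged (all-channel) frame rate is `1000 / Σ exposure_ms`. Reported
as an integer it is the *floor* of that value — a four-channel cycle at
7.8 ms per frame runs at 32.05 fps and is reported as 32 — while
`effective_framerate_exact` keeps full precision. Zero dead time is a
declared assumption, not a measured fact; if a detector has appreciable
readout time the configured exposures should be inflated accordingly.

The phase convention is fixed once: `offset` is the index of the cycle
channel that illuminated raw frame 0, so frame *i* belongs to channel
`(i + offset) mod C`. Trailing partial cycles are kept (per-channel lengths
may differ by one) rather than discarded.

### Offset estimation

The cyclic grouping of frames is *identical* for every candidate offset —
only the channel labels permute — so the starting phase cannot be inferred
from any statistic of the partition alone. `estimate_offset` therefore
matches the observed per-residue-class mean intensities against a
per-channel **reference brightness** (Pearson correlation over the C cyclic
labelings). The reference should come from a correctly phased calibration
recording; absent one, relative laser power densities from the config are
used, under the stated assumption that collected emission scales with
excitation power. Ties (e.g. a constant recording) break to offset 0.
Strict cycle periodicity is assumed throughout; `channel_separation_report`
flags overlapping per-channel intensity statistics as a dropped-frame
symptom but no resynchronisation is attempted.

## Exposure simulation

A simulated exposure of (2k+1)·e replaces frame *t* by the arithmetic
**mean** of frames t−k…t+k. A mean rather than a sum keeps display windows
comparable across window sizes. Windows are symmetric and odd; the default
`"drop"` edge mode emits T−2k interior frames (partial windows at the edges
would be biased), `"truncate"` keeps all T frames averaging what is
available. Output is floating point; `quantize_counts` (round-half-even)
is an explicit separate step. Both `exposure_ms` and `frame_period_ms` of
the output are scaled by the window — the output represents the effective
integration, not the original frame spacing. `window_for_exposure` returns
the odd window nearest to `target/base`, rounding exact ties upward.

## Unmixing

`unmix_pixelwise` solves y = M·a per pixel by ordinary least squares
(`numpy.linalg.lstsq` on the stacked pixel matrix) or, with `nonneg=True`,
by active-set NNLS per pixel (`scipy.optimize.nnls`), whose solution
satisfies the KKT conditions. M must have at least as many channels as
fluorophores and full column rank; the error message carries the condition
number. The stage is **off by default**: an acquisition tuned so channels
are visually separable needs no unmixing, and because fluorophore response
deviates from linearity across organ geometries, unmixed abundances should
not be treated as quantitative comparisons *between* organs.
`crosstalk_report` estimates M from user-supplied reference regions where
one fluorophore dominates (column = region mean per channel, normalised to
its maximum) as a diagnostic of residual crosstalk.

## Markers and filtering

Coordinates are 0-based pixel indices, x = column (rightward), y = row
(downward), origin at the top-left pixel centre. The DeepLabCut CSV dialect
(scorer/bodyparts/coords header rows) and a long-format CSV parse to
identical tables. A frame is retained iff **every required bodypart** has
likelihood ≥ the threshold; the default 0.9 is the conventional
pose-estimation cutoff and is configurable. Dropped frames are excluded,
never interpolated, because a misplaced marker corrupts the rigid alignment;
`interpolate_gaps` can optionally bridge gaps up to a configurable length,
marking interpolated rows with likelihood 0.

## Rigid alignment

The forward map is p′ = centre + R(θ)·(p + (dx,dy) − centre): translate the
target marker to the output centre ((W−1)/2, (H−1)/2), then rotate about the
centre. θ is chosen so the target→anterior vector maps to the −y ("up")
direction; with x right and y down, θ = −π/2 − atan2(v_y, v_x), wrapped to
(−π, π]. Two markers determine the heading deterministically (the default);
with `heading="procrustes"` the rotation is instead the 2-D orthogonal
Procrustes fit of all anterior+peripheral marker offsets against the first
valid frame's posture (pre-rotated to face up), which averages marker noise
down by roughly √n. Target and anterior closer than 1e-6 px yield an
*invalid* transform, never an arbitrary rotation.

Resampling inverts the map per output pixel through
`scipy.ndimage.map_coordinates` (bilinear by default, nearest optional);
pixels whose source location falls outside the input frame are recorded in a
boolean fill mask rather than filled with zeros. Nearest-neighbour
resampling under an integer translation is an exact pixel shift and
conserves total intensity on the overlapping support. Ventral-view
recordings can be mirrored (x-flip) before alignment with `mirror=True`;
dorsal and ventral views are otherwise treated identically.

## ROI extraction and the threshold baseline

ROIs are polygons rasterised by the **even-odd rule at pixel centres**
(vectorised crossing-number test, half-open edge convention), or explicit
boolean masks; the rule is fixed so ROI areas are deterministic across
implementations. Per-frame mean and median are computed only over ROI
pixels not covered by the fill mask; the median over an even count is the
standard midpoint. A frame whose ROI is fully masked is flagged invalid
with NaN statistics — gaps propagate as absent/invalid rows, never zeros.

`threshold_baseline` segments each raw frame at a fixed count level and
reports the largest 8-connected component's area and centroid
(`scipy.ndimage.label`). It is retained as the comparison baseline the
marker pipeline replaces: its centroid follows whatever exceeds the level —
pose-dependent brightness, residual tail signal, low signal-to-background —
which the test suite reproduces on a phantom with a bright tail blob.

## Phantom generator

The phantom is a rigid elliptical body (default half-axes 28 × 52 px on a
144 × 112 px canvas — a scaled-down field of view keeping the body/canvas
proportions of whole-mouse imaging) carrying 2-D Gaussian organ emitters
fixed in body coordinates, each assigned a fluorophore, a peak emission in
counts and an optional temporal profile. Pose follows a random walk
(default step σ 1.5 px/frame, turn σ 0.06 rad/frame, reflecting off a
margin). The default spec mirrors the four-fluorophore experiment: lasers
785/892/968/1064 nm at 49/81/113/165 mW/cm², 7.8 ms per frame, 1150 nm
long-pass, organs labelled intestines (ICG), liver (JuloChrom5),
vasculature (Chrom7) and peritoneal space (JuloFlav7) with peak counts of
order the corresponding display windows (800–1800 over a 100-count
background).

The expected value of raw frame *t* in its active channel c is
`background + Σ_f M[c,f]·abundance_f(pixel, t)`; Poisson shot noise is
applied to the expectation, Gaussian read noise (default σ 5 counts) added,
and the result clipped and quantised to uint16. Marker tables contain exact
organ centres plus head/tail-base/flank body points at likelihood 1;
`corrupt_markers` models pose-estimation error as coordinate jitter plus a
per-row miss probability that draws likelihood below the filter threshold.
All randomness derives from a single seed through `numpy` `SeedSequence`
substreams (trajectory / shot / read), so identical seeds are bit-identical.

Not modelled: tissue scattering and absorption, depth-dependent blur, body
deformation, nonlinear fluorophore response. Tests passing on phantoms
demonstrate correctness of the processing chain, not robustness to those
real-data effects.

## Numerical and testing choices

* Pose-recovery accuracy under marker jitter is assessed as **mean absolute
  error over frames** (rotation and translation separately): with the
  translation determined by a single jittered marker, per-frame maxima are
  order statistics of the jitter itself and say nothing about the estimator.
  With exact markers the centring is checked per-frame at 1e-9 px.
* Recovery tests use 200–240-frame phantoms on ~144 × 112 px canvases —
  sizes at which every stage's behaviour is already asymptotic while the
  whole suite runs in seconds.
* Shot-noise SNR quoted in tests is √(peak counts); peak 400 ⇒ SNR 20.
* Angles are wrapped to (−π, π]; the degenerate-heading cutoff is 1e-6 px;
  offset-estimation ties break to the smallest offset.
* Display scaling is linear (no gamma) between per-channel (vmin, vmax);
  composites are additive per RGB primary, clipped to [0, 1]; default
  channel colours magenta/red/green/blue in cycle order.

## Known limitations

* No dropped-frame or trigger-jitter recovery: a slipped cycle silently
  mixes channels (the separation report only warns).
* Alignment is strictly rigid; peripheral-limb motion relative to the trunk
  is not corrected.
* Cross-channel motion within one ~31 ms cycle is uncorrected; channels of
  one merged frame are up to C−1 frame periods apart.
* Unmixed abundances are not quantitative across organs (nonlinear response
  is not modelled, only documented).
* `estimate_offset` needs a brightness reference; with the power-density
  fallback it is only as good as the emission∝power assumption.
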