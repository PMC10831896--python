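# Methods

This note records the models implemented in `mirtrack`, the conventions
and defaults behind them, the design choices that were genuinely open, and
the limits of what the synthetic validation shows.

## Scope and data model

The pipeline analyzes time-lapse fluorescence movies of individual miRNA
particles in living cells (20 Hz, pixel 0.16 μm on the emulated
100×/1.49 NA system), binned photon-count traces from a confocal volume,
and label-image ROIs. All positions are in micrometers (x = column·pixel
size, y = row·pixel size, origin at the center of pixel (0,0)), frames are
0-based, and every tabular output has fixed column order and 6-decimal
formatting so that reruns are byte-identical.

## Synthetic microscope

The generators provide ground truth for every stage; all are deterministic
under a fixed seed.

**Trajectories.** Four motion modes at frame interval Δt = 0.05 s:
stationary (no movement), free (Brownian increments, per-axis variance
2DΔt), directed (Brownian plus drift vΔt; motor transport has both, pure
drift via D = 0), and confined (Brownian steps radially reflected at a
circular boundary of radius R_conf). Reflection preserves step-length
statistics and, in the small-step limit, samples the disc uniformly; when
the per-frame step approaches R_conf the stationary density develops a
slight inward bias, so "fast exploration" fixtures use steps ≲ R/3.

**Movies.** Each emitter is rendered as an error-function-integrated 2-D
Gaussian (PSF σ 0.13 μm) over the pixel grid — integration, not point
sampling, keeps photometric centroids unbiased — and pixel values are
Poisson draws of emitter-plus-background expectation. Defaults
(3000 photons/spot/frame on a background of 10/pixel) make detection
comfortable; the brightness of the real movies is not on record, so this
is an explicit assumption. No camera excess noise, photobleaching or
blinking is modeled by default.

**FCS traces.** Particles diffuse in a periodic box (lateral side
10·w_xy, axial extent ≥ 4·w_z) and contribute photons weighted by the 3-D
Gaussian profile exp(−2(x²+y²)/w_xy² − 2z²/w_z²); per-bin counts are
Poisson. Occupancy `n_particles` is defined over the effective volume
V_eff = π^{3/2}·w_xy²·w_z, so the fitted amplitude 1/N should recover it
directly. A `double_labeled_fraction` of particles emits into both
channels (intact duplexes); the rest split between single-channel species.
Defaults: w_xy = 0.25 μm, κ = 12, D = 15 μm²/s (τ₁ ≈ 1 ms), 5-s traces at
0.1-ms bins, chosen so the diffusion time sits well inside the 0.01–813 ms
fit window.

**Amplitude series.** exp(−(t−t₀)/τ) plus Gaussian noise, first value
forced to 1 — the duplex-dissociation readout normalized at the first
observation (2 min after introduction).

**Colocalization sets.** Per frame, a planted fraction of channel-A points
receives a channel-B partner displaced by isotropic Gaussian jitter; all
other points are uniform over the field.

## Detection

DoG filter with σ₁ = diameter/(2√2) in pixels and σ₂ = √2·σ₁ — the
standard blob-detector convention for a stated diameter (0.5 μm default).
Spot candidates are DoG local maxima with minimum separation equal to the
diameter; *quality* is defined as the DoG response at the peak, and the
absolute threshold (default 50) plays the role the original tracking
software gives it: a hard cut separating true spots (well above) from
background maxima (well below). The exact quality scaling of that software
is version-dependent, so only the threshold's role, not its absolute
scale, is reproduced. Sub-pixel positions come from 3×3 quadratic
interpolation of the DoG peak (adequate at the 0.4 μm linking gate; RMSE
< 0.3 pixel on bright synthetic spots); a 2-D Gaussian-fit refinement is
available via `refine="gaussian"`. No background subtraction or median
filtering is applied before detection.

## Linking

Between consecutive frames, all candidate pairs within the 0.4 μm gate are
accepted greedily in order of increasing distance. "Nearest neighbor"
leaves conflict resolution open; global greedy matching is deterministic
and independent of detection input order (ties broken by coordinates).
There is no motion prediction, no merge/split handling and no gap closing
by default (`allow_gaps` bridges a configurable number of missed frames if
enabled). The duration filter keeps tracks with (n−1)·Δt ≥ 2.8 s — at
20 Hz, ≥ 57 points, which guarantees the 55-lag MSD window. Whether the
original boundary was inclusive cannot be determined; `strict=True` gives
the exclusive variant.

## MSD and motion classification

The time-averaged MSD uses overlapping displacement pairs. The analysis
window caps the maximum lag at 55 frames; by default all available pairs
of the track enter the average. A variant truncating each track to its
first 56 points (making per-lag pair counts identical across tracks) is
available via `truncate=True` / `ClassifierConfig.msd_truncate`, but is
not the default because the free/confined discrimination depends strongly
on the number of averaged pairs (see *Statistical limits* below).

Decision tree (defaults in parentheses):

1. **D estimate** — least squares of MSD = 4Dt over lags 2–11, *through
   the origin*; negative slopes clamp to 0. D ≤ 0.01 μm²/s ⇒ stationary.
   The through-origin form is essential to the tree's semantics: a
   strongly confined particle has a flat MSD at ≈ R²conf from lag 1
   onward, so a free-intercept fit would return slope ≈ 0 and absorb every
   confined track into "stationary". Through the origin, a confinement
   plateau maps to an effective D ≈ plateau·Σt/(4Σt²), comfortably above
   the immobile cut, while genuinely immobile tracks (whose plateau is
   only the localization-error floor 4σ_loc², σ_loc ≈ 0.02–0.05 μm) stay
   below it. The free-intercept variant is kept under
   `d_intercept="free"`.
2. **Confined fit** — nonlinear least squares of
   MSD(t) = (4R²conf/3)(1 − e^(−t/τ)) over lags 2–30, t in frames,
   starting values R_conf = 0.3 μm, τ = 20 frames (the thresholds and
   inits are stated in frame units; seconds are obtained by ·Δt).
   τ ≤ 30 frames ⇒ confined. Non-convergence is flagged and the track
   falls through to step 3 with a warning.
3. **Quadratic test** — MSD = a·t² over lags 2–30 (closed-form LS
   solution Σ MSD·t²/Σt⁴, a ≥ 0), t in seconds. a > 4D×1.2 ⇒ directed,
   else diffusive. The criterion compares quantities of different
   dimension (μm²/s² vs μm²/s), so it is only meaningful for a fixed time
   unit; seconds are adopted and a frames-unit variant exists
   (`directed_time_unit="frames"`) because the original convention is not
   recoverable. All fits are unweighted (count-weighting was examined and
   does not change the discrimination behavior).

Lag 1 is excluded from every fit range, which suppresses
localization-noise bias at the shortest lag.

### Statistical limits

The time-averaged MSD of a *single* track has large, strongly correlated
fluctuations at high lags (relative standard deviation ≈ √(2n/3(N−n)) at
lag n with N points — order unity at n = 30, N = 56). Consequences,
measured on ideal simulated tracks:

* With 57-frame tracks, ~38% of genuinely free tracks have a *global*
  least-squares confined fit with τ ≤ 30 frames and are labeled confined;
  the confusion is scale-invariant in D and cannot be removed by
  weighting, starting values or optimizer choice. Free-track accuracy at
  that length tops out near 60%, while stationary, confined and directed
  reach 97–100%.
* The confusion decays with track length (≈ 37% / 18% / 7% / 1% at
  57 / 150 / 300 / 500 frames with full-track averaging). The pipeline's
  default synthetic scenes therefore use 300-frame movies, and mode
  fractions recovered end-to-end match the planted ones to a few
  percentage points.
* The confined model's plateau convention (4R²conf/3) differs from the
  uniform-disc saturation (R²conf), so fitted R_conf on plateau-dominated
  disc-confined tracks is biased low by a factor √3/2 ≈ 0.87. Recovery
  tests accommodate this known 13% bias.

These are properties of single-track MSD classification itself, not of
this implementation; any analysis using the same tree on 57-frame tracks
inherits them.

## FCS / FCCS

The correlator evaluates G(τ)−1 = ⟨δF_A(t)δF_B(t+τ)⟩/(⟨F_A⟩⟨F_B⟩) by
direct shifted products of the overlapping trace segments on a
quasi-logarithmic grid (16 lags per octave, spacing doubling per octave —
the multiple-tau register layout). Amplitudes are *not* octave-rebinned:
direct evaluation is exactly reproducible by a brute-force correlator, and
for 5-s traces the extra long-lag variance is immaterial inside the
0.01–813 ms fit window. Poisson shot noise is uncorrelated between bins
and therefore drops out at every lag ≥ 1.

The single-species 3-D diffusion model
G(τ)−1 = (1/N)(1+τ/τ₁)⁻¹[1+(1/κ)²(τ/τ₁)]^(−1/2) is fitted with κ held
fixed (default 12; the instrument's calibrated value, 10–15, and κ is
notoriously unidentifiable from a single curve). The two-component variant
shares N and κ and splits the amplitude by a fraction parameter. The
zero-lag amplitude of the fitted model is 1/N.

The relative cross-correlation amplitude (1/N_cc)/min(1/N_A, 1/N_B) is
the standard bound-fraction readout: ≈ 1 for fully double-labeled
samples, ≈ 0 with no co-diffusing species, monotone in the double-labeled
fraction in between. Whether the original "amplitude" was the fitted 1/N
or the mean of the first lags is not on record; the fitted amplitude is
used.

The amplitude-decay fit holds the value at t₀ fixed to 1 (the series is
normalized there); a free-amplitude variant exists. A best-fit rate
indistinguishable from zero is flagged `non_decaying` rather than reported
as an unbounded constant.

## Colocalization and ROI quantification

Colocalization is object-based and per-detection: a channel-A detection is
colocalized iff a same-frame channel-B detection lies within the radius
(default 0.3 μm — two-color registration plus diffraction scale, below the
linking gate; the radius is a reporting-required parameter, not a measured
constant). The percentage is over all channel-A detections pooled across
frames. Co-moving track pairs require a minimum number of coincident
frames and a median same-frame distance within the radius. Pixel-intensity
coefficients (Pearson/Manders) are deliberately out of scope.

ROI ratios subtract the mean over a user-supplied background region, clip
negatives to zero, and ratio the sums over named regions (perinuclear /
whole cell; cytoplasm late / cytoplasm early). Subtracting the measured
background makes the ratio exactly invariant to a constant offset on the
image. Masks are user-supplied label images; there is no automated
segmentation.

## Pipeline and problem sizes

`run_pipeline` validates every stage's configuration before any stage
runs, executes simulate → render → detect → link → classify, and writes a
manifest (config hash, seed, versions, per-stage row counts). Default
scene: 50 particles, 300 frames, non-directed modes on a 5-μm grid and
directed particles on an outer ring heading radially outward — sparse
geometry in which trajectories never compete for links, so linking errors
reflect the linker rather than emitter density. Scene motion parameters
(free D = 0.1, confined R = 0.175 μm / D = 0.4, directed v = 0.8 μm/s /
D = 0.02 μm²/s) keep per-frame displacements inside the 0.4 μm gate;
faster free motion (e.g. D = 0.5 μm²/s at 20 Hz) would exceed the gate in
~20% of frames and no track would survive the duration filter — a
property of the gate itself. Validation suites use 10²–10³ tracks,
10⁴–10⁵-bin traces and 10²-seed recovery studies; these sizes give the
estimators enough power while keeping a full run in tens of seconds.

## Known limitations

* Whole-track classification only; a track that switches mode mid-way is
  assigned a single label.
* The synthetic movies lack EMCCD excess noise, photobleaching, blinking,
  drift, and out-of-focus light; detection performance on real data will
  be worse than on these fixtures.
* The FCS simulator has no triplet state, background or afterpulsing; fits
  to real curves may need those terms.
* Colocalization percentages depend on the chosen radius and on emitter
  density (chance pairing); report both alongside any percentage.
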