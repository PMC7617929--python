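# Methods

## Scope

`rhizotrack` re-implements, as testable code with synthetic ground truth,
four analyses used in rhizobial motility/symbiosis studies: single-cell
capillary video tracking, swimming-halo dose-response modelling,
flow-cytometric bacteria/bacteroid gating, and stained-nodule counting.
Inferential statistics downstream of these tables (ANOVA, Dunnett contrasts,
GLMs) are deliberately out of scope: the package emits the tidy per-track /
per-sample tables those tests consume.

## Run-and-tumble simulator (`swim_sim`)

The generative model is the minimal standard one sufficient for recovery
testing, since published studies report only summary speed and tumble rate:

* per-cell constant speed v ~ Normal(μ, σ), truncated below at 0.1 μ
  (defaults μ = 44 μm/s, σ = 7 μm/s — a wildtype-on-glucose population);
* heading diffusion during runs with D_r = 0.062 rad²/s, the classic value
  measured for swimming enteric bacteria; at 10 fps this contributes
  4.5°/frame of angular wander;
* tumbles as a Poisson process (default 0.11 /s), realised per frame with
  probability 1 − exp(−λ/fps); the reorientation kernel is uniform by
  default (`tumble_angle_spread` = 0) or von Mises about the incoming
  heading; tumbles are instantaneous — a pause phase would be unobservable
  at 10 fps;
* absorbing field-of-view boundary: a camera loses cells, so records
  truncate at exit rather than wrap.  The simulation is 2-D (imaging at the
  capillary's top surface); out-of-plane loss is implicit in truncation.

Imaging follows the source acquisition: 10 fps, 1440 × 1080 px full frame
(512 × 512 for the recovery studies, to keep them minutes-scale), with a
configurable μm/px calibration defaulting to 0.2 μm/px — plausible for a
40× objective and never hard-coded downstream.  Spots are isotropic
Gaussians (σ = 1.3 px, peak 400 counts on a 100-count background) plus
white Gaussian read noise (σ = 40 counts, i.e. peak SNR 10).  Rendering
stops at the last frame containing an in-view cell; trailing empty frames
carry no information.

The other generators draw halo diameters as 4PL(conc) + N(0, 1.5 mm) over
1–30 mM with 3 replicates; cytometry events as two bivariate normal scatter
populations (bacteroids above bacteria in both FSC and SSC, enforced) with
a bright fluorescence channel and optional dim debris; and root photographs
as a textured root-coloured background bearing softly-edged stained
ellipses placed non-merging (centre spacing ≥ 2 r_max + 5 px).

What the generators do **not** emulate: cell shape and anisotropic PSFs,
photobleaching, shot noise, hydrodynamic or steric cell–cell interactions,
3-D capillary geometry, plate random effects in halo data, spectral
spillover in cytometry, and lighting gradients or out-of-focus blur in root
photographs.  Passing recovery tests therefore demonstrates correctness of
the algorithms under their stated assumptions, not robustness to every
artefact of real data.

## Spot detection (`detect`)

Classic particle locating: subtract a large-scale background (box filter at
4 × the upper band-pass scale), band-pass at the spot scale (Gaussian low
cut minus box high cut), keep above-threshold local maxima separated by a
minimum distance, and refine each to an intensity-weighted centroid with one
recentring pass.  Local maxima are evaluated sparsely at above-threshold
pixels (identical to a dense maximum filter, cheaper at video scale), and a
post-refinement dedupe removes the double maxima that noise raises on one
spot's flanks.  Detections whose refinement window would leave the image are
dropped — edge spots are clipped and bias the centroid.  Default threshold
is 25% of the expected band-passed spot peak, derived from the imaging
configuration.  Measured accuracy: 0.005 px RMSE noiseless, ≈0.1 px at the
default SNR.  Coordinates are 0-based, pixel centres at integers, x =
column, y = row.

## Linking (`link`)

Per frame pair, active tracks are matched to detections by exactly optimal
gated assignment (Hungarian solver on an augmented matrix): minimise the sum
of squared displacements over links within the gate, with a fixed no-match
penalty of gate² per unmatched point.  The gate is ceil(1.5 × mean step) px,
derived from configuration.  A track survives `memory` = 1 missed frame; a
closed gap is linearly interpolated and flagged, and gap links are judged by
per-frame-equivalent squared displacement.  Tracks shorter than 10 frames
(1 s) or with net displacement < 5 px are discarded as noise/debris.

Position-only assignment (no velocity model, by design) cannot preserve
identity when two cells fall inside one gate: at 22 px/frame steps, crossing
cells swap tracks often enough to dominate naive tumble statistics.  Track
points with a foreign particle within the gate at the same or an adjacent
frame are therefore flagged *contested*; contested steps are excluded from
the speed mean, and contested intervals neither seed tumble events nor count
toward tumble exposure.  Track purity (majority-overlap with a unique true
cell) exceeds 95% at dilute densities (≈1 cell / 2000 μm²) and degrades at
crowded ones; the recovery suite pins the dilute regime.

## Motility metrics (`motility`)

Per-step speeds are frame-to-frame displacements × fps (px → μm first); a
track's mean speed is its path length over its duration, excluding
contested steps.  Turning angles use tangent vectors spanning
k = smooth_window // 2 frames on either side (default k = 1, i.e. raw
consecutive displacements): an instantaneous turn registers at its full
angle, which a centred moving average would attenuate ~2.5-fold.  An event
is an interval with |Δθ| > 18°, optionally also requiring an instantaneous
speed drop (off by default — simulated tumbles have no pause); flagged
intervals within 3 frames merge at the frame of maximal turning.

The 18° threshold sits ≈3.8 sd above the angular noise of a running cell
(rotational diffusion 4.5°/frame ⊕ localisation ≈0.6°), keeping false
events ≈0.001–0.008 /s while counting 90% of uniform reorientations;
completeness is bounded at 1 − θ/180 for any threshold θ, so recovered
rates sit below generative truth by design, inside the 25% recovery band.

Per-track tumble rate = events / tumble-eligible exposure.  Tracks with
< 1 s of eligible exposure contribute no rate (their speed still counts):
on FOV-truncated tracks, straight swimmers exit fastest, so very short
tracks are tumble-poor and drag the unweighted across-track mean down
≈25%; the 1-s floor was calibrated once by parameter-recovery simulation
at 4,000 track-seconds per wildtype condition and then frozen.  Population
summaries report unweighted across-track means and SDs per group — the
zero-inflated SD ≫ mean pattern on ~1-s tracks is expected and reproduced.

## Halo dose-response (`halo`)

f(x) = c + (d − c)/(1 + exp(b (ln x − ln e))), fitted by Levenberg-
Marquardt with analytic Jacobian in (b, c, d, ln e), initialised from the
data (d = max mean diameter, c = min, e = geometric mid-concentration) with
a multi-start over b ∈ {±0.5, ±1, ±2}; the orientation degeneracy
(b, c, d) ≡ (−b, d, c) is resolved by reporting d ≥ c.  Exponents are
clipped at ±500 for overflow safety.  ≥5 distinct concentrations are
required; an all-identical series returns a flagged degenerate flat fit.
Parameter SEs are curvature-based (Gauss-Newton covariance) and labelled
approximate; prediction CIs use a delta method on those SEs.

"Linear where appropriate" is operationalised as corrected-AIC selection
(Gaussian likelihood from RSS; k = 5 vs 3 including the variance), ties and
non-converged 4PL falling to linear; on 500 simulated linear tables at
1 mm noise the 4PL is falsely chosen < 10% of the time.  The maximum
non-motile baseline is mean + 2 SD (sample SD) of a designated control
strain's diameters — the caption-level rule is otherwise undefined.
Replicates are treated as independent (no plate random effect).

## Cytometry gating (`cytogate`)

Events below the fluorescence threshold are unlabelled and excluded; the
rest split by an explicit linear boundary a·FSC + b·SSC ≥ c ⇒ bacteroid
(a, b ≥ 0 so the bacteroid side is the larger/more-granular side; boundary
equality deterministically bacteroid).  Instrument-drawn gates are thus
replaced by reproducible parameters; curved/polygon gates and FCS binary
parsing are out of scope (events are CSV).  "5000 reasonable events" is
operationalised as: keep the first 5000 rows passing finiteness/positivity,
warn if exhausted earlier.  cells/g = count × dilution × (resuspension
volume / analysed volume) / nodule mass.

## Nodule counting (`nodulescan`)

Hue/saturation/value thresholding against a stain preset (blue-green
X-gal-like hue 0.42–0.65; magenta GlcA-like 0.80–0.97; saturation ≥ 0.25),
morphological closing (radius 2 px), 8-connected components, optional
distance-transform watershed for touching blobs, and an area filter
(40–5000 px²).  Counts are invariant to 90° rotations and ±20% uniform
brightness; on 100 seeded synthetic roots bearing 5–40 nodules the count
error is ≤1 in ≥95% of images (100% in practice).

## Problem sizes and numerical choices

Recovery studies run at 512 × 512 px (102.4 μm FOV): in-view residence at
~40 μm/s is ≈1 s, so population statistics accumulate over replicate 30-s
videos, 40 cells each — ≥500 swimmers for speed, ≥10,000 measured
track-seconds for tumble rates (≈250 videos/condition, a few minutes each
on one CPU).  At that scale the full pipeline recovers wildtype population
speeds within ~3% and tumble rates within ~6% of generative truth
(e.g. seed 1: 42.7 vs 44, 0.107 vs 0.11, 0.076 vs 0.08).  All random
draws flow from explicit integer seeds through `numpy` `SeedSequence`
spawning; identical seeds give bit-identical outputs.

## Known limitations

* Tumble completeness is capped by the angle threshold (90% for uniform
  reorientations at 18°); rates are systematically a little low, never
  corrected post hoc.
* The across-track mean tumble rate is an estimand sensitive to the track
  length distribution; the 1-s exposure floor stabilises it for this FOV
  geometry but other geometries would warrant re-calibration.
* Identity through dense crossings is unrecoverable without a motion
  model, which the linker intentionally omits; contested masking trades
  exposure for correctness.
* Halo CIs are curvature-based approximations, not profile or bootstrap
  intervals.
* The cytometry boundary is linear; heavily overlapping populations would
  need quadratic or data-driven gates.
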