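# Methods

This note documents the models and numerical choices behind `insolesim`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the methodology left the implementation open.

## Coordinate frame, units, geometry

All geometry lives in a side-relative frame: origin at the posterior-medial
corner of the insole bounding box, x = medial→lateral (mm), y =
posterior→anterior (mm). Medial is at low x for either foot. Pressures are
stored as %BW/mm² (percent body weight per mm²), vertical load as %BW,
so results are weight-normalized across subjects; kPa data can be converted
at read time from the recording's body-weight metadata.

The footprint outline is a smooth symmetric template: a monotone-cubic
(PCHIP) half-width profile along normalized insole length, with a rounded
heel, a waisted mid-section and a broad metatarsal band. Per-size bounding
boxes are 245×80, 257×83, 269×86 and 281×89 mm for sizes 38–39 through
44–45. The total insole surface is 15787 mm² for size 38–39 — the reference
value for this class of insole — and scales with the bounding-box area for
the other sizes, which are not separately standardized.

The region mask is rule-based on normalized length: hindfoot < 0.30,
midfoot 0.30–0.55, forefoot 0.55–0.80, toes ≥ 0.80, with the
medial/lateral split at the outline midline. The band boundaries are a
design choice (common masking procedures name the regions but not exact
cut-offs) and are centralised in `geometry.py`.

## Experimental sensor grid

`generate_template` tiles 99 rectangular cells in 12 posterior→anterior
bands covering 5–93 % of the insole length, with per-band cell counts
apportioned to the local outline width (largest-remainder rounding, total
exactly 99). Cells are ~8–16 mm and jointly cover most of the insole
surface, matching how commercial capacitive grids tile the shoe: full-
coverage tiling is what produces the documented behaviour of the reference
system (contact areas of 60–85 % of the surface, GRF near body weight, and
a sensorized-area ratio ≈ 0.23 against the 3600 mm² reduced layout). A
`cell_mode="nominal5mm"` variant places 5 × 5 mm active areas at the same
centers for sensitivity analyses; note that with 25 mm² cells the
experimental system integrates less area than the simulated one and the
under-estimation structure inverts, which is why tiling is the default.
A 1 µm inter-cell separation keeps abutting rectangles strictly disjoint
under floating-point arithmetic.

## Synthetic pressure fields

The instantaneous field is a convex combination of seven anatomical 2-D
Gaussian sources (heel, lateral arch, three metatarsal-head groups, hallux,
lateral toes; σ between 8 and 18 mm). Each source is normalized by its
*discrete* integral over the cell grid, so the frame-wise vertical load
Σᵢ pᵢAᵢ equals an analytic profile L(t) exactly and the discrete
pressure-weighted COP is a closed-form blob-weighted mean. Both are emitted
as `TrialGroundTruth` beside every trial, which is what lets event
detectors, variable computations and the whole pipeline be checked without
real data.

Task structure (all at 100 Hz; durations and amplitudes get ±10 % uniform
subject jitter in cohorts):

* **Gait** — 10 stances of 0.65 s separated by 0.40 s zero-pressure swings.
  L(t) per stance is the classic double-hump sin(πτ) + 0.2·sin(3πτ),
  normalized to a 115 %BW peak (single support). Source weights roll
  posterior→anterior (heel strike → lateral arch → metatarsal heads →
  hallux/toes) with cos² windows, so the frame of peak spatial pressure
  migrates monotonically from heel to toes. The heel-marker height sits at
  ~2 mm during stance and rises to ~57 mm in swing.
* **Drop landing** — 1 s of forefoot-dominant standing on the 32 cm
  platform (the protocol has the subject weight-shifted as far forward as
  possible, so the hallux carries a clear share), an abrupt release to a
  0.45 s airborne window of exactly zero pressure, then an impact spike
  (5-frame rise to 250 %BW, exponential decay with 0.15 s time constant to
  a 100 %BW single-leg settle held ≥ 2 s).
* **Lifting** — one squat-lift cycle: the vertical L5 trace goes
  top → bottom (first minimum) → top plateau → bottom (second minimum) →
  top via cosine ramps; the plateau is the leave-and-peak interval excluded
  from analysis. One insole carries 50 %BW plus half the lifted load
  (default 16 kg) during the loaded ascending/descending phases, with 0.3 s
  grab/release ramps; source weights shift anteriorly with squat depth and
  load, so the COP moves forward in the loaded portions.

Noise is additive per-sensor Gaussian truncated at zero (default
σ = 0.001 %BW/mm²), applied after the closed-form field; ground truth is
exact only for `noise_sd = 0`. All randomness derives from the trial seed.

What the generator does **not** emulate: inter-step variability of real
gait, mediolateral balance corrections, sensor drift/hysteresis/saturation,
shear, cross-talk, temperature effects, and subject-specific foot shapes.
Passing tests therefore demonstrate that the pipeline's algorithms are
correct and self-consistent, not that a physical prototype would achieve
the same error figures on real feet.

## Layout design

The peak-location histogram counts, per experimental cell, how often the
spatial pressure maximum falls on it — per trial by default (one count per
trial at the trial's global maximum, ties to the lowest sensor id), or per
frame as an option. Selection is greedy per region group in a fixed
posterior→anterior order: candidates (experimental cell centers) are ranked
by descending count (ties: lower y, then lower x) and accepted when the
15 × 15 mm square stays inside the outline and at least `min_gap = 2 mm`
from all accepted squares, until the group quota (2/2/1/2/7/2) is met. The
methodology describes criteria rather than an algorithm; greedy selection
with deterministic tie-breaks is the minimal faithful choice. If greedy
cannot fill a quota, a deterministic exhaustive repair over the group's
best-ranked candidates (maximizing summed counts under the same feasibility
rule) runs before raising an error naming the region.

The shipped default layouts are a pure function of the package code: the
38–39 layout is designed from a canonical per-frame histogram over one
noise-free trial of each task, and the other sizes are affine-scaled from
it (centers scaled by the length/width ratios, 15 mm side kept — scaling up
preserves containment because the outline scales with the same ratios).

## Simulation

Default grouping is k-nearest with k = 3 — the grouping cardinality stated
for the original simulation — resolved globally so groups stay disjoint: all
(simulated, experimental) pairs are visited in ascending center distance
and a cell joins the nearest still-unfilled group. Disjointness prevents
double counting in loss-of-data maps. The simulated reading is the plain
arithmetic mean of the group (cells are near-equal in size; no area
weighting). `geometric_overlap` grouping (all cells intersecting the
simulated square, ties by overlap area then distance) is available for
sensitivity analyses.

## Variables

* Peak pressure: per-frame max over sensors. Contact: p > threshold, where
  the threshold is the per-sensor zeroing threshold when available and
  0.1 % of the trial maximum otherwise.
* **Mean pressure** has two conventions. The spatial mean over the total
  insole surface (GRF / total surface) is the default in `compute_all`:
  under it, a reduced-coverage layout scales Mean Pressure exactly like
  GRF, which is the behaviour reported when validating reduced layouts
  against full-coverage systems (their printed mean-pressure and GRF error
  ranges are near-identical). The contact-sensor arithmetic mean is exposed
  as `mean_pressure()` and via `mean_policy="contact"`; its error direction
  under a peak-seeking layout is indeterminate, which is why it is not the
  comparison default.
* COP: formulation 1 weights sensor centers by instantaneous pressures;
  formulation 2 weights them by pressures normalized to each sensor's
  temporal peak (sensors that never load are excluded; the "per-sensor COP"
  of a single cell is its center — the only computable reading). Unloaded
  frames are carried as missing and excluded from RMSE.
* dCOP: Euclidean distance of the COP from the origin divided by
  √(total surface). The distance is reported in a "% of surface area" style
  unit in this literature, which is dimensionally inconsistent for a
  length; normalizing by √area reproduces the printed magnitude order
  (~0.6–1.1) and is switchable.
* Contact area: 100 · Σ Aᵢ[pᵢ > thr] / total surface.
* Filtering: zero-phase (forward–backward `filtfilt`, odd-reflection
  padding) 3rd-order Butterworth, cutoff f_s/8 — digital design, so the
  forward-backward gain at the cutoff is exactly ½ and the DC gain 1.
  COP series are left unfiltered. Gap-bearing series (dCOP) are linearly
  interpolated across missing stretches before filtering and the gaps
  restored afterwards.

## Events

Regional signals are sums over the region's sensors (heel = both hindfoot
regions; hallux = the medial half of the toes region), compared against the
sum of the member zeroing thresholds; single-sensor signals are a config
choice away but regional sums are robust. Zeroing thresholds are per-sensor
baseline maxima plus a margin of 0.0005 %BW/mm² (~3.4 kPa at 675 N,
comparable to capacitive activation thresholds). Threshold crossings are
debounced (3-frame sustained runs) so isolated noise spikes do not open
segments; on noise-free signals this leaves crossing frames unchanged.
Gait IC/TO follow the heel-exceeds / hallux-drops rule; the heel marker,
when supplied, corroborates each IC by requiring the filtered marker height
to be in its lowest 25 % band near the IC (point minima on a flat stance
plateau are numerically ill-defined). Drop windows run from hallux release
to landing + 2 s (clipped and flagged if the trial ends earlier). Lifting
phases come from the filtered vertical L5 trace: the two prominence-gated
minima bound the loaded phases, and the leave-and-peak plateau is the
velocity-gated still interval (|v| < 5 % of peak within the top height
band) — a velocity gate locates the plateau corners to ±3 frames where a
pure height band would bias them by ~10 frames.

## Evaluation

RMSE% normalizes by the gold-standard series' peak magnitude over the
analyzed segment (per-phase for lifting; whether to normalize per phase or
per trial is unspecified in the source methodology — per analyzed segment
is the default and it is configurable by cropping). Loss-of-data maps use
unfiltered per-sensor peaks over the analyzed segment; uncovered cells lose
100 %, covered cells 100·(exp − sim)/exp with 0/0 → 0. Left/right averaging
resamples both sides onto a 101-point 0–100 % segment base (standard
practice for bilateral gait averaging) before the element-wise mean;
trial reports are averaged element-wise. Summaries aggregate into a
task × size × phase table with variable-wise mean ± SD for both systems and
the ⟨min–max⟩ RMSE% range.

## Problem sizes

Default test and acceptance runs use cohorts of 2–10 subjects with 1–2
trials per subject and 3–10 steps per gait trial; these sizes give stable
RMSE summaries (the quantities are means over hundreds of frames per trial)
while keeping a full run to seconds on one CPU.

## Known limitations

* The synthetic fields are smooth Gaussian mixtures; real plantar pressure
  has sharper gradients under bony prominences, so absolute RMSE% values on
  real data will differ (the directional structure — magnitude variables
  underestimated, COP preserved — is the robust prediction).
* Only the vertical force component is modelled; no shear.
* The event detectors assume the synthetic task protocols (e.g. exactly two
  L5 minima per lift); irregular real trials may need the prominence,
  velocity and debounce parameters adjusted.
* Physical sensor characteristics (linearity, hysteresis, temperature) and
  gait-phase subdivision beyond IC/TO are out of scope.
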