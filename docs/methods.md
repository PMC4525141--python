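# Methods

## Geometry and conventions

The world frame is in cm with the origin at the arena corner farthest from
the stimulus wall; the x-axis points away from the stimulus, so the stimulus
wall lies at x = 0 and the stimulus direction is exactly 180°. Angles are
degrees in [0, 360), counter-clockwise from +x (all internal computation in
radians). The default arena is 12 × 12 cm at 29 fps; the region of interest
(ROI) is the full-width strip of depth 3 cm against the stimulus wall — 25%
of the arena, so 25% occupancy is the chance level for an indifferent fish.
Pixel coordinates use the image convention (column = x, row increasing
downward, stimulus wall on the left edge); a single linear px↔cm calibration
is assumed (no lens-distortion model).

Tracked coordinates up to 2% of the arena width outside the rectangle are
clamped to the boundary (wall jitter); anything farther is a validation
error. The detected flag is encoded 0/1 in CSV, with empty coordinate cells
allowed only for undetected frames; files are comma-separated with a
mandatory header and 6-decimal fixed precision.

## Attention read-outs

Per detected frame the body orientation αᵢ is the centroid-to-head axis
angle. The mean resultant vector r = n⁻¹ Σ (cos αᵢ, sin αᵢ) has length
R ∈ [0, 1] (directional focus; inversely related to the angular standard
deviation) and direction α; when R = 0 the direction is an explicit flagged
state, never silently 0°. The projection R proj = R·cos(α − 180°) maps focus
onto a linear scale: +R fully stimulus-directed, −R fully opposite. A group
of fish is summarised by the vector average of the members' Cartesian
resultants — each fish's direction thereby weighted by its own R. The group
table additionally reports the arithmetic mean ± SEM of the individual
R proj values, the form in which group focus is usually tabulated; both
quantities are computed because published group entries with a ±SEM can only
be the latter.

Percent time in the ROI uses the centroid position and the detected-frames
denominator (undetected frames occur at the water surface along walls, where
the x–y position is ambiguous). Total distance sums centroid steps over
consecutive detected pairs and scales by (n_frames − 1)/n_detected_pairs,
implementing the convention that distance while undetected is proportional
to distance while detected; gaps contribute neither distance nor pairs.
Mean speed in the ROI averages step speed over steps whose *starting*
centroid is inside the ROI; steps spanning a gap are excluded (the source
assays leave this computation unspecified; starting-frame assignment is
deterministic and gap-safe). Occupancy heatmaps bin detected centroids at
0.5 cm (24 × 24 grid) and expose the 1D marginal along the stimulus axis;
display normalisation is relative to the maximum cell. Temporal dynamics use
fixed 30-s bins (a whole number of frames; the final partial bin is
dropped); a bin with no usable frames is NaN.

## Moore's Modified Rayleigh test and the direction CI

Uniformity of a group's individual mean directions is tested with the
rank-based statistic R\* = √(X² + Y²)/N^{3/2}, X = Σ rᵢ cos αᵢ,
Y = Σ rᵢ sin αᵢ, where rᵢ are the ascending ranks of the members' resultant
lengths (average ranks on ties). The p-value is Monte Carlo (default 9999
seeded replicates, each redrawing N uniform directions while keeping the
ranks), giving p ≥ 1/(n_mc + 1) and supporting any N ≥ 4; published analyses
of this test report only threshold crossings, so threshold agreement is the
inherited claim, not exact p equality. The group-direction CI is a seeded
percentile bootstrap over fish (default 10,000 resamples) computed on signed
angular deviations from the point estimate to avoid wrap-around; degenerate
(zero-resultant) resamples are redrawn, with an error after 100 consecutive
failures. The CI method used by the original desktop packages is not
documented; the bootstrap is this package's choice.

## Summary-statistics inference

Group tables in this literature print mean ± SEM and n, which determine
every first/second-moment test exactly (implied SD = SEM·√n):

- Welch's ANOVA: weights wᵢ = nᵢ/SDᵢ², weighted grand mean m\*,
  F = [Σ wᵢ(mᵢ − m\*)²/(k − 1)] / [1 + 2(k − 2)/(k² − 1)·Λ] with
  Λ = Σ (1 − wᵢ/W)²/(nᵢ − 1) and df₂ = (k² − 1)/(3Λ). The true Welch df is
  reported; published tables sometimes print nominal integer df instead, so
  only the F value is expected to match.
- Classic one-way ANOVA from reconstructed between/within sums of squares.
- Games–Howell: q = |mᵢ − mⱼ|/√((SDᵢ²/nᵢ + SDⱼ²/nⱼ)/2), Welch–Satterthwaite
  pairwise df, p from the studentized range with k groups. Tukey HSD uses
  the pooled error variance. Both rely on `scipy.stats.studentized_range`.
- One-sample t: t = (mean − μ₀)/SEM, df = n − 1.

These formulas are exact, not approximations: tests verify they reproduce
raw-data results (scipy, pingouin) on samples generating the summaries.
Rank-based procedures need raw values: Kruskal–Wallis (tie-corrected, via
scipy) and Spearman (Pearson correlation of average ranks; two-sided seeded
permutation p for n < 30). An ln-transform helper mirrors the convention of
log-transforming hormone concentrations before testing; it is applied only
on explicit request.

The mixed pre/post ANOVA (between = treatment, within = phase) exploits the
two-level within factor: the interaction is the one-way ANOVA on per-fish
difference scores d = pre − post, F(k − 1, N − k). Within-group phase
contrasts use the pooled difference variance (t = d̄_g/√(MSW_d/n_g),
df = N − k). Between-group contrasts at a fixed phase use the pooled
between+within error (MS_subjects + MS_phase×subject)/2 with Satterthwaite
df; because the error-term construction for such planned comparisons varies
across statistics packages, a plain two-sample-t variant is reported
alongside and neither is asserted against published planned-comparison
values.

## Video tracker

The tracker is deterministic and classical: per-pixel temporal-median
background (≥25 sampled frames) → absolute difference → Otsu threshold
(restricted to the tracked region; frames whose difference image peaks below
0.02 on the [0, 1] intensity scale are "missing") → largest connected
component → PCA pose. Head and tail are the extremal blob pixels along the
first principal axis; the head end is the half with the larger mean
perpendicular spread, falling back on heading continuity (turn ≤ 90°) and
then motion direction when the width asymmetry is below 5%. Blobs under
3 pixels are degenerate. The plausible-area gate defaults to [0.2×, 3×] the
median blob area of the first 100 detected frames. No gap interpolation is
performed at the tracking stage — undetected frames are recorded as such and
handled downstream by the distance correction. Tracker output is clamped
into the arena rectangle. Re-running on the same frames is bit-identical.

## Stimulus editing

Dot replacement composes, over the temporal-median (fish-free) background,
two anti-aliased filled discs of radius √(area/π) at the tracked centroid
positions, using each fighter's mean colour; "contrast" is carried as the
mean absolute blob-background intensity difference. Motion is preserved
exactly by construction. Dyad activity is the mean over both fish of
frame-to-frame centroid speed in 30-s bins (steps assigned to the bin of
their starting frame). Re-tracking an edited clip recovers dot centroids to
sub-pixel accuracy while the dots are separated; identity through overlaps
(fighters in body contact) is out of scope.

## Synthetic data

The bystander generator is a biased correlated random walk at the frame
rate. Each frame is either *attending* (probability `p_att`): body
orientation drawn von Mises(180°, `kappa_att`) while the fish hovers along
its gaze at `attend_speed_factor` × the drawn speed; or *wandering*: the
persistent motion heading advances by a von Mises(0, κ₀ = 4) increment, the
body aligning with motion. The wander heading is deliberately *not*
re-anchored by attending frames — coupling them turns the walk into a pure
taxis that pins the agent to the stimulus wall, which real bystanders do not
do; decoupling yields the empirically observed combination of high R with
partial ROI occupancy. Step speeds are gamma distributed; an optional
constant `roi_drift` pulls toward the stimulus wall; boundaries reflect the
position and motion heading (an attending fish keeps facing the stimulus at
the wall). Head and tail sit ±1.5 cm (half a 3 cm adult body length) along
the orientation, shrunk angle-preservingly near walls so all points stay in
the arena. Frames within 0.5 cm of the three dark walls are dropped to
undetected with probability 0.3 — detection loss in the real assay occurs
along the dark outer walls, never at the high-contrast stimulus glass —
yielding ~4% undetected overall, the level real recordings show.

Defaults are one decision, not a dial: the attentive preset
(`kappa_att = 2`, `p_att = 0.5`, `attend_speed_factor = 0.25`,
speed mean 9 cm/s, shape 3) produces ~45% ROI occupancy, R ≈ 0.26 at
α ≈ 180° and ~100 m covered in 30 min; the `null()` preset (no bias, speed
mean 5.5 cm/s — lower because it never hovers) produces chance occupancy
(~25%), R ≈ 0 and likewise ~100 m, matching the observation that activity
does not differ between conditions. With `p_att = 1` the observed R recovers
the von Mises closed form I₁(κ)/I₀(κ) exactly, which anchors the
calibration. Between-fish heterogeneity (the spread real cohorts show) is
added at the cohort level by jittering `p_att` per fish
(`simulate_cohort(..., p_att_sd=0.25)` reproduces a Table-like SD ≈ 23
percentage points of ROI occupancy). `attend_until_s` switches attention off
mid-session for pre/post designs.

The fight-dyad generator is two-phase: before the resolution time (default
3.5 min) the fish orbit a slowly drifting centre on opposite sides at
`pre_speed` (noise scales with `pre_speed`, so a zero-speed configuration is
exactly stationary); afterwards a two-state Markov switch alternates pauses
with chases in which the dominant steers straight at the subordinate
("heat-seeking") and the subordinate flees. The post-phase mean-speed level
(bout occupancy × chase speed) must exceed the pre level by construction.

The renderer rasterises fish as tapered dark teardrops (beta-like radius
profile peaking toward the head, 15 anti-aliased discs) on a light
background, with optional Gaussian pixel noise and occlusion, and returns
exact ground truth. Frames carry a 2 cm margin around the arena, and a fish
nosing a wall keeps its full body by sliding backward along its axis (the
recorded truth is the rendered geometry), so blob orientation stays well
defined everywhere. The rendered blob's centroid is aligned to the head–tail
midpoint using a cached numerically computed shape offset.

What the generators do *not* emulate: swim-bout kinematics (tail beats,
burst-and-glide), thigmotaxis, freezing, perspective distortion, lighting
gradients, reflections at the glass, or any feedback from the stimulus to
the bystander. Passing tests therefore demonstrate the correctness of the
analysis chain under the stated statistical structure, not tracker
performance on degraded real footage.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: tracker
validation uses a 10–30 s noise-free clip at 10 px/cm; Moore-test
calibration uses 2000 null datasets of 20 fish at 999 Monte-Carlo replicates
each; pre/post power uses 25 replicate experiments of 2 × 12 fish over 2-min
sessions; the chance-occupancy check simulates 20 full 30-min sessions. All
stochastic operations take explicit seeds and no global RNG state is used;
Monte-Carlo p-values use the add-one estimator (1 + #extreme)/(n + 1).
Games–Howell/Tukey p-values come from scipy's studentized-range CDF.
Floating-point ties in the head call and Moore ranks are handled
deterministically (continuity fallback; average ranks).

## Known limitations

- The tracker is single-animal; the dot re-tracker maintains two identities
  only while the dots are separated.
- Welch df₂ is reported as the real-valued Welch–Satterthwaite value, which
  may differ from nominal integer df printed in older tables.
- The bootstrap direction CI is approximate for very dispersed groups (the
  interval widens toward 360° and should be treated as "unreliable" rather
  than interpreted literally).
- Video file I/O depends on the imageio backends available at runtime; the
  analysis API operates on in-memory frame arrays and does not require any
  codec.
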