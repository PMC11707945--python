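# Methods

This note documents the models, conventions and numerical choices behind
`mpjunction`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frames and units

Three unit systems are used. Pixel coordinates are 0-based, x rightward,
y downward, origin at the top-left pixel corner. Retinal micrometers are
pixel coordinates scaled by the frame's μm-per-pixel factor (same origin
and axes). Visual-degree coordinates are fovea-centered with y upward
(the perimetric convention); converting to image coordinates flips y and
anchors the fovea to the frame center. Only square fields are accepted —
the modeled FAF acquisition is a 30° × 30° field at 768 × 768 px, giving
30/768 × `um_per_degree` μm per pixel.

The degree→micrometer scale is not part of the image metadata and no
device calibration is assumed; the package uses the emmetropic
schematic-eye value of **291 μm per visual degree** as a configurable
default, carried on every `ImageFrame` and echoed into reports. All
μm-valued outputs scale linearly with this constant, so it must be
explicit and overridable rather than buried.

## The 10-2 stimulus grid

The rectilinear 10-2 pattern is generated as the odd-integer lattice
x, y ∈ {±1, ±3, ±5, ±7, ±9}° restricted to x² + y² ≤ 82. This is the
unique symmetric radius cutoff on the 2°-spaced odd lattice that yields
the standard 68 points (17 per quadrant); ordering is deterministic
row-major from the top-left. Stimuli are treated as 2-D center points
throughout; the Goldmann III diameter (0.43°) is metadata only. The
device dB scale is fixed to [0, 36] with −1 as the "brightest stimulus
not seen" sentinel. Device stimulus ordering conventions vary; the
row-major ordering here is imposed and documented, not inherited.

## Similarity registration

`fit_similarity` implements the closed-form least-squares similarity fit
(Umeyama/orthogonal-Procrustes-with-scale): both point sets are centroid
centered, the rotation comes from the SVD of the cross-covariance, and
the scale from the trace formula. Design choices:

- **Reflection is disallowed.** Fundus-to-fundus registration cannot
  mirror, so the determinant-negative branch is forced to the best
  proper rotation and a warning diagnostic is set. (In the exactly
  mirrored limit the best proper-rotation scale degenerates toward 0 and
  the fit is rejected as degenerate.)
- **Equal weighting, no outlier rejection** — graders pick few, curated
  bifurcations; robust variants are out of scope.
- **Degeneracy guard:** fewer than 3 pairs is an error; the source
  configuration is declared collinear when its smallest singular value
  is below 1e-6 of the largest.

Least-squares optimality, exact recovery from consistent pairs (to
1e-9), order invariance and translation equivariance are all enforced by
tests, with `scikit-image`'s independent similarity estimator and a
Nelder–Mead optimizer as cross-checks.

## Lesion geometry and signed distances

Traced GA foci are simple closed polygons in FAF micrometers, normalized
to counterclockwise orientation on construction (shapely backs the
geometry predicates). Foci under the minimum traceable lesion size
(default 0.05 mm²) are dropped before any distance is computed, mirroring
the tracing protocol order. The signed stimulus-to-margin distance is
the minimum Euclidean distance to any retained focus boundary, negative
iff the point lies inside an odd number of foci. The **even-odd rule**
covers nested tracings (islands of spared retina inside atrophy) — a
documented convention, since tracing protocols rarely state one. A point
exactly on a margin returns 0 with non-negative sign.

Zone membership is inclusive at both bounds: junctional = [−250, +250] μm,
perilesional = [0, +500] μm. "Within 250 μm" does not specify a boundary
policy, so the inclusive convention is adopted and tested explicitly;
a stimulus exactly on the margin is in both zones but counts as outside
atrophy.

The test suite validates the distance path against a brute-force oracle
(dense boundary sampling at 0.1 μm plus from-scratch ray casting) on
1000 random multifocal instances, at 0.5 μm agreement.

## Zone metrics and the scotomatous rule

A stimulus is scotomatous iff its raw not-seen flag is set or its mapped
sensitivity is strictly below 0 dB. Mean zone sensitivity must decide
what to do with the −1 dB sentinel; published analyses are silent on
this, so three conventions are supported — **floor-at-zero (default)**,
as-recorded, and exclude — and the convention used is serialized into
every report. An empty zone yields an explicit `empty_zone` flag and an
undefined mean, never a silent zero; eyes with an empty zone for either
grader are excluded from (not imputed into) eye-level agreement
statistics. Grader correspondence is always by stimulus id — both
graders transform the same acquisition, only the registration differs.

## Agreement statistics

- **Bland–Altman:** bias = mean(g1 − g2); LOA = bias ± 1.96·SD(diff).
  The multiplier is fixed at 1.96; Student's t enters only the
  individual 95% CIs on each limit,
  LOA ± t₀.₉₇₅,ₙ₋₁·SD·√(1/n + 1.96²/(2(n−1))).
- **ICC:** fixed to ICC(A,1) — two-way random effects, absolute
  agreement, single measurement — computed from the two-way ANOVA mean
  squares. Absolute agreement is the defensible form for inter-grader
  interchangeability; the form label is printed in every report. The
  error sum of squares is accumulated directly from interaction
  residuals so that identical graders give MSE = 0.0 and ICC = 1.0
  exactly. ICC and CoR are computed for n ≥ 2 units (the mean squares
  are well defined there); Bland–Altman CIs require n ≥ 3. Zero total
  variance makes the ICC undefined (NaN + warning), not 0 or 1.
- **CoR / smallest real difference:** primarily 1.96·√2·s_w with s_w²
  the two-way ANOVA error variance; the 1.96·SD(diff) convention is
  reported alongside because the repeatability literature uses both and
  published values frequently do not say which. No claim is made about
  which convention any given publication used.
- **Repeated measures:** stimulus-level differences (68 per eye) are
  modeled as μ + aᵢ + eᵢⱼ with a random eye intercept; σ²_a and σ²_e are
  estimated by method-of-moments one-way ANOVA (unbalanced-design n₀
  coefficient, negative estimates truncated at 0) and the LOA widened to
  μ ± 1.96·√(σ²_a + σ²_e). The moment estimator was chosen over
  iterative REML because for the balanced two-grader design it is closed
  form and exactly testable; the two coincide in expectation. With one
  observation per cluster (or a single cluster) the analysis falls back
  to the plain Bland–Altman, to which it is then identical. On finite
  samples with zero true between-eye variance the moment-based LOA
  differ from pooled-SD LOA at O(1/n); they agree asymptotically, which
  the tests check at loose tolerance. The stimulus-level ICC is the
  naive pooled ICC and is labeled as such in report warnings; the
  eye-level variance decomposition is reported next to it rather than
  folded into a single cluster-adjusted coefficient.

## Synthetic studies

The generator emulates the study conditions this workflow targets:
**30 eyes** by default; two graders picking on average **3.3 ± 0.7** and
**4.6 ± 1.7** fiducials (clipped at the minimum of 3); per-focus lesion
areas log-normal with mean 3.25 / SD 1.75 mm² and 1–3 foci per eye, so
total per-eye lesion area averages ≈ 6.5 mm². Values no protocol states
were chosen once on realism grounds:

- **Fiducial click jitter SD 1.5 px** per grader at both ends of each
  pair (the grader clicks in both images — a symmetric error model),
  representing the precision of manually localizing a vessel
  bifurcation.
- **Sensitivity field:** logistic in the signed margin distance, inside
  level −5 dB (dense scotoma — below the device floor, so deep intra-
  lesional stimuli go unseen), outside level 26 dB (normal mesopic
  sensitivity), half-width 125 μm (a functional transition on the scale
  of the junctional zone).
- **Frames:** SLO 36°/1024 px (the MAIA convention), FAF 30°/768 px;
  the true SLO→FAF transform has scale ≈ 0.9 (the deg-per-px ratio)
  × e^N(0, 0.02), rotation N(0, 2°), and a fovea-anchored translation
  with 5 px scatter.
- **4-2 staircase:** start 25 dB; 4 dB steps until the first reversal,
  2 dB steps until the second; estimate = last level seen; never seen
  anywhere (including at 0 dB, the brightest) ⇒ −1 sentinel. The
  observer is Bernoulli with a cumulative-normal psychometric function
  (slope SD 1 dB; slope 0 = deterministic). Commercial staircase
  protocols are proprietary; this two-reversal variant is a documented
  stand-in, exact enough to test (deterministic estimates are within
  2 dB of truth across [2, 34] dB) and never claimed device-exact.

Lesion boundaries are star-convex (radial profile modulated by smooth
low-order harmonics, relative amplitude 0.15), so polygons are simple by
construction; multifocality is modeled as disjoint foci placed
largest-first (satellites in a ring beyond the main focus), not holes.
Satellite areas shrink by 10% per attempt only after 30 failed disjoint
placements, so the log-normal area target is essentially unbiased.

Randomness is hierarchical (`SeedSequence`-style keys per eye and
purpose), which gives byte-identical reruns at a fixed seed and, because
click jitter is stored as SD × unit normals, **common random numbers
across jitter levels** — the degradation of ICC with increasing jitter
is evaluated on the same underlying study, isolating the jitter effect.

What the generator does not emulate: real FAF/SLO pixel content,
fixation instability, media opacity, lesion growth between visits, or
grader-specific systematic bias in fiducial placement (jitter is
zero-mean). Passing tests therefore demonstrate the correctness of the
geometry and statistics and the qualitative response of the workflow to
registration error — not clinical performance on real images.

## Problem sizes

Default analyses use 30 eyes × 68 stimuli × 2 graders; property tests
use 1000-instance oracle sweeps (geometry, registration) and n = 3000
simulated pairs for estimator-recovery checks, sizes at which the
Monte-Carlo error is far below the asserted tolerances.

## Known limitations

- The similarity model cannot represent true inter-modality deformation;
  the residual it leaves behind is exactly what the repeatability
  battery measures, but more general transforms are out of scope.
- The repeated-measures LOA assume a balanced random-intercept model;
  heteroscedastic eyes (a few eyes with much larger grader discrepancy)
  inflate σ̂_e rather than being modeled.
- Degree→μm conversion uses a single global constant; no axial-length
  individualization.
- The even-odd containment rule resolves nested/overlapping tracings in
  a defined way, but overlapping foci from sloppy tracings may not mean
  what the tracer intended; the generator never produces them.
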