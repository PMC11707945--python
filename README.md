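# mpjunction

Microperimetry (MP) junctional-zone analysis for geographic atrophy (GA).

In eyes with GA secondary to age-related macular degeneration, the retinal
locations most informative about disease progression are those straddling
the atrophy border — the **junctional zone**, the band within ±250 μm of
the GA lesion margin. Relating MP sensitivity thresholds to that zone
requires bringing two modalities into one coordinate frame: the MP
stimulus grid, acquired on a scanning-laser-ophthalmoscopy (SLO) fundus
image, and the GA lesion tracings, drawn on fundus autofluorescence (FAF)
images. `mpjunction` implements that workflow, plus the statistics needed
to ask how repeatable it is when two human graders perform the
registration independently.

The pipeline, per eye:

1. **Registration.** Each grader marks n ≥ 3 corresponding retinal vessel
   bifurcations in the SLO and FAF images. The least-squares similarity
   transform (translation t, rotation θ, isotropic scale s; no shear, no
   reflection) minimizing Σᵢ‖sR(θ)xᵢ + t − yᵢ‖² is recovered in closed
   form (orthogonal Procrustes with scale).
2. **Signed distances.** The 68 stimulus centers of the rectilinear 10-2
   grid are mapped into FAF micrometers, and each gets the signed
   Euclidean distance d to the nearest point on the traced GA margin —
   negative inside atrophy, positive outside. Foci below the minimum
   traceable lesion size (0.05 mm²) are dropped first.
3. **Zone metrics.** Over the stimuli with |d| ≤ 250 μm (or the
   perilesional variant, 0 ≤ d ≤ 500 μm): mean sensitivity in dB and the
   number of scotomatous points (raw −1 dB "not seen" value or mapped
   sensitivity < 0 dB).
4. **Repeatability.** For two graders: Bland–Altman bias and 95% limits
   of agreement (bias ± 1.96·SD) with individual confidence intervals on
   each limit; the intraclass correlation ICC(A,1) (two-way random
   effects, absolute agreement, single measurement); the coefficient of
   repeatability CoR = 1.96·√2·s_w (smallest real difference); a
   repeated-measures Bland–Altman for the 68-per-eye stimulus-to-margin
   distances, with eye-level variance components by method-of-moments
   ANOVA; and per-stimulus coordinate differences between the graders'
   transformed grids.

No study datasets exist for this workflow, so the package ships a
synthetic-study generator with known ground truth (multifocal star-convex
GA lesions, a logistic sensitivity field across the margin, a simulated
4-2 staircase observer, and per-grader fiducial click jitter) that
exercises every stage end to end.

## Worked example

```python
import mpjunction as mj

study = mj.simulate_study(mj.SimulationConfig(n_eyes=30, seed=1))
analyses = mj.analyze_study(study)                     # both graders
battery = mj.repeatability_battery(analyses["grader1"], analyses["grader2"])

eye = analyses["grader1"][0]
print(eye.fit.rmse, eye.transform.scale)
# 1.7738 0.9089   ← registration residual (px) and fitted SLO→FAF scale

zm = eye.zone_metrics["junctional"]
print(zm.n_in_zone, zm.mean_sensitivity_db, zm.n_scotomatous_in_zone)
# 11 12.18 1      ← 11 stimuli within ±250 μm of the margin; mean 12.18 dB;
#                   1 scotomatous point

s = battery.mean_sensitivity
print(s.bias, (s.loa_lower, s.loa_upper), s.icc, s.cor)
# -0.001 (-1.49, 1.49) 0.8628 1.4880
```

The last line is the inter-grader agreement for mean junctional-zone
sensitivity over the 30 synthetic eyes: the graders are unbiased against
each other (−0.001 dB), 95% of their per-eye differences are expected
within ±1.49 dB, the ICC is 0.86, and a sensitivity change smaller than
1.49 dB is indistinguishable from registration noise. With zero click
jitter (`SimulationConfig(...).with_jitter(0.0)`) every ICC is exactly 1
and every CoR is 0.

The same workflow runs from the shell on files
(`mpjunction grid | simulate | register | analyze | repeatability`);
see `mpjunction --help`.

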