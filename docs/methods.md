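# Methods

This note records the models, conventions and numerical choices behind
`mlcsens`, and what the synthetic cohort does and does not emulate.

## Plan model and coordinates

Plans follow IEC 61217: leaf and jaw positions are millimetres projected to
the isocenter plane, bank 1 is the negative-X bank, so `x1 <= x2` for every
opposed pair. Leaf positions are stored per control point (static
interpretation); how apertures are treated *between* control points is a
dose-engine convention, not part of the model. The default MLC geometry is
80 pairs of 5 mm leaves with a 0.5 mm minimum dynamic gap — a configurable
choice, not a measured machine property. The JSON dialect stores every
field verbatim (units mm / MU / Gy); DICOM-RT Plan round trips preserve
leaf positions to better than 0.001 mm (DS precision is 5 decimals).

## Synthetic cohort

Each site template defines a phantom (2 mm isotropic grid, 56×56×44
voxels, isocenter at the grid centre) and an aperture-generation recipe:

| site | target | OARs | aperture margin | prescriptions |
|---|---|---|---|---|
| prostate | sphere ⌀45–55 mm | rectum (posterior cylinder), bladder (anterior–superior sphere) | 6 mm | 78 Gy/39 fx, 36.25 Gy/5 fx |
| lung | sphere ⌀30–40 mm, lateral | normal lung (ellipsoid) | 6 mm | 60 Gy/30 fx, 52 Gy/4 fx |
| brain met | sphere ⌀20–28 mm | normal brain (sphere) | 9 mm | 42 Gy/10 fx, 30 Gy/3 fx |
| spinal met | ~300° annulus r≈8–17 mm around the cord | spinal cord (cylinder r 5 mm) | 4 mm | 30 Gy/10 fx, 16 Gy/1 fx |

Target sizes and OAR positions are jittered per case seed; the cord is
never jittered because the wrap topology is structural. Table-style dose
constraints are carried per template for DVH *reporting* only — there is no
inverse optimization.

A plan is a single 360° arc (default 90 control points). Per control point
the aperture is the target's beam's-eye-view outline plus the template
margin, applied in both the leaf-travel and leaf-width directions so the
superior/inferior target edges are not penumbra-limited. The `modulation`
knob m ∈ [0, 1] then:

* narrows each gap by `shrink_gain · m · (0.3 + 0.7 s)` of its width, with
  `s` a per-leaf/per-control-point sinusoid (site gains 0.60/0.50/0.35/0.22
  for spine/lung/prostate/brain);
* jitters each gap centre with SD `jitter_gain · m` (7/6/4/2.5 mm,
  ×1.4 for the `static_jaw` profile);
* roughens the meterset weights (`w ∝ 1 + 2m|N(0,1)|`);
* raises the meterset: MU = base·MU/Gy · (outline area / delivered
  area) · (1 + 2.5 m) · fraction dose. The openness ratio ties MU/Gy to
  the same gap narrowing that drives dose-error sensitivity — the physical
  reason the two correlate in delivered plans — and the explicit term
  guarantees ≳3× MU/Gy span across m ∈ [0.1, 0.9] within each site.

For the spinal template, rows crossing the cord keep only one side of it,
alternating per control point so the aperture sweeps both sides over the
arc; a blocked row never closes entirely (minimum 6 mm segment). Apertures
the generator closes deliberately park at (0, 0). The two sequencer
profiles differ in jaw handling (`jaw_tracking` fits the jaws per control
point; `static_jaw` fixes them to the arc envelope) and jitter amplitude;
FF/FFF is a label only. Everything is a pure function of (template, case
seed, modulation), so cohorts are bit-reproducible.

What this emulates: the *spread* of complexity and its coupling to dose-
error sensitivity across sites and sequencer styles. What it does not:
inverse-optimized fluence, deliverability (leaf speed, interdigitation),
heterogeneity, or any absolute clinical dosimetry. Passing tests therefore
certify orderings, linearity and correlation structure — not clinical
sensitivity magnitudes.

## Error injection

*Close* moves both banks toward each other by δ (gap −2δ); *open* the
reverse. δ is per bank because sensitivities are reported per millimetre of
leaf displacement. Random mode draws i.i.d. N(0, δ²) per leaf, bank and
control point. Pairs displaced below the mechanical floor are clamped
symmetrically about their midpoint to the minimum gap — except that a pair
already at or below the floor keeps its original gap (an error must never
open a closed pair); every clamp is logged as (beam, control point, leaf).
Parked pairs — at the floor *and* fully outside the Y jaws — are skipped by
default (`perturb_parked` overrides). Random-set builders take an explicit
replicate count; seeds derive deterministically from a base seed.

## Surrogate dose engine

Per control-point interval: fractional-coverage fluence of the MLC∩jaw
opening on a 1 mm grid (±110 mm), Gaussian penumbra σ = 3 mm, weighted by
the interval MU (cumulative-weight difference × beam MU, aperture taken
from the interval's starting control point), back-projected with parallel
rays along the interval's mean gantry direction, summed, and scaled so the
reference plan's target mean equals the prescribed fraction dose. The
calibration factor is frozen and reused for that plan's error variants —
re-normalizing would erase the dose error being measured. Fractional pixel
coverage keeps the dose response continuous (and hence linear) in
sub-millimetre leaf shifts. No scatter, attenuation, divergence or
spectral model: the engine is linear in fluence, which is the property the
sensitivity analysis rests on. Its absolute outputs are not clinical
dosimetry.

DVHs are differential histograms of mask-voxel doses (default bin 0.05 Gy,
total-dose scale by default). `D_x%` is the minimum dose of the hottest x%
(bin-centre convention), `V_xGy` the fractional volume at ≥ x Gy, `D_cc`
the hottest-volume variant.

## gEUD

Computed on differential DVH bins with bin-centre doses, through
log-sum-exp so a = ±100 stays finite in doubles. Bin centres are floored at
0.01 Gy so negative exponents remain defined when a structure holds
zero-dose voxels; the floored result is then correctly cold-spot-dominated.
Target exponents: prostate −25, lung −20, brain −10, spine −20. OAR
exponents default to 1/n of the Burman–Emami volume-effect parameter
(rectum 8.33, bladder 2, normal lung 1.15, cord 20, brain 4) and are
configuration, shipped as `data/a_values.json`. The a = 0 geometric-mean
limit is out of scope. gEUD is evaluated on the total-dose scale by
default (percent changes are scale-invariant; Gy/mm OAR slopes are not,
and total dose is the scale DVH constraints are written in).

## Statistics and tolerances

Sensitivity is the OLS slope (with intercept; the fit correlation r is
reported) of gEUD change versus error magnitude, per direction, with the
(0, 0) reference point included; a signed combined axis (close negative) is
also fit. Targets are reported in %/mm, OARs in Gy/mm. Group comparisons
and correlations pass a Shapiro–Wilk gate at α = 0.05 (t-test/Pearson when
normal, Wilcoxon signed-rank/Spearman otherwise); correlation strength
bands are ≤0.2 zero, ≤0.4 weak, ≤0.7 moderate, >0.7 strong. No
multiple-testing correction by default (per-comparison α = 0.05).

The scenario tolerance is `threshold / max(|slope_close|, |slope_open|)`
per case, averaged over cases (mean by default; median/min available —
with per-case reciprocals the mean exceeds threshold/mean-slope by
Jensen's inequality, which is the convention adopted). The default
threshold of ±2% target gEUD change corresponds to a dose error a standard
dosimeter can resolve. Zero-slope cases are flagged unbounded and excluded
rather than averaged.

## Problem sizes and determinism

Tests and the acceptance script use reduced cohorts chosen as the package's
own desk-scale defaults: a 4-case single-site (spinal) cohort on the full
0.25–2 mm grid for linearity and the random-vs-systematic contrast, and a
20-case four-site sweep (modulation 0.1–0.9, grid {0.5, 2} mm) for the
complexity correlations; phantoms at 2 mm spacing, 90 control points per
arc. All randomness flows from one base seed through named substreams
(cohort, plan, error, statistics), so every table reruns bit-identically.

## Known limitations

* The dose engine's absolute sensitivities and tolerances are surrogate-
  specific; only orderings, linearity and correlation structure transfer.
* Close/open responses are asymmetric for the spherical templates (margin-
  limited opening); the spinal template, whose leaf ends sit at the target,
  responds nearly symmetrically.
* One arc per plan, X-direction leaves only; no multi-beam or dual-layer
  MLC support.
* Gantry-angle, MU, jaw and dose-rate error modes are out of scope.
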