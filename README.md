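# mlcsens

Dose sensitivity of VMAT treatment plans to multileaf-collimator (MLC)
positional errors — and the MLC QA tolerances that follow from it.

## The problem

In volumetric modulated arc therapy the MLC shapes the radiation aperture at
every control point of the arc, and small calibration errors in leaf
position translate into delivered-dose errors. How large that translation
is depends on the MLC sequence: treatment site, sequencer style, fraction
size and plan complexity all change it, so a single facility-wide leaf
tolerance (e.g. "1 mm") protects some plans and not others. `mlcsens`
implements the full analysis chain needed to quantify this and to derive
site-specific tolerances:

1. **Synthetic cohort** (`mlcsens.cohort`) — four site templates (prostate,
   lung, brain metastasis, spinal metastasis) with voxel phantoms and
   single-arc VMAT plans whose apertures conform to the target outline. An
   explicit `modulation` knob narrows leaf gaps, roughens the sequence and
   raises MU/Gy, standing in for the complexity spread of clinical plans.
   The spinal template wraps a concave target around the cord and blocks
   the cord per control point — the geometry that drives high complexity.
2. **Error injection** (`mlcsens.errors`) — systematic *close*/*open* bank
   displacements (each bank moves by δ, the gap changes by 2δ) and random
   per-leaf Gaussian displacements with SD = δ, applied at every control
   point, with mechanical-gap clamping and a clamp log.
3. **Surrogate dose engine** (`mlcsens.dose`) — aperture fluence with a
   Gaussian penumbra, back-projected through the phantom per control-point
   interval, calibrated once on the reference plan and frozen for its error
   variants; DVHs and D_x%/V_xGy/D_cc queries.
4. **gEUD scoring** (`mlcsens.geud`) — the generalized equivalent uniform
   dose over differential DVH bins,

       gEUD = (Σᵢ vᵢ Dᵢᵃ)^(1/a),

   with site-specific target exponents (a = −25, −20, −10, −20 for
   prostate, lung, brain and spinal metastasis) and Burman-style OAR
   exponents; dose-error sensitivity is the slope of the gEUD change versus
   error magnitude, in %/mm (targets) or Gy/mm (OARs).
5. **Complexity metrics** (`mlcsens.complexity`) — MU/Gy and plan
   irregularity PI (Du et al.): per control point the aperture
   irregularity AI = perimeter²/(4π·area) of the rectilinear opening, MU-
   weighted into beam and plan irregularity.
6. **Statistics & tolerances** (`mlcsens.stats`, `mlcsens.study`) — OLS
   sensitivity slopes per direction, Shapiro–Wilk-gated t/Wilcoxon
   comparisons and Pearson/Spearman correlations, and the MLC tolerance per
   scenario: the largest error keeping the target's |ΔgEUD| within ±2%,
   i.e. `threshold / max(|slope_close|, |slope_open|)` aggregated over cases.

Plans round-trip through a documented JSON dialect (units mm/MU/Gy) and
DICOM-RT Plan via `pydicom`.

## Worked example

The numbered drivers under `analysis/` run the study at desk scale and
write their tables under `results/`. The sensitivity analysis on a
four-case spinal cohort:

```bash
$ python analysis/03_sensitivity_linearity.py
4 spinal cases -> results/sensitivity_spine.csv
target systematic slopes: close -17.71 %/mm, open +14.21 %/mm
linear-fit |r| range: 0.9991-0.9999
spinal-cord sensitivity: 4.53 Gy/mm
random vs systematic slope ratio: 0.176 (random MLC errors are dosimetrically minor)
```

Closing the banks lowers the target gEUD, opening raises it, the response
is almost perfectly linear in the error magnitude, and random (zero-mean)
errors matter far less than systematic ones. The complexity correlation on
a 20-case, four-site cohort with modulation swept over 0.1–0.9:

```bash
$ python analysis/04_complexity_correlation.py
  mu_per_gy vs sensitivity: spearman r = 0.967 (strong, p = 4e-12)
  pi vs sensitivity: spearman r = 0.940 (strong, p = 7.9e-10)
  mu_per_gy vs pi: spearman r = 0.965 (strong, p = 5.9e-12)
```

and the tolerance derivation (`analysis/05_tolerances.py`) orders the sites
spine < lung < prostate < brain — the most complex sequences demand the
tightest MLC tolerance. The absolute millimetre values depend on the
surrogate dose engine and synthetic cohort; the ordering and the
derivation are the transferable result.

A small CLI mirrors the library for one-off use:

```bash
mlcsens perturb --mode close --mm 1.0 --in plan.json --out plan_err.json
mlcsens complexity --in plan.json
mlcsens run --sites spine_met --n-cases 2 --out results/run1
```

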