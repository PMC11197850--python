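# adcrepro

Multi-centre reproducibility of apparent diffusion coefficient (ADC)
derivation from diffusion-weighted MRI (DWI).

The ADC is a candidate quantitative imaging biomarker for radiotherapy
response, measurable at every fraction on an MRI-linac. Before it can carry
clinical decisions it must be reproducible — yet two analysis choices made
independently at every centre move the number: *which delineation* the ADC
is read from, and *how* it is calculated (b-value subset, ROI-based vs
voxel-based fitting, mean vs median, fit method, voxel filters). This
package implements the analysis framework used to quantify and compare
those two sources of variation in a nine-centre setting, and — because the
patient data of such studies are not public — a synthetic study generator
that reproduces the design with known ground truth.

It is intended for medical-physics and image-analysis researchers setting
up multi-centre quantitative-DWI studies who need tested building blocks
for ADC calculation and reproducibility statistics.

## The model and the statistics

Signal decay follows the mono-exponential Stejskal–Tanner model

    S(b) = S0 · exp(−b · ADC)

fitted on the log scale, either by ordinary least squares (LLS) or by
weighted least squares with weights `w_i = S_i²` (WLLS), the first-order
inverse-variance weighting of `ln S` under constant additive noise. Eight
pre-specified *calculation conditions* form a 2×2×2 grid — {all b-values,
b ≥ 150 s/mm²} × {ROI-based, voxel-based} × {mean, median} — and a ninth,
centre-local method is any condition plus local fit/filter options.

For each case and ROI type, a **cross-table** holds the ADC of every
delineation (rows) under every centre's calculation method (columns). From
it:

- **CV_C** — mean over rows of the per-delineation coefficient of
  variation across methods (calculation-related variation);
- **CV_D** — mean over columns of the per-method CV across delineations
  (delineation-related variation); exact-zero CVs are excluded and counted;
- **wCV** — within-subject coefficient of variation from back-to-back
  test–retest scans, `wCV_i = sqrt(d_i²/2)/ȳ_i`;
- condition differences — Friedman tests per factor (Bonferroni m = 3)
  plus mean paired percent differences `100·(a−b)/((a+b)/2)`;
- delineation agreement — pairwise Dice and mean surface distance (mm).

The synthetic generator builds sphere-in-sphere lesions (GTV = lesion,
VTV = GTV minus necrotic core, CTV = GTV plus margin) with biexponential
IVIM signal — so low b-values carry perfusion contamination that inflates
all-b ADCs — plus Rician magnitude noise, per-centre delineation
perturbations, and nine distinct local calculation methods.

## Worked example

```python
from adcrepro import (PhantomSpec, build_phantom, add_rician_noise,
                      CalcCondition, BValueSet, Mode, Statistic, FitOptions,
                      compute_condition_adc)

spec = PhantomSpec()  # viable shell: D = 1.1e-3 mm^2/s, perfusion f = 0.10
series, gtv, vtv = build_phantom(spec)
noisy = add_rician_noise(series, sigma=2.0, seed=1)
for bset in BValueSet:
    cond = CalcCondition(bset, Mode.VOXEL_BASED, Statistic.MEDIAN)
    adc = compute_condition_adc(noisy, vtv, cond, FitOptions("wlls"))
    print(f"{bset.value:>5}: median voxel ADC = {adc*1e3:.3f} x 10^-3 mm^2/s")
```

prints

```
  all: median voxel ADC = 1.278 x 10^-3 mm^2/s
 b150: median voxel ADC = 1.088 x 10^-3 mm^2/s
```

The true diffusion coefficient is 1.1×10⁻³ mm²/s: restricting the fit to
b ≥ 150 s/mm² recovers it to ~1 %, while including the low b-values lets
the perfusion component inflate the estimate by ~17 % — the direction and
scale of the b-set effect that dominates calculation-related variation.

The full study pipeline runs from the shell:

```sh
adcrepro all -o results        # simulate 9 centres x 4 cases, fit, report
```

and writes cross-tables, CV summaries, contour statistics, wCV,
condition tests and a condition-mean summary table under `results/`.

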