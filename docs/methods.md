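# Methods

## Signal model and ADC estimation

All fitting assumes mono-exponential Stejskal–Tanner decay,
`S(b) = S0·exp(−b·ADC)`, estimated by linear regression of `ln S` on `b`.
Two estimators are provided:

- **LLS** — ordinary least squares. Because the variance of `ln S` grows
  as `σ²/S²` when the magnitude noise is (approximately) additive with
  constant σ, LLS over-weights the noisy high-b points.
- **WLLS** — weighted least squares with `w_i = S_i²`, the first-order
  inverse-variance weights. One pass, no iterative reweighting: the
  observed signal stands in for the expected one, which is adequate at the
  SNRs where a log-linear fit is sensible at all.

Both are closed-form (weighted normal equations), vectorised over voxels.
For exactly two b-values the two estimators coincide (perfect
interpolation) and R² is reported as undefined rather than 1.0. R² is
computed on the `ln S` scale with the fit's weights.

Non-positive signals have no logarithm. The default policy drops the
offending b-point from that voxel's fit and drops the voxel only when
fewer than `min_points` (default 2) remain; a stricter `drop_voxel`
policy discards the voxel outright. Voxel-based maps additionally filter
fitted values to a physical range, default (0, 4×10⁻³) mm²/s — the upper
bound exceeds free-water diffusivity at body temperature, so values
outside it are non-physical. Optional, off-by-default filters exclude
voxels by minimum SNR at the lowest fitted b-value or by minimum R².
Every map satisfies `n_used + n_excluded = mask size`.

### Calculation conditions

The pre-specified grid is 2×2×2: b-subset ∈ {all acquired b-values,
b ≥ 150 s/mm²} × {ROI-based, voxel-based} × {mean, median}. "All" means
every acquired b-value, including b = 0 when present. ROI-based fits use
the per-b mean (or median) in-mask signal and fit one curve; voxel-based
fits every voxel and aggregates the retained per-voxel ADCs. The median
of an even count is the mean of the two central values. A centre-local
("own") method is a condition plus local fit method and filters. For the
ROI-based branch with a median statistic, the median signal per b-value
is aggregated before fitting; the alternative (fit, then median) is the
voxel-based branch.

## Delineation agreement

Dice = 2|A∩B|/(|A|+|B|). The mean surface distance (MSD) is the symmetric
average of the two directed mean nearest-surface distances between
voxel-centre surfaces: a mask voxel is surface iff a 6-connected
face neighbour is background or off-grid. Distances are Euclidean in mm
with anisotropic voxel spacing; no sub-voxel mesh is extracted, which
keeps the metric deterministic and exactly checkable against an
all-pairs oracle. Pairs involving an empty delineation are skipped and
counted, never imputed.

## Reproducibility statistics

For each case and ROI type the cross-table has delineations as rows and
calculation methods as columns. CVs use the sample (n−1) standard
deviation over the mean — small-n rows and columns make the ddof choice
material. CV_C is the mean of per-row CVs, CV_D the mean of per-column
CVs; rows/columns with fewer than two present values are skipped and
logged; CVs that are exactly zero are excluded from the means and
counted, because coarse reporting precision (e.g. local software printing
one decimal) produces spurious zeros — an ingestion helper
(`round_to_decimals`) reproduces that mechanism for testing.

wCV per case is `sqrt(d²/2)/ȳ` for the test–retest pair, and the pooled
value is the root mean of per-case squared wCVs (the per-case values are
primary, since each case is a single subject). Both are invariant to a
common rescaling.

The Friedman test is implemented as rank ANOVA with mid-ranks, which
incorporates the standard tie correction and reduces to
`12n/(k(k+1))·Σ_j(R̄_j−(k+1)/2)²` without ties; p-values come from the
χ²(k−1) approximation. The in-package implementation exists because the
condition comparisons have k = 2 treatment levels, which scipy's
`friedmanchisquare` rejects; for k ≥ 3 it agrees with scipy exactly and
with a within-block permutation null to Monte-Carlo error. Blocks for the
factor tests are every (case × delineating centre × calculating centre ×
other-factor combination) on GTVs only; the blocking is recorded in the
output. The three factor p-values are Bonferroni-corrected with m = 3.

Percent differences are paired at the finest available level and use the
pair mean as denominator, `100·(a−b)/((a+b)/2)`; applying this formula to
the published adrenal-GTV condition-mean row reproduces the published
b-set difference within input-rounding error (32.91 vs 32.86), which is
the evidence for this convention. Condition-mean summary tables report
ADC in 10⁻³ mm²/s at 2 decimals with an unweighted column-mean row.

## Synthetic study generator

The generator emulates a nine-centre, four-case study with known truth.

**Geometry.** Each case is a sphere-in-sphere phantom on a
48×48×20 grid with 2×2×4 mm voxels: GTV = lesion sphere, necrotic core =
concentric inner sphere, VTV = GTV minus core exactly, prostate-analogue
CTV = lesion plus a 4 mm margin. Case presets (lesion radius 7–16 mm,
viable-tissue D 0.9–1.3×10⁻³ mm²/s, per-case delineation-perturbation
scale) qualitatively mirror the study's spread — the small pancreas
lesion is most sensitive to delineation, the prostate analogue has the
largest delineation variation — with no claim of quantitative match.

**Signal.** Biexponential IVIM,
`S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]`, with defaults f = 0.10 and
D* = 50×10⁻³ mm²/s in viable tissue: perfusion decays away below
b ≈ 100 s/mm², so fits that include low b-values overestimate ADC, in the
reported direction. Two acquisition sets are used, (0, 30, 80, 150, 500)
and (30, 80, 150, 300, 500) s/mm², two cases each.

**Noise.** Rician magnitude noise `sqrt((S+n₁)²+n₂²)` with σ = 2 (SNR 50
at b = 0 for viable tissue). At low SNR the Rayleigh-distributed floor
props up the high-b signal, flattening the decay: ADC is underestimated,
and the tests assert that direction at SNR(b=500) ≤ 3.

**Centres.** Each centre contributes (a) a perturbed delineation per ROI
— Gaussian rigid shift (σ 1.0–1.8 mm × case scale, rounded to voxels)
followed by a random dilation or erosion, never emptying the mask — and
(b) a distinct local calculation method. All local methods are
voxel-based, differing in b-subset, statistic, fit method and filter
range. Under *aligned* conditions each centre keeps its local fit method
and filters while the condition (b-subset, mode, statistic) is fixed:
this models the residual software-implementation variation that condition
alignment cannot remove, and makes the aligned CV_C small but non-zero.
Test and retest differ only in the noise realisation (no repositioning).
All child seeds derive from the master seed by hashing (case, centre,
role), so components are decoupled and every run is reproducible;
volumes are voxel-identical and manifests byte-identical across runs.

**What the generator does not emulate.** Real anatomy and partial-volume
mixtures, EPI geometric distortion, motion between b-values, multi-coil
noise correlation, T2/TE weighting, physiological test–retest change, and
observer-specific delineation bias. Passing tests therefore demonstrate
correctness of the estimators and statistics under the stated model, not
clinical-scale effect sizes: synthetic wCV (~1 %) and CV magnitudes are
smaller than the patient values, while directions (perfusion inflation,
alignment reducing CV_C, noise-floor underestimation) are the asserted
content.

## Pipeline conventions

Every calculating centre evaluates every delineation under its own method
and all eight aligned conditions (9 methods/centre), so the default study
yields 72 × 9 × 9 = 5832 cells; failed cells are recorded as missing with
a reason and the accounting identity computed + missing = expected is
asserted on every run. Cross-table values are stored in 10⁻³ mm²/s;
non-positive fit results become missing cells. Reports (CSV/JSON/
Markdown) embed the config hash, seed and software version and are
byte-reproducible. Problem sizes (grid, sphere radii, replicate counts in
the statistical tests) are chosen so the whole suite and the acceptance
script each run in well under a minute on one CPU while keeping ≥10³
voxels where distributional assertions are made.

## Known limitations

- ROI-based ADC is mathematically inconsistent with averaging per-voxel
  ADCs for heterogeneous ROIs; both are implemented because both are in
  field use, and their difference is itself a reported statistic.
- No noise-floor bias correction, IVIM/kurtosis fitting, or nonlinear
  (Levenberg–Marquardt) estimation; out of scope by design.
- Masks are assumed to live on the DWI grid; no resampling from an
  anatomical grid, no DICOM-RT contour parsing, no b-value registration.
- The stored-value unscaling convention is `true = m·stored + c` with
  user-supplied (m, c); vendor-specific scaling dialects are not
  auto-detected.
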