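# Methods

## The ALPS readout

The ALPS index assumes a specific geometric configuration that holds at
the body of the lateral ventricle: projection fibers along z, association
fibers along y, subcortical fibers along x, and the perivascular spaces of
the medullary veins along x. Under that configuration the x-axis
diffusivity measured in the projection and association ROIs is
perpendicular to both fiber families, so any excess over the reference
perpendicular diffusivities (Dyy in the projection ROI, Dzz in the
association ROI) is attributed to water movement along the perivascular
space:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

The index is computed per subject from that subject's own trimmed ROI
means and only then summarised across subjects; the index of group-mean
diffusivities is *not* the group-mean index (the ratio is nonlinear), and
the per-subject ordering is what the group t-test needs.

Axis diffusivities are the diagonal entries of the fitted tensor in the
image frame — deliberately not eigenvalues. The readout is only
meaningful when fibers are axis-aligned; the phantom enforces this by
construction and exposes an oblique-rotation angle (default 0°) to probe
violations.

### Trimmed ROI means

Each of the nine (fiber × axis) cells is the arithmetic mean over the
ROI's valid voxels after removing exactly one occurrence of the maximum
and one of the minimum. Two consequences of this definition are treated
as contracts and tested: the contributing count is always `mask − 2`
(ties do not remove extra voxels), and trimming is independent per cell —
the voxel with the largest Dxx still contributes to the Dyy and Dzz
means of the same ROI.

## Phantom and signal model

The phantom is a 16×16×6 voxel grid (2 mm isotropic; RAS-like axes)
holding three disjoint 4×4×4 fiber boxes in an isotropic background
(0.8×10⁻³ mm²/s). Tensors are diagonal in the image frame:

| region       | Dxx                      | Dyy      | Dzz      |
|--------------|--------------------------|----------|----------|
| projection   | 0.45×10⁻³ + g·Δpv        | 0.50×10⁻³| 1.05×10⁻³|
| association  | 0.536×10⁻³ + g·Δpv       | 1.05×10⁻³| 0.40×10⁻³|
| subcortical  | 1.10×10⁻³                | 0.65×10⁻³| 0.65×10⁻³|

with Δpv = 0.2456×10⁻³ mm²/s. The dimensionless glymphatic coefficient
g ∈ [0, 1] is the simulation's ground truth: it scales the perivascular
x-axis gain in the two ROIs the index reads. The noiseless index is then
the closed form

    ALPS(g) = 1.095675 + 0.54575·g,

which the end-to-end pipeline must reproduce to 1×10⁻⁹ on noiseless
input. The baseline/gain values were calibrated in closed form (no
simulation involved) so that the default group coefficient means
g = 0.3 and g = 0.7 map onto group mean indices of 1.2594 and 1.4777 —
the working values of the early-CKD case-control scenario the cohort
generator emulates — while each per-axis diffusivity stays at a
plausible deep-white-matter magnitude. Group *standard deviations* are
not calibrated: with the default g-spread of 0.1 the simulated ALPS SD
(~0.03–0.06) is smaller than the ~0.2 printed in such studies, because
the phantom omits the anatomical and physiological variability (ROI
placement, partial volume, pulsation) that dominates real between-subject
spread. Group-level *means* and the direction and detectability of the
group difference are therefore the quantities the simulation is meant to
reproduce; absolute p-values of simulated comparisons will be smaller
than in real data.

Signals follow the Stejskal–Tanner monoexponential model
S = S0·exp(−b·gᵀDg) on a scheme of one b = 0 volume plus 32 directions at
b = 1000 s/mm². The direction table was produced once by L-BFGS
minimisation of the antipodally symmetric Coulomb energy of 32 axes
(minimum inter-axis angle 24.8°) and frozen into the source, so the
scheme is identical in every run. Noise is Rician by default — the
magnitude of the complex signal with two independent Gaussian channels,
the correct model for magnitude MRI, with its characteristic positive
bias at low SNR — at σ = 20 for S0 = 1000 (SNR 50 at b = 0, typical of a
3 T DTI protocol). A plain Gaussian model is available behind a flag;
σ = 0 is the exactness path used by round-trip tests.

## Tensor fitting

Ordinary least squares on the log-linearised model, 7 unknowns per voxel
(6 tensor components + ln S0), solved with one pseudoinverse for the
whole volume. Design choices:

* **OLS, not WLS, by default.** The estimator is closed-form and exactly
  inverts noiseless data (round-trip tolerance 1×10⁻¹⁰ relative over
  1000 random SPD tensors); iteratively reweighted LLS is available via
  `weighted=True` for noisy data.
* **Signal flooring.** Nonpositive or tiny signals are floored at
  1×10⁻⁶ of the voxel's b0 mean before the log; a voxel needing the
  floor for more than half its measurements (or with no positive b0
  signal) is marked invalid rather than raising, and invalid voxels are
  excluded from every downstream mean.
* **No positive-definiteness projection.** Fitted tensors may have
  negative diagonal entries under noise; clamping (to 0, with a count)
  happens only at axis-map extraction, keeping the estimator linear.
* **Degenerate schemes fail loudly.** A direction set whose design
  matrix is rank-deficient (fewer than six independent directions)
  raises a scheme error before any voxel is fit.
* Multiple b = 0 entries all enter the regression; there is no
  pre-averaging.

Fractional anisotropy (from eigenvalues, standard formula) is provided
purely as a QC aid for phantom orientation checks.

## Cohort generator

Per subject, g is drawn from the group's truncated normal (resampling
into [0, 1], max 1000 attempts, then error). Defaults: patients
g ~ N(0.3, 0.1), controls g ~ N(0.7, 0.1), 18 subjects per group.

Covariates emulate an early-CKD case-control table: ages N(65.9, 9.9) vs
N(66.4, 6.3) years, male fractions 9/18 and 11/18, and a patient lab
panel of independent normals (hemoglobin, hematocrit, protein, albumin,
AST, ALT, BUN, creatinine, electrolytes, total CO₂, cholesterol) at the
scenario's means/SDs. Lab–lab correlation is not modelled — a known
simplification. eGFR is drawn uniformly within the band of the subject's
CKD stage (3a: 45–59, 3b: 30–44, 4: 15–29 ml/min/1.73 m²) so stage and
eGFR stay consistent. Controls carry no lab panel (healthy reference
group; the correlation analysis is patients-only anyway).

The patient group's joint diabetes/hypertension composition (5 both, 3 DM
only, 8 HTN only, 2 neither, of 18) and stage composition (5/10/3) are
assigned by largest-remainder apportionment of those fractions and then
shuffled — not drawn iid — so subgroup comparisons are well defined in
every replicate at any group size. This trades a little realism
(composition is fixed, not sampled) for determinism of the analysis
structure.

Reproducibility is bit-level: one master generator seeded by the study
seed drives covariates and spawns per-subject simulation seeds, and
identical (config, seed) produces byte-identical CSV outputs.

## Statistics

* **Student's t = pooled variance**, df = n1+n2−2, two-tailed. The
  summary-statistics route (`t_test_from_summary`) is the primary
  implementation and the raw-sample route reduces to it; the two agree
  to 1×10⁻¹² by construction and the summary route is cross-checked
  against `scipy.stats.ttest_ind_from_stats` in tests. Welch's test is
  available for sensitivity analyses, not used by default.
* **Categorical 2×2**: uncorrected Pearson chi-square when all expected
  counts ≥ 5, else two-sided Fisher exact; the result carries a method
  tag. Published tables sometimes use variants that are not recoverable
  from the printed counts; no attempt is made to force agreement there.
* **Correlation**: Pearson, p from t = r·√((n−2)/(1−r²)) on n−2 df;
  Spearman behind a flag. Computed within the patient group by default.
* **Multiplicity**: the nine per-axis diffusivity comparisons share a
  Bonferroni threshold α/9 = 0.00555…; the ALPS row itself is judged at
  the raw α, mirroring how such tables treat the index as the single
  primary endpoint.
* p-values are reported raw and additionally rounded to 4 decimals in
  emitted tables.

Under the null (both groups drawing the same g) the group test's
rejection rate at α = 0.05 stays within the binomial band [0.025, 0.085]
over 400 replicates; under the calibrated separation the control > patient
ordering of group means is detected in ≥ 95 of 100 replicates. Both are
asserted in the acceptance tests at those replicate counts, chosen to
keep the full suite around a minute of compute.

## Numerical and degenerate-input policy

* Trimmed mean of fewer than 3 values: error (undefined after
  exclusion); an ROI cell with fewer than 3 valid voxels: error naming
  the fiber.
* ALPS with any nonpositive input cell: error.
* Zero pooled variance: t = 0, p = 1 when the means agree, error
  otherwise.
* Zero-variance samples in a correlation: error; the pipeline emits NaN
  rows for covariates that are degenerate in a given cohort instead of
  failing the run.
* Truncated-normal sampling failure after 1000 attempts: error (occurs
  only for parameter choices whose mass is essentially outside [0, 1]).

## Known limitations

* The phantom is artifact-free: no eddy currents, susceptibility
  distortion, motion, partial-volume CSF, or white-matter
  hyperintensities — so preprocessing (artifact correction, masking) is
  out of scope and passing tests say nothing about robustness to those
  effects in real scans.
* Fibers are exactly axis-aligned by default; real anatomy is not, and
  the ALPS readout degrades with obliqueness (the rotation parameter
  exists to study exactly that, but no correction is implemented).
* Between-subject ALPS variance is under-dispersed relative to real
  cohorts (see calibration note above).
* ROI placement on real scans is manual by assumption: masks are inputs,
  and no atlas registration or automatic placement is provided.
* One ROI set per subject by default; bilateral analysis (the mean of two
  per-hemisphere indices, `bilateral_alps_index`) is available but off
  the default path.
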