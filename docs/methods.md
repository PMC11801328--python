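# Methods

## Scope

`placenta_dwr` implements a combined diffusion-relaxation analysis of
placental MRI: forward signal models and voxel-wise fitting of a
mono-exponential T2*-ADC model and a two-compartment T2*-IVIM model,
single-tensor fractional anisotropy at the shortest echo time, ROI
summarisation with exclusion of supraphysiological T2*, and the cohort
statistics of a preterm-birth case-control study (gestational-age
trends, case-control and membrane-status contrasts, and a latency-ratio
split of the cases).  Because no scan data are distributed, a synthetic
generator produces phantoms and cohorts with the statistical structure
the analysis expects; every stage is validated against it.

## Signal models

With `TE` the echo time, `TE_min` the shortest echo time acquired, `b`
the diffusion weighting and `S0` the signal at `TE_min` with `b = 0`:

mono-exponential T2*-ADC

    S(TE, b) = S0 · exp(−(TE − TE_min)/T2*) · exp(−b·ADC)

two-compartment T2*-IVIM

    S(TE, b) = S0 · [ f · exp(−(TE − TE_min)/T2*_fast) · exp(−b·D*)
                    + (1 − f) · exp(−(TE − TE_min)/T2*_slow) · exp(−b·ADC) ]

`f` is the perfusion fraction of the fast (pseudo-diffusing, perfusing
blood) compartment; `D*` its pseudo-diffusion coefficient; `ADC` the
true tissue diffusivity.  Compartments are always relabelled so that
`D* > ADC` and `f` refers to the fast one.  FA is computed from a
single-tensor fit `S = S0 · exp(−b·gᵀDg)` restricted to the
shortest-echo-time volumes, with eigenvalues clamped at zero, so FA lies
in [0, 1] by construction.

## Acquisition scheme

The protocol object encodes 60 diffusion preparations — three gradient
directions at b = 5, 10, 25, 50, 100, 200, 400, 600, 1200 and
1600 s/mm², eight at b = 18, seven at b = 36 and fifteen at
b = 800 s/mm² — each acquired at TE = 78, 114, 150 and 186 ms
(240 volumes, no b = 0).  Gradient directions are not part of the
printed protocol; each shell's directions are generated by
electrostatic-repulsion spreading on the sphere (antipodally symmetric,
fixed per-shell seeds), sorted into a canonical hemisphere order so the
scheme is bit-reproducible.  Sidecars use the FSL bval/bvec dialect plus
a same-length TE file in ms, written with 6 significant digits.

## Fitting

All fits are bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`) with analytic Jacobians.

* **T2*-ADC**: initialised by two log-linear regressions (log-signal
  vs TE at low b for T2*; vs b at `TE_min` for ADC); bounds
  T2* ∈ (1, 300] ms, ADC ∈ [0, 0.01] mm²/s.  The physiological
  > 200 ms exclusion is *not* a fit bound — it is applied downstream at
  the ROI stage so its effect on summaries stays observable.
* **T2*-IVIM**: the `segmented` strategy first fits the slow
  compartment on b ≥ 200 s/mm² (where the fast compartment has decayed
  to ~10⁻⁵), then fits the fast compartment on the remaining
  measurements with the slow prediction as a fixed baseline.  The
  `full` strategy refines the segmented estimate by a joint six-
  parameter fit with five randomised restarts (seeded; lowest residual
  wins, ties to the first start).  Degenerate fits with `f` pinned at a
  bound and indistinguishable compartments are flagged non-identifiable.
* **Tensor/FA**: weighted log-linear fit (weights proportional to the
  signal, the standard first-order noise propagation for log-
  linearised decays); requires at least six non-collinear directions
  plus a low-b reference, enforced through the design-matrix rank.

### Rician noise handling

Magnitude MRI noise is Rician.  At SNR 30 the noise floor
(σ·√(π/2) ≈ 4 % of S0) dominates the most attenuated measurements
(high TE, high b), and a fit of the raw magnitude underestimates the
fast compartment's T2* by ~18 % while Gaussian-noise controls are
unbiased — the bias is purely the floor.  When the noise SD is known
(`FitConfig.sigma`), the model therefore predicts the exact Rician
expectation

    E[M | S, σ] = σ·√(π/2) · [(1 + x)·I0e(x/2) + x·I1e(x/2)],  x = S²/(2σ²)

computed with exponentially scaled Bessel functions (stable at any
SNR), with the matching analytic derivative in the Jacobian.  This
removes the floor bias (all median parameter biases < 3 % at SNR 30).
With `sigma=None` (default) the fit uses the raw magnitude; estimating
σ from data (e.g. background air) is the user's responsibility and a
known limitation.

### Identifiability

The IVIM objective has a flat valley coupling T2*_fast and D*: on this
protocol, exhaustive grid search and the trust-region optimiser agree
to within one grid cell for S0, f, T2*_slow and ADC, but the
fast-compartment axis can wander a few cells at essentially identical
residual, even on noiseless data.  This is a property of the model and
sampling, not of the optimiser; D* in particular should be treated as
weakly identifiable, and single-voxel fast-compartment estimates
scatter far more than ROI means.

## ROI summarisation

Voxels with fitted T2* above 200 ms are treated as supraphysiological
(fluid or maternal blood pool) and excluded; the rule is strictly
greater-than, so 200 ms exactly is retained.  For the IVIM model the
rule is applied to both compartments' T2* maps through the same code
path (which map(s) to threshold is configurable).  The summary is the
arithmetic mean over retained voxels (median available, never the
default); an empty retained set yields NaN means and flags the subject
for exclusion from cohort statistics rather than raising.

## Cohort statistics

All comparisons are two-sided OLS at α = 0.05 with no multiple-testing
correction.  Group contrasts regress each parameter's ROI mean on
gestational age at MRI plus a case indicator (controls as reference);
subgroup contrasts restrict cases to the PPROM or intact-membranes
subset while keeping all controls.  GA adjustment is configurable; the
GA trend among controls is a separate fit.

For cases, the latency ratio is

    ratio = (GA_delivery − GA_MRI) / (GA_MRI − GA_onset)

which *decreases* as the scan sits relatively closer to delivery.  (The
other orientation — time since onset over time to delivery — increases
toward delivery; it is available behind an `invert` flag but never the
default, since the decreasing-toward-delivery direction is the
documented convention.)  Ratios are z-scored over the scored cases
(population SD) and split at zero; a z of exactly 0 goes to the
above-zero side (measure-zero for continuous ratios).  The split
contrast is OLS on a below-zero indicator.  A constant outcome is
reported as zero slope with p = 1 rather than a 0/0 t-statistic.

## Synthetic generator

The generator is configuration, not measurement; every level lives in
one frozen dataclass (`GeneratorConfig`) so studies are reproducible
and the null configuration (`without_effects()`) is one call away.
Defaults, chosen to be physiologically plausible for placenta:

| parameter | default | meaning |
|---|---|---|
| `s0` | 100 a.u. | signal at TE_min, b = 0 |
| `f_mean` | 0.25 | perfusion fraction |
| `d_star` | 0.05 mm²/s | pseudo-diffusion coefficient |
| `adc_mean` | 2.0e-3 mm²/s | tissue diffusivity |
| `fa_mean` | 0.12 | GA-constant FA level |
| `t2_slow_at_20wk`, `t2_slow_slope` | 70 ms, −2.5 ms/wk | control slow-compartment T2* declines with gestation (floor 25 ms) |
| `t2_fast_offset` | +40 ms | fast compartment T2* above slow |
| `pprom_t2_factor_fast/slow` | 0.75 / 0.75 | PPROM reduces both compartments |
| `intact_t2_factor_fast/slow` | 0.97 / 0.85 | intact membranes: predominantly the slow compartment |
| `latency_t2_slow_max_reduction` | 0.15 | extra slow-T2* reduction as delivery nears |
| `latency_f_max_reduction` | 0.30 | perfusion-fraction gradient toward delivery |
| `spatial_cv` / `subject_cv` | 0.10 / 0.08 | voxel-wise and between-subject variability |
| `snr` | 30 | S0/σ, Rician |
| cohort | 23 cases (14 PPROM) / 52 controls | case-control structure |

Latency proximity is `exp(−latency/8 d)`.  The perfusion-fraction
effect is *centred* on the cases' mean proximity: perfusion falls below
the case average near delivery and sits above it far from delivery, so
the within-case gradient that the latency split detects does not move
the case-vs-control mean — reproducing the observed dissociation
(group f contrast null, split f contrast negative) as an explicit
generator choice.

The MRI-to-delivery interval is gamma-distributed with realised mean
8 d and SD 8.7 d (shape (8/8.7)², scale 8.7²/8).  A lower-truncated
normal cannot realise these moments — its coefficient of variation is
below 1 on positive support while 8.7/8 > 1 — so gamma is the minimal
positive-support distribution matching them.  Cases deliver uniformly
in [26, 31.9) weeks with symptom onset 0.5–4 weeks before the scan;
controls deliver in [37, 42) and are scanned in [20, 37); draws that
would put the scan before 20 weeks are resampled and counted.

Phantoms are ellipsoidal parenchyma masks (semi-axes 0.42 of the grid)
with parameter maps modulated by smooth Gaussian random fields
(σ = grid/8) of 10 % fractional SD.  What the generator does **not**
emulate: motion and its correction, coil/reconstruction effects, fetal
anatomy, sub-regional structure (basal plate vs periphery), partial
voluming at the placental boundary, or between-vendor TE/b sampling
differences.  Passing tests therefore validate the estimators and the
statistical machinery under the stated noise model, not robustness to
those real-world effects.

## Problem sizes

Desk-scale defaults keep every stage interactive: phantoms default to
32³ standalone and (16, 16, 12) inside the pipeline; the end-to-end
qualitative-pattern check uses (8, 8, 6) grids (~120 parenchyma voxels
per subject, ROI-mean standard errors ≈ 1 %) across five replicate
cohorts at the full 23/52 cohort size; calibration uses 500 simulated
cohorts on the generator's subject-level means.  Voxel counts only
tighten ROI means — group effects are injected at subject level — so
grid size trades runtime against ROI-mean precision, not against the
effects under test.

## Known limitations

* σ must be supplied for the Rician-expectation fit; no background-air
  estimator is included.
* D* is weakly identifiable on this sampling (see Identifiability) and
  is excluded from recovery guarantees.
* No spatial regularisation between voxels; maps are independent fits.
* The latency split assumes the case set yields both sides; near-tie
  cohorts (all ratios equal) are rejected rather than split arbitrarily.
* Demographic tables, histopathology subgroups and motion correction
  are out of scope.
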