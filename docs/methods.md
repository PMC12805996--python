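# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `ramanqa`.

## Data model

A *ramanome* is a set of single-cell Raman spectra (SCRS) on one shared,
strictly increasing wavenumber axis in cm⁻¹.  The instrument calibration
window is 320–4256 cm⁻¹; axes extending outside it trigger a warning, not
an error, since resampled or trimmed acquisitions are legitimate.  Spectra
arriving on differing grids are linearly interpolated onto a target axis
(linear interpolation keeps piecewise-linear test fixtures exact and is the
standard choice for Raman resampling); target points outside a cell's
native range are zero-filled and the cell flagged.  Intensity units are
arbitrary throughout — normalization and the ratio-based vitality metrics
remove any absolute-intensity semantics.  Missing metadata defaults to
`batch_id="batch1"`, `d2o_hours=0`, so minimal files run the full pipeline.

## Baseline correction (arPLS)

Baselines are estimated by asymmetrically reweighted penalized least
squares: minimize `(y−z)ᵀW(y−z) + λ zᵀDᵀDz` with `D` the second-difference
operator.  Each iteration solves the weighted system, then updates weights
by a logistic function of the residuals below the baseline: with
`d = y − z`, `m` and `s` the mean and SD of the negative part of `d`,
`wᵢ = logistic(−2(dᵢ − (2s − m))/s)`.  Iteration stops when the relative
change of the weight vector falls below the sensitivity parameter, or at
`max_iter`.

* `lam = 1e6` (smoothness) and `ratio = 0.05` (sensitivity) are the
  pipeline defaults; `max_iter = 50`.
* The system `W + λDᵀDz` is pentadiagonal and is solved by banded Cholesky
  factorization with one step of iterative refinement, which brings every
  iterate within ~1e-9 of a dense direct solve of the identical system
  (verified in the tests against `numpy.linalg.solve`).
* `corrected = input − baseline` holds to machine precision.

**Degenerate input caveat.** On *exactly* noiseless input the negative
residual scale `s` collapses, the logistic weights harden into a threshold,
and the baseline erodes toward the lower envelope of the signal — recovery
bounds do not hold there.  Any realistic noise floor (≥0.5% of the drift
amplitude) regularizes the weights; the recovery tests therefore use
drift+peaks fixtures with a small noise floor, on which the baseline is
recovered within ~1% and 100-unit peak heights within ~0.2%.

An optional Savitzky–Golay smoothing stage is deliberately absent by
default; arPLS plus band selection suffices for the synthetic regimes and
keeps the chain minimal.

## Quality control

After baseline correction, per cell:

* `SNR = max(corrected intensity in the fingerprint band) / SD(corrected
  intensity in the silent region)`.  The silent region defaults to
  1730–1980 cm⁻¹ *minus* any overlap with the fingerprint/C-D/C-H bands
  (effectively 1802–1980 cm⁻¹), a window where cells have no Raman bands.
  Cells with `SNR < 3` are dropped (`low_snr`).
* Surviving cells are screened once by Pearson correlation against the mean
  of SNR-passing spectra; `ρ < 0.70` drops the cell (`outlier`).

These thresholds are package defaults, exposed in `PreprocessConfig` and
recorded in the QC report — they are operating choices, not claims about
any particular instrument vendor's QC.  Note that for pure Gaussian noise
the *maximum* over ~650 fingerprint points is ≈3.3σ, so a pure-noise cell
sits marginally above the default SNR gate and is instead caught by the
correlation rule; raising `snr_threshold` to 5 makes the SNR gate itself
reject such cells.

## Normalization and feature construction

Per-cell max-min normalization maps a spectrum onto [0, 1]; it is monotone,
so peak shapes are preserved up to affine scale, and it errors on constant
spectra (which QC should have removed).  Normalization is applied *after*
band selection when building classifier features, so [0, 1] refers to the
analyzed window.  The C-D ratio is computed on baseline-corrected,
**un-normalized** intensities — the ratio is scale-invariant, so the choice
is harmless, but determinism requires fixing it.

## Classification

Features are normalized fingerprint-band intensities (500–1800 cm⁻¹ by
default; the window is configurable since the biological fingerprint has no
single canonical boundary).  Algorithms: LDA, RF (500 trees), SVM (RBF),
Gaussian NBC, KNN (k=5), DT (unlimited depth) — hyperparameters are
config-exposed defaults.  LDA on raw spectra is ill-posed when features
approach sample count, so the LDA route is PCA retaining 99% of variance
followed by linear discriminants; shrinkage LDA (Ledoit–Wolf) is available
behind a flag.  Splits are stratified (protecting minority classes); KNN
and posterior ties resolve to the lowest label index via scikit-learn's
deterministic argmax.  Accuracy is reported per cell (micro); a macro
average is also emitted.  All sampling flows from one seeded generator and
the seed is recorded in the model manifest.

Prediction is closed-world: a cell of a species absent from the database
receives some in-vocabulary label.  Open-set recognition is out of scope.

## Spike-in counting

With classifier proportions `p_test`, `p_ref` over *all* classified cells
and mixing volumes `v_test : v_ref`:

    c_test = n_ref · (p_test / p_ref) · (v_ref / v_test)   [CFU/mL, pre-mix]
    CFU/g  = c_test · Π(dilution factors) / (g powder per mL)

Strain proportions used for live-count arithmetic are renormalized over
non-reference labels (they sum to 100%).  The dose recommender inverts the
dilution algebra and rounds to a power of ten aimed at the geometric
midpoint of the validated 1:1–1000:1 test:reference window, so rounding
cannot leave it.  A delta-method standard error (binomial proportion
variance plus the stated reference-dose SD) accompanies each count; it is
model-based, not a replicate SD.  CFU and "cell count" are treated as
interchangeable units — a deliberate simplification that ignores
chain/clump biology.

## D₂O vitality metrics

Band "intensity" is the trapezoidal band *area* (C-D is broad; area is the
robust convention), with a peak-maximum mode available for sensitivity
analysis.  Negative corrected intensities are floored at zero inside band
integrals so `CDR ∈ [0, 1]`, and a C-D integral below 1e-12 of the total
band signal is treated as exactly zero — at that level the "signal" is the
C-H peak's floating-point tail, and carrying it through would let rounding
noise decide the live/dead call of unlabeled cells.  Per-cell `MAL = CDR − mean CDR(0 h control)`:
the mean-level reference is the only reading of the definition that yields
a per-cell MAL distribution, which the heterogeneity index requires.  If a
strain-specific 0 h control is missing, a global 0 h mean is used with a
warning.  `MAL-HI` is the sample variance (n−1) of per-cell MAL; population
variance and SD variants are switches.

**Boundary-bias limitation.**  Truly dead cells have expected MAL exactly 0;
any measurement noise scatters them symmetrically across the `MAL > 0`
threshold, so the estimated viability rate of a population with dead
fraction `d` is biased upward by up to `d/2`.  This is a property of the
threshold rule itself, not of the implementation; the binomial-recovery
verification therefore runs with noise off, where dead cells sit exactly at
the boundary and count dead.  Reported viability rates on noisy data should
be read with this in mind.

## Synthetic-data generator

The simulator emulates the features the pipeline must be robust to, not
Raman physics:

* **Axis**: 320–4256 cm⁻¹ at 2 cm⁻¹ spacing (1969 points) — desk-scale
  runtimes at realistic dimensionality.
* **Species**: shared biological fingerprint peaks (1003, 1095, 1250, 1450,
  1660 cm⁻¹) with species-specific amplitudes, plus ≥2 species-unique
  Gaussian peaks drawn from a disjoint partition of a reserved center grid.
  Separation levels set the unique-peak amplitude (high 0.8, medium 0.35,
  low 0.15 versus a 0.02 noise SD and a C-H amplitude of 3 — the C-H
  stretch dominates real bacterial SCRS too).
* **Cell variability**: a lognormal whole-cell gain (SD 0.20) plus
  per-peak jitter.  The shared gain makes features *correlated*, which is
  what real single-cell intensity variation does and what separates LDA
  (models shared covariance) from naive Bayes (assumes independence).
* **Baseline**: per-species quadratic polynomial plus exponential decay,
  with per-cell amplitude jitter.
* **Batch effects**: axis shift (≤5 cm⁻¹), multiplicative gain, and a
  smooth baseline perturbation — the minimal set whose removal (gain,
  baseline) or survival (axis shift) through preprocessing reproduces the
  single-batch-model failure mode.
* **D₂O labeling**: a live cell (Bernoulli `live_fraction`) moves a
  per-cell fraction `f ~ N(vitality_mean, vitality_sd)`, clipped to
  [0, 0.5], of its C-H band area into a broad C-D Gaussian at 2170 cm⁻¹
  (σ = 40, the band-window midpoint).  The transfer is mass-conserving, and
  for a noise-free cell `CDR(labeled) − CDR(0 h twin) = f` in closed form —
  the parameter-recovery oracle.  Defaults `vitality_mean = 0.06` (the CDR
  level used in instrument-precision experiments), SD 0.015,
  `live_fraction = 0.8`.
* **Determinism**: byte-identical output under a fixed seed; the per-cell
  draw order is independent of `d2o_hours`, so one seed yields an exact
  unlabeled twin of a labeled population.

The generator does **not** model instrument point-spread, cosmic rays,
cellular adhesion artifacts, real inter-strain spectral similarity, or
physically calibrated cross-sections.  Passing tests demonstrate that the
*algorithms* recover known ground truth under these variation sources; they
do not certify accuracy on any particular real product.

## Benchmark studies (`ramanqa.benchmarks`)

* *Worked product arithmetic*: strain live counts and species totals from a
  three-strain product's printed total count, proportions and viability
  rates — pure counting arithmetic, no simulation.
* *Classification*: 4 species × 1500 cells (the recommended sampling
  depth), high separation, default noise → LDA 70/30×5 accuracy.
* *Sampling depth*: the SD-versus-depth comparison runs in a
  moderately-noisy regime (`separation="low"`, noise SD 0.10, cell
  variability 0.35, fixed in `moderate_noise_conditions()`) because at high
  separation LDA saturates at 100% for every size and the comparison
  degenerates to a tie.
* *Batch effects*: the same moderately-noisy regime with the strong batch
  triple (shift ∓5 cm⁻¹, gains 0.7/1.0/1.4, baseline perturbations), 20
  seeded runs of single- versus two-batch training.
* *Mixtures*: 1:1 and 9:1 at n=1500; 999:1 at n=5000 over 20 seeds (the
  expected 5 minor cells make detection a Poisson-regime event).
* *Spike-in linearity*: a 10⁶–10¹² CFU/g half-decade grid, n=1500 cells per
  point, reference dosed by the recommender, classifier stipulated perfect
  (true labels) so the study isolates the sampling-plus-algebra error.
* *Vitality*: CDR scale invariance, transfer-fraction recovery (noise off),
  90%-live binomial recovery at n=1500 (noise off; see the boundary-bias
  note), MAL-HI of identical cells.

Study sizes are the package's chosen desk-scale defaults; all randomness
derives from the caller's seed.

## Known limitations

* Closed-world classification; no novelty detection.
* Viability boundary bias under noise (above).
* The delta-method count SE ignores classifier error correlation between
  strains.
* MAL-HI magnitudes are reported exactly as the variance of the listed
  per-cell MAL values; published heterogeneity indices of other pipelines
  may scale differently, so cross-pipeline comparison of MAL-HI magnitudes
  is not meaningful — orderings are.
* The simulator's "low separation" mode is a stand-in for near-identical
  strains, not a claim of realism for any particular strain pair.
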