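# Methods

## The measurement model

A plasma Raman scan is modelled as

I(ν) = Σ_j A_j · V(ν; ν_j, w_j) + c · B(ν) + ε(ν) + spike(ν),

where V is a pseudo-Voigt line (η = 0.5 Lorentzian/Gaussian mix, the common
compromise shape for Raman bands), ν_j are the 37 assigned band positions of the
bundled peak table (681–1672 cm⁻¹) plus a stable CH₂-bending reference band at
1445 cm⁻¹, B(ν) is a smooth fluorescence background, c a per-scan multiplicative
scatter factor, ε white detector noise, and spike an occasional single-bin
cosmic-ray event. The preprocessing chain inverts this model stage by stage:
despiking removes spike, Savitzky–Golay smoothing attenuates ε, ModPoly removes
c·B, SNV removes the remaining per-scan scale, and reference normalization puts
all patients on a common intensity scale anchored at the 1445 cm⁻¹ band (chosen
because it varies least between samples).

## Synthetic cohorts

The generator emulates the structure of a longitudinal plasma study — two cohorts
(healthy, preeclampsia) × three trimesters, default cell sizes 23/25/24 and
22/20/29 patients, 100 replicate scans per patient — with known ground truth:

- **Band amplitudes.** Between-patient variation is log-normal with CV 15%
  (keeps intensities positive); within-patient replicate variation is Gaussian
  with CV 5% of the nominal amplitude. Nominal amplitudes are class-level
  defaults (0.25–0.45 relative to the reference band, with phenylalanine
  1002 cm⁻¹ at 0.6 as the dominant sharp feature of plasma spectra). Band widths
  (FWHM) are drawn once per dataset from U(8, 20) cm⁻¹ and fixed per metabolite.
- **Cohort effects.** Preeclamptic patients at designated bands are shifted by
  d × (between-patient SD). The default effect map plants |d| = 1 at the bands
  that separate the cohorts in this disease setting (lipids 956, cholesterol
  701, carotenoids 1154, sugars 848, glycine 898, tyrosine 835 and citric acid
  940 cm⁻¹ up; histidine 1317, tryptophan 1551, phenylalanine 1031, threonine
  1340, amide III 1243 and carbohydrates 1017 cm⁻¹ down; phospholipids
  1657 cm⁻¹ flipping sign between trimesters; DNA 1420 cm⁻¹ rising late).
  The directions reflect the reported cohort trends; the magnitude is a package
  default because the underlying study quantifies none.
- **Fluorescence baseline.** A degree-5 polynomial hump, positive everywhere,
  with peak amplitude 5× the reference band, scaled per scan by U(0.8, 1.2).
  Real fluorescence is larger still but carries no extra information for testing
  the baseline stage; photobleaching over the exposure series is not modelled.
- **Noise and spikes.** Additive Gaussian noise with sd 0.02 (2% of the reference
  amplitude); cosmic rays hit 5% of scans with amplitude 20–60× the noise sd,
  single-bin by default (real events can span 1–3 bins; width is configurable).
- **Clinical covariates.** Drawn from the two cohorts' demographic
  distributions: maternal age N(31.2, 4.5)/N(32.0, 5.9), BMI N(30.8, 11.7)/
  N(28.3, 6.9), gestational age at delivery N(38.47, 1.95)/N(36.23, 2.62) weeks
  (truncated to plausible ranges by redraw), gravida/parity/pregnancy-loss
  rounded normals, chronic hypertension 11%/20%, current hypertension 11%/10%,
  history of preeclampsia 3%/22%, and severity "severe" with probability 0.57
  (else "mild") among preeclamptic patients. An optional severity link tilts
  designated band amplitudes along encoded severity to a target correlation r
  (implemented via λ = r/√(1−r²) · σ_band/σ_severity).
- **ELISA.** sFlt-1/PlGF = a + b·(lipid₉₅₆/trp₁₅₅₁) + Gaussian noise, with
  individual sFlt-1 and PlGF columns consistent with the stored ratio; defaults
  a = 5, b = 30, noise sd = 3 keep the ratio positive over the amplitude range
  (a ratio of concentrations cannot be negative; a floor at 0.05 guards the
  tail). TNF-α and GM-CSF are drawn with zero cohort effect, mirroring the
  non-discriminative behaviour of these cytokines.

Everything derives from one seed through `numpy.random.SeedSequence` spawning
(separate streams for amplitudes, clinical, ELISA, rendering), so identical
configs give bit-identical datasets, including CSV exports.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: instrument drift and wavenumber miscalibration beyond the
±4 cm⁻¹ extraction window, correlated (pink/fluorescence-shot) noise, band
overlap and Fermi resonances, photobleaching, patient covariance structure
between bands beyond the planted severity link, and longitudinal within-patient
correlation across trimesters (patients are drawn independently per cell).

## Numerical choices

- **Savitzky–Golay filter.** Authored here rather than taken from
  `scipy.signal.savgol_filter`: at the protocol's 45-point window and 10th-order
  polynomial, coefficients computed on raw sample indices lose ~10 digits to
  Vandermonde conditioning (errors ~10⁻⁴), while a Chebyshev basis on window
  positions rescaled to [−1, 1] reproduces degree-≤10 polynomials to ~10⁻¹⁵.
  Edges are handled by evaluating the polynomial fitted to the first/last full
  window.
- **ModPoly baseline.** The iteration fits a degree-9 polynomial (Chebyshev
  basis on a rescaled grid), clips the working signal to min(signal, fit), and
  stops when the relative RMS change between successive fits is < 10⁻⁴ (the
  protocol's "threshold", interpreted as a relative convergence tolerance; the
  source does not define it) or after 500 iterations (warning, not error).
  The corrected spectrum may contain small negative values by construction.
- **Despiking.** The MAD-based replicate filter iterates to a fixpoint (≤ 10
  rounds): replacing an outlier tightens the MAD and can expose a second
  outlier; the fixpoint makes the operation idempotent. With < 3 replicates a
  rolling-window median test is used, with a warning.
- **Stage order.** The chain runs despike → smooth → baseline → SNV →
  normalize. Smoothing before the baseline stabilizes the ModPoly fit; the
  baseline-first order is available via `smooth_before_baseline=False` and both
  orders are tested.
- **Reference normalization.** SNV output is negative-going, yet normalized
  spectra are conventionally reported in [0, 1]; this is resolved by shifting
  the minimum to 0 before scaling by the reference maximum (plain division is
  available via `min_shift=False`). The reference is located as the maximum
  within ±4 cm⁻¹ of 1445 cm⁻¹ to tolerate calibration jitter, ties breaking
  toward the lower wavenumber. The reference wavenumber is configurable (some
  reports place the same lipid band at 1447 cm⁻¹).
- **SNV** uses the sample (n−1) standard deviation.
- **Band intensity** is the window maximum (±4 cm⁻¹), not a fitted area:
  robust to small calibration shifts and matching the "peak value" convention;
  no deconvolution of overlapping bands is attempted.
- **t-tests** are pooled-variance, two-sided, df = n₁+n₂−2, with no
  multiple-testing correction by default (matching the screening protocol this
  package implements; Benjamini–Hochberg is available behind a flag). Zero
  pooled variance is flagged as degenerate rather than given an arbitrary p.
- **t-SNE** uses the exact algorithm with cosine distance on PCA scores and a
  fixed seed; the exaggeration parameter is applied through scikit-learn's
  early-exaggeration phase. Per-trimester defaults: perplexity 11/10/18 with
  10/6/5 PCA components; exaggeration 2 (3 is sometimes used for
  trimester-separation views).
- **SVM CV.** "Weighted SVM" is implemented as a linear-kernel SVC with
  balanced class weights (inverse class frequency), standardized features, and
  50 stratified Monte-Carlo splits (2/3 train); stratification guarantees both
  classes in every test split. The CI is the 2.5/97.5 percentile of per-repeat
  AUCs, widened to include the pooled AUC when necessary. Features are the
  significant primary bands by default (full spectra are a config switch);
  ratio-feature augmentation is deliberately not offered (overfitting risk at
  these cohort sizes).
- **ORA.** Upper-tail hypergeometric p with the bundled ~24-pathway map whose
  universe is the 18 specific compounds of the peak table; users may supply
  their own map TSV. Only set membership is used — intensity-weighted
  enrichment is out of scope. No correction on enrichment p-values by default.
- **Biomarker regression** runs on the six cohort × trimester cell means by
  default (per-patient mode behind a flag); cohort ratios are means of
  per-patient ratios, not ratios of means. Cut-off boundaries are inclusive
  exactly as printed (≤ 33, ≥ 85, ≥ 110).
- **Clinical encoding** keeps the full 0/1/2/3 severity scheme (including the
  "low" grade) even though generated cohorts only use healthy/mild/severe.
  Missing covariates correlate pairwise-complete with per-cell n recorded.

## Power utility

`power_two_sample` implements the standard noncentral-t power for an unpaired
two-sample test. At n = 45 per group, sd = 1, minimum detectable effect 0.5 and
α = 0.05 it returns 0.650 two-sided (0.76 one-sided) — a conventional
superiority design reaching 80% at these settings would need different inputs;
the utility reports the standard formulas and leaves design-specific variants
to the caller.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at sizes chosen to give stable statistics at desk
scale: null calibration uses 200 seeds of patient-level band amplitudes (the
same distributions the spectra are rendered from) at n = 20/20, giving ~7,400
null t-tests; planted-effect recovery uses 40 seeds at the first-trimester cell
sizes (23/22); rendered-spectrum checks (spiking linearity, end-to-end effect
detection, pipeline determinism) use one or a few full cohorts with 3–8
replicates per patient rather than 100, since replicate averaging only tightens
the patient mean. The acceptance script's headline cohort uses the full study
cell sizes (143 patients) with 8 replicates per patient.

## Known limitations

- Band assignments are tentative by nature; a window-maximum intensity at an
  assigned position conflates overlapping contributors (e.g., citric/succinic
  acid at 940 cm⁻¹).
- The bundled pathway map is a small fixture sufficient for testing the ORA
  machinery; real analyses should supply a current KEGG-derived map.
- AUCs obtained on synthetic cohorts reflect the planted effect sizes, not any
  clinical performance; with the default |d| = 1 map they land near 0.95,
  higher than typically reported for first-trimester screening.
- The exaggeration factor applies only during t-SNE's early phase; an optimizer
  applying it throughout would shrink clusters slightly differently.
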