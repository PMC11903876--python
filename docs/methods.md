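# Methods

## The measurement and its statistical model

Each urine sample is read out six times: three illumination geometries
(direct transmission DT, angular transmission AT, angular reflection
AR) × two integration times ("low"/"high" exposure; the physical device
settings such as 20/200/320 ms are metadata only).  A read-out is a
vector of 288 intensity counts on a wavelength grid spanning 340–850 nm,
clipped at the 65,000-count detector ceiling.  One sample therefore
yields a 3 × 2 × 288 = 1,728-value feature cube.  Patients contribute
repeated samples (1–11, mean ≈ 3), so observations are clustered.

The analysis chain is: saturation filtering → SNV normalization →
per-wavelength correlation screening → dichotomization of lab values →
logistic classification (with and without a patient random intercept) →
AIC best-subset selection → 5-fold cross-validated optimism correction
of AUC and balanced accuracy.

## Saturation filtering

A detector count at or equal to the ceiling is treated as clipped.  If
any high-exposure spectrum of a sample contains such a channel, the
sample's high-exposure spectra are removed on all three light paths;
low-exposure spectra are never removed and retained intensities are
never altered.  Whether removal should instead apply dataset-wide is
ambiguous in practice; per-sample removal is the default and a
`dataset_wide` switch exists.  Samples missing a setting after
filtering are dropped from that setting's matrix only (complete-case
per model).

## SNV normalization

s̃ᵢ = (sᵢ − μ(s⃗)) / σ(s⃗) per spectrum, with the sample (n−1) standard
deviation — the chemometrics convention; the choice of n vs n−1 is
irrelevant downstream because models are refitted on the scaled values,
but it is fixed for exactness of tests.  SNV removes exactly the
artifact family the generator injects (per-spectrum multiplicative
scatter and additive offset), so on synthetic cohorts the per-wavelength
standard deviation across spectra drops by several orders of magnitude;
the test suite asserts at least one order, a deliberately weak bound
that does not depend on the artifact scales chosen here.

## Correlation screening

For each spectrometer setting, the n × 288 matrix of SNV intensities is
correlated column-wise with the laboratory vector: Pearson's r with a
two-sided t-test p-value for quantitative assays, Kendall's τ-b (tie
corrected, normal-approximation p-value) for ordinal dipstick scales.
No multiplicity correction is applied across the 288 × 6 tests by
default (a Benjamini–Hochberg helper exists but is off), matching the
practice the pipeline reproduces.

Wavelength candidates are the local extrema of |coefficient| (a channel
at least as large as both neighbours; tie runs keep their lowest
wavelength) with p below the significance level (default 0.05), ranked
by |coefficient| and truncated to a per-marker maximum.  Two
refinements:

* **Plateau exclusion.** SNV couples every channel to every other
  through μ(s⃗) and σ(s⃗); channels in spectral regions with little
  independent signal become smooth functions of total absorbed light
  and show high but nonspecific correlations that form flat plateaus
  (typically above ~500 nm).  A channel is masked when the rolling
  range of the coefficient over a centred window (default 15 channels)
  stays below a flatness tolerance (default 0.05) for a run at least
  one window long.  The rule formalises a visual exclusion; window and
  tolerance are configurable.
* **Literature priors.** Known absorption maxima can be supplied per
  marker; the nearest grid channel is appended when significant and not
  already selected.

A marker with no surviving candidate terminates at screening and is so
flagged in the pipeline summary.

## Labels

Quantitative markers are dichotomized at clinical cut-offs with an
explicit per-marker direction: elevated bilirubin, erythrocytes,
ketones, leukocytes, nitrite, protein and urobilinogen are
pathological; pH and specific gravity are pathological outside their
literature reference ranges ([5, 7.5] and [1.002, 1.04]).  Boundary
values count as healthy.  A literal "pathological iff value ≤ cut-off"
rule is available as a per-marker override (`caption_rule`) because
tabulated summaries sometimes state the rule that way even though it
contradicts clinical convention for markers that are pathological when
elevated.  Ordinal dipstick values map to labels through a declared
pathological-level set.  pH is additionally bifurcated into an acidic
(pH < 7) and a basic (pH > 7) outcome, with pH 7 neutral — label 0 — in
both (exclusion of neutral samples is available via configuration).

## Models

**LR** is a logit-link Bernoulli GLM fitted by iteratively reweighted
least squares (statsmodels underneath the module surface).  Perfect or
quasi-separation is detected (diverging coefficients, non-finite
likelihood, or statsmodels' separation warning), flagged on the
results object, and such fits are excluded from subset selection rather
than penalised.

**LRRE** adds a patient random intercept bᵢ ~ N(0, σ_b²) with the
marginal likelihood

L(β, σ_b) = ∏ᵢ ∫ ∏ⱼ Bernoulli(yᵢⱼ | logit⁻¹(xᵢⱼ'β + b)) φ(b; 0, σ_b²) db

evaluated by adaptive Gauss–Hermite quadrature: per patient, a damped
Newton iteration finds the posterior mode and curvature of the
integrand, and the Hermite nodes (default 15; 1 node = Laplace
approximation) are recentred and rescaled there.  The quadrature
reproduces dense numerical integration to well below 1e−6 on test
fixtures and the full fit matches `lme4::glmer(nAGQ = 15)` to ~1e−3 on
a simulated fixture (asserted in the suite via Rscript).  Optimisation
is L-BFGS-B over (β, σ_b) with σ_b bounded at zero; σ_b below 1e−6 falls
back to the exact plain-logit likelihood, so the σ_b = 0 boundary
reproduces LR exactly.  A boundary flag reports σ̂_b ≈ 0.  Standard
errors come from the numerically differentiated Hessian of the marginal
log-likelihood.  With single-sample-per-patient data the variance
component is only weakly identified (a near-flat ridge trades σ_b
against attenuated β); estimates there should be read with the boundary
and convergence flags in hand.

**AIC** is −2·loglik + 2·k with k counting the intercept, the slopes
and (for LRRE) the variance component as one parameter; the identity is
asserted on every returned model.

**Best subset**: every non-empty subset of the candidate wavelengths up
to `max_size` is fitted (the intercept-only baseline included as a
comparator, excludable for studies that require feature-bearing
models), capped at 12 candidates (4,096 fits).  The minimum-AIC
converged model wins; ties break toward fewer features, then
lexicographic names, making the result invariant to candidate order.

**Prediction**: marginal predictions use logit⁻¹(x'β̂); conditional
predictions (LRRE) add the patient's posterior-mode intercept (BLUP),
with 0 — i.e. the marginal prediction — for patients unseen at fit
time.  Inner-sample evaluation uses conditional predictions and
held-out evaluation marginal ones by default; both are switchable, as
no single convention is universal.

## Validation

AUC uses the Mann–Whitney formulation (ties count ½; asserted against
an exhaustive threshold-sweep trapezoid oracle).  BAC classifies at
probability > 0.5 (the threshold is configurable; no other value is
canonical) and equals (sensitivity + specificity)/2 by construction.

Folds are drawn uniformly at the sample level with sizes differing by
at most one (401 samples → 81/80/80/80/80), so one patient may span
training and test — deliberately, to match the validated procedure; a
patient-grouped-fold switch exists.  Within each fold the *entire*
modelling procedure (best-subset selection + fit) is repeated on the
training 4/5; the mean of the five (inner − held-out) differences is
the correction term, subtracted from the full-data model's inner
metric and clipped to [0, 1].  Folds whose training or test part is
single-class are redrawn from a derived seed (logged); persistent
failure raises.  The same fold partition is shared between LR and LRRE
for a marker by default.

## The synthetic generator

The generator is the package's study bench; its defaults define the
conditions under which the validation studies run.

* **Cohort structure**: 168 patients by default; samples per patient
  from a truncated geometric on 1–11 with mean ≈ 3, matching a ward
  cohort where stay length drives sample counts.
* **Classes and clustering**: per marker, each patient receives an
  independent latent effect b ~ N(0, 1.0²) on the class log-odds; the
  intercept is calibrated by 1-D root finding so the marginal
  pathological probability equals 1 − healthy_fraction exactly under
  the random effect.  Effects are independent across markers so that a
  marker without absorption features is genuinely uninformable from
  spectra — with a shared effect, every marker would correlate with
  every other marker's bands through the patient, which would make
  null-calibration studies impossible.
* **Concentrations**: gamma distributions for the healthy and
  pathological classes with overlapping supports (real assay
  distributions overlap; disjoint supports would make class a
  deterministic function of concentration and induce perfect separation
  in any informative logit fit).
* **Physics**: I(λ) = clip(scatter · gain · I₀(λ) · 10^(−L·Σ εₘ(λ)cₘ) +
  offset + noise, 0, 65,000).  The baseline I₀ mixes a UV, a broad
  full-spectrum and an NIR emitter; per-path scales (DT > AT > AR) and
  effective path lengths L (1.0/0.6/0.35) differentiate the three
  geometries.  Extinction bands are Gaussian in wavelength.  Default
  band parameters keep typical pathological absorbances at or below
  ~0.1: in that linear Beer–Lambert regime the per-wavelength
  correlation extremum coincides with the band center, whereas strong
  absorbances (≳0.5) saturate the transmission nonlinearly and push the
  Pearson extremum to the band shoulders — a real chemometric effect,
  but one that would defeat localization studies by construction.
  Band centers follow literature absorption maxima (bilirubin ≈ 426 nm,
  haemoglobin Soret ≈ 414 nm, urobilinogen ≈ 490 nm); glucose has no
  band in this range.
* **Artifacts**: per-spectrum lognormal scatter (sd 0.15 on the log
  scale) and additive offset (sd 300 counts) — exactly the family SNV
  removes — plus per-channel Gaussian noise (sd 60 counts).  Exposure
  gains (1.0, 4.5) put the high exposure near the ceiling so that a
  realistic minority of samples saturates and exercises the filter.
* **Read-outs**: quantitative markers report the concentration; ordinal
  markers threshold it at fixed levels (neg/1+/2+/3+), the first
  threshold at the clinical cut-off so dipstick level and class agree.
* **Wavelength calibration** is linear over 340–850 nm by default and
  injectable; device-specific printed wavelengths (e.g. 426.49 nm) are
  instrument calibration artefacts and not reproduction targets.

What the generator does **not** emulate: turbidity microphysics,
wavelength-dependent stray light, drift between batches, correlated
channel noise, non-Gaussian band shapes, and any correlation between
markers beyond chance.  Passing the recovery studies therefore shows
that the statistical machinery is correct under its own assumptions,
not that the assay performs at any particular level on real urine.

## Validation studies (`urispec.studies`) and their sizes

Study sizes were chosen to finish in minutes on one CPU while leaving
usable statistical resolution.

* **σ_b recovery**: 200 patients × 4 samples, true σ_b = 1.0,
  intercept-only LRRE on the latent class of a balanced marker
  (healthy_fraction 0.5) — the generating model itself, and the most
  informative outcome per sample for a variance component.  Estimates
  fall within [0.7, 1.3] across seeds.
* **Screening localization**: single-band quantitative marker,
  130 patients; the top candidate lies within ±10 nm of the 426-nm
  band center in ≥ 90% of seeds.
* **Subset selection**: one informative SNV channel plus three
  independent noise columns at n ≈ 1,000.  The informative feature is
  retained in ≥ 90% of seeds.  The noise features are *not* excluded at
  a 90% rate and cannot be: AIC admits an irrelevant predictor whenever
  its deviance improvement exceeds 2, an event of asymptotic
  probability P(χ²₁ > 2) ≈ 0.157 per feature regardless of sample
  size, so three noise candidates are all excluded only ≈ 60–70% of
  the time.  This is the known selection-inconsistency of AIC, reported
  as measured.
* **Null calibration**: six arbitrary SNV channels of an
  absorption-free marker (150 patients × 3), selection restricted to
  feature-bearing models so training performance shows overfitting;
  the corrected AUC averages within 0.05 of 0.5 while the inner AUC
  exceeds 0.5.
* **Holdout closeness**: clustered single-band cohorts (100 patients
  × 3, σ_b = 1.0) with LRRE and conditional inner predictions — the
  regime where BLUP memorisation makes inner metrics most optimistic —
  compared against a fresh 10,000-sample holdout; the corrected AUC is
  closer than the inner AUC to the holdout AUC in ≥ 80% of seeds.

## Numerical choices and degenerate inputs

Constant spectra (σ = 0) raise a degenerate-spectrum error naming the
sample; constant lab vectors and single-class outcomes raise analogous
errors rather than returning NaNs.  Kendall p-values use the large-n
normal approximation (cohorts here have n in the hundreds); exact pair
counting is used as the oracle for n ≤ 10.  Quadrature node count is
configurable; log-likelihoods change by < 1e−6 between 15 and 25 nodes
on test fixtures.  The posterior-mode Newton iteration clips steps at
±5 to survive flat starts.  Random-number use is confined to explicit
seeds: cohorts from `CohortConfig.seed`, folds from the evaluation
seed, and the pipeline expands one root seed into independent per-stage
seeds via `numpy.random.SeedSequence`.

## Known limitations

The per-marker independence of patient effects is a modelling
convenience; real comorbidity correlates markers within patients.  The
plateau rule and the local-extremum candidate definition are
reproducible formalisations of what is, in practice, a manual reading
of correlation curves.  Corrected metrics remain estimates: the CV
correction is itself noisy (five fold differences), and for weakly
overfitted models it can overshoot the true optimism.  LRRE standard
errors rely on a finite-difference Hessian and degrade near the σ_b = 0
boundary.
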