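# Methods

## Assay geometry and grid

A biodynamic assay cycles a camera across all 36 wells of a plate once per
**loop** (82 min), recording per-well intensity fluctuation spectra between
10 mHz and the camera Nyquist frequency of 12.5 Hz (25 frames/s).  The
default grid is 50 log-spaced frequencies × 13 loops: 4 baseline loops
(≈ 5.5 h) followed by 9 post-dose loops (≈ 12.3 h).  Doppler frequency maps
to intracellular speed through Δω = qv with q = 4πn/λ₀ (λ₀ = 840 nm,
n = 1.33), so the analysis bands correspond to speed regimes: 10–100 mHz
(shape change / rheology), 0.1–1 Hz (membrane and nuclear motion), 1–10 Hz
(organelle transport, ≈ 0.3–3 µm/s).

## Synthetic cohort model

No deposited per-well spectra exist, so the generator is a tested,
first-class stage that emulates the statistical structure the analysis
assumes.

**Baseline spectrum.** S(ω) = A / (1 + (ω/ω_k)^s) + NY — a low-frequency
plateau A (default 100, arbitrary spectral-density units), knee frequency
ω_k (0.3 Hz), roll-off exponent s (1.6) and Nyquist noise floor NY (1).
This is the minimal family that realizes every precondition the feature set
measures (plateau, knee, half-width, slope, floor, dynamic range).

**Drug response.** Two multiplicative factors ramp linearly from 1 at the
dose to endpoint values at the final loop: a knee factor κ and an amplitude
factor α applied to the dynamic (above-floor) part of the spectrum.
Defaults:

| phenotype × treatment | κ_end | α_end | effect |
|---|---|---|---|
| resistant × carboplatin or paclitaxel | 0.5 | 2.0 | red shift |
| sensitive × carboplatin or paclitaxel | 1.1 | 0.91 | mild blue shift |
| any × combination | 1.0 | 0.5 | broadband inhibition |
| any × vehicle control | 1.0 | 1.0 | null |

The red shift pairs κ < 1 with α ≈ 1/κ because a pure knee decrease only
depletes high frequencies; slowing with (approximately) conserved spectral
power moves density into the low bands, which is what the resistant
phenotype shows (positive 10–100 mHz response, negative 1–10 Hz).
Metastatic specimens always draw resistant-type response parameters,
whatever their clinical label (sensitive by default).

**Heterogeneity and noise.** Per (patient, treatment), κ_end and α_end are
jittered log-normally with sd 0.25 (natural log) — biological
patient-to-patient variability that replicate averaging cannot remove.
Per-bin measurement noise is multiplicative log-normal with σ_log = 0.05
(log10 units), i.e. additive Gaussian on the log spectrogram.  These
effect/noise scales were calibrated once, during development, so the
default 20-patient cohort is classifiable at high (≥ 90%) cross-validated
accuracy without being a toy problem: top component z-factors land at a few
units, weaker selected components below 1.

**Quality-control violations.** Four independent criteria are injected with
probability 0.59 each: an immobilization shift (a ×2 step in the brightness
trajectory, later *detected* rather than read from a flag) and three
pre-assigned flags.  With the halving rule DQ = 2⁻ᵐ this yields a typical
data quality of (1 − p/2)⁴ ≈ 0.25.

**What the generator does not emulate.** Raw holograms/speckle, spatial
heterogeneity within a well, frequency-correlated noise, drift, plate-edge
effects, or immobilization-chemistry differences.  Passing tests therefore
demonstrate that the pipeline recovers the structure this model encodes —
not performance on real biopsies.

## Spectrograms and data quality

The baseline S(ω,0) is the per-frequency geometric mean of the last 4
pre-dose loops (averaging in log space is the average consistent with the
log-ratio definition of D).  D(ω,t) = log₁₀ S(ω,t) − log₁₀ S(ω,0) over the
post-dose loops; all logarithms are base 10.  DQ starts at 1 and is halved
per violated criterion: a consecutive-loop brightness ratio outside
[1/1.5, 1.5], baseline band power (0.01–1 Hz, above the floor) below 5% of
the cohort median, and any pre-assigned flags.  Replicates are combined by
DQ-weighted element-wise mean (the averaged spectrogram stores the mean DQ,
which no longer has the 2⁻ᵐ form).  The DMSO control spectrogram is
subtracted from each drug arm before feature extraction by default
(configurable), since the published average spectrograms are
vehicle-subtracted.

`power_spectrum` (for raw intensity traces) computes a one-sided boxcar
periodogram at the camera frame rate and resamples onto the log grid by
averaging within geometric bins — preserving band-integrated power —
with log-log interpolation into bins narrower than the frequency
resolution.

## Biomarkers

**Global masks.** Tensor products of degree 0–2 polynomials on the
post-dose loop index and on log₁₀(frequency), both affinely mapped to
[−1, 1].  The axis polynomials are built by QR orthonormalization of the
monomial basis on the *sampled* points (discrete Legendre polynomials), so
the 9 masks are exactly orthonormal under the grid inner product —
continuum Legendre polynomials sampled on a finite grid are not, and exact
orthonormality makes the features independent contrasts.  Unit Frobenius
norm keeps features comparable across grids.

**Local masks.** Indicators of the rheology (10–100 mHz), mid (0.1–1 Hz)
and high (1–10 Hz) bands × the same degree 0–2 time polynomials; bands are
half-open so supports are disjoint.  The sub-10 mHz cell-motility band and
the Nyquist bin are excluded (outside the display range and
detection-noise-dominated respectively).

**Preconditions.** From each baseline (and endpoint) spectrum: NY = density
of the top bin; A, KNEE, S by least squares on log₁₀ densities with the
additive floor refined as a nuisance parameter initialized at NY (the
knee's power-law tail still contributes at Nyquist, so fixing the floor at
the top-bin reading would bias KNEE and S by several percent); HW = the
measured half-power frequency; DR = log₁₀((A + floor)/floor); SF = the
log-log slope over the top half-decade.  NSD (speckle contrast), BSB
(brightness) and NCNT (sample size) are acquisition metadata passed through
from the generator — their image-level definitions are not recoverable from
spectra.  A fit whose knee pins to a grid edge or fails to converge is
flagged and its KNEE/S/HW set to NaN.

**Deltas.** Positive scale parameters (BSB, NY, KNEE, HW) change as log₁₀
ratios endpoint/baseline; the rest as arithmetic differences.  Whether the
original assay used ratios or differences is not documented; log-ratios are
the scale-free choice for positive quantities.  A delta involving a failed
fit is imputed to 0 (no change) and recorded in a flag that is *not* part
of the feature vector, keeping its length fixed at 81.  The unstable
deltas (NCNT, KNEE, S) are retained by default; a
`drop_unstable_preconditions` switch removes them (24-feature blocks).
Precondition deltas are computed at the patient × treatment level from
DQ-weighted geometric-mean baseline and endpoint spectra.

## Selection and similarity

The 18 spectrogram features per treatment are z-scored over training
patients (z-scoring rather than covariance-PCA, since the features carry
heterogeneous scales), decomposed by SVD, and components ranked by the
absolute z-factor z = (μ_R − μ_S)/√(σ²_R + σ²_S) (root-sum class variances:
symmetric in the classes and √2 × the two-sample effect size).  The top 5
across treatments are the working feature vectors.  Standardization and
loadings are frozen from training patients; metastatic and test patients
are transformed with the frozen statistics and never enter selection.
Loading signs follow a largest-element-positive convention.  Precondition
deltas bypass the SVD and, by default, the classifiers (which see only the
5 selected components).

Similarity is the correlation contrast S_AB = (2√β/(1+β)) cos(A,B); the
prefactor is invariant under β → 1/β and ≤ 1 with equality at matched
amplitudes.  The display order of the similarity matrix is resistant →
metastatic → sensitive with average-linkage clustering on 1 − S within each
group (the clustering method is not documented in the protocol;
average linkage is the standard choice for similarity heatmaps).  The
k-neighbor network (k = 3) keeps both the directed top-k adjacency (used by
the network classifier) and its symmetrized union (for display); top-k ties
break by patient id for determinism.

## Classifiers

All four map a held-out feature vector to P ∈ [−1, 1]; negative P =
resistant.

1. **Logistic perceptron.** Minimizes Σ_p [σ̃(b + f_p·w) − y_p]² + λ‖w‖²,
   λ = 0.1, with σ̃(x) = 2/(1+e⁻ˣ) − 1 = tanh(x/2).  The rescaling to
   (−1, 1) makes the ±1 targets attainable and a zero decision threshold
   meaningful.  Optimization: deterministic gradient descent with Armijo
   backtracking from zero initialization, 20 000-iteration budget,
   convergence at gradient norm < 1e−8 (warning if the final gradient is
   far from that).  Verified against an independent quasi-Newton optimizer
   on the identical cost.
2. **Gibbs-relaxation recurrent network.** Features are centered at the
   training mean (inner products are otherwise dominated by the common
   offset).  Each iteration draws a training vector with probability
   ∝ max(f_p·f, 0) — negative inner products clamp to zero, since they are
   selection probabilities — and copies one uniformly chosen feature value
   into the working vector.  Because the chain does not converge pointwise,
   the relaxed vector f′ is the running mean, declared converged when it
   moves < 1e−4 (max-norm) over a 50-iteration window (500 max).
   P = Σ y_p ŵ_p / Σ ŵ_p with the same clamped weights, hence P ∈ [−1, 1].
3. **Log-likelihood.** Independent per-feature Gaussians per class (mean
   and n−1 variance of the training members, variance floored at 1e−6 of
   the pooled variance); the score Σ_a [L_{+1} − L_{−1}] is squashed
   through σ̃ so its range matches the other ensemble members.
4. **Network vote.** Mean label of the k = 3 training patients most similar
   by correlation contrast.

The ensemble mean is over the four P values; its SE is the
across-classifier sample sd / √4, with the root-variance of 8 stratified
80%-of-training resamples added in quadrature (the resampling term
represents training-set uncertainty).  A classifier that raises is dropped
(SE divisor shrinks) and recorded.

## Evaluation

Training patients are predicted by leave-one-out cross-validation with
selection and standardization refit inside every fold; folds that leave a
class with fewer than two members are skipped with a warning.  Metastatic
(and any test) specimens are predicted by the full-training model.  For
scoring, the R-class is *resistant or metastatic*, the S-class sensitive
non-metastatic.

Each class's prediction distribution is an equal-weight Gaussian mixture
over the patients' (mean, SE) pairs, with SE floored at σ = 0.02 to avoid
delta functions.  The ROC sweeps a dense threshold grid through the two
mixtures (sensitivity = R-mass below threshold, specificity = S-mass
above); AUC by trapezoidal integration, cross-checked against a 10⁶-draw
Monte-Carlo oracle.  Two decision points are reported: the pre-fixed zero
threshold and the Youden-optimal threshold (max sens + spec).  Accuracy,
PPV and NPV use cohort prevalence; PLR = sens/(1−spec) (infinity sentinel
at spec = 1), NLR = (1−sens)/spec.  Mean class separation is the difference
of class means with a 1.96·SE CI whose class SEs combine between-patient
variance and per-patient SEs.

## Problem sizes and determinism

Default study: 24 patients × 71 wells × 13 loops × 50 frequencies
(~1.1 M spectral samples), chosen to mirror the clinical assay layout while
keeping a full simulate→evaluate run around a minute on one core.  All
randomness flows from one master seed through named substreams
(simulate / classify / evaluate); reruns are byte-identical.  Tests use a
reduced 7-patient cohort with 3–4 wells per arm except for the end-to-end
calibration check, which runs the full default cohort.

## Known limitations

- The generator's response model is two-factor and linear-in-time; real
  drug responses show richer kinetics (delays, non-monotonicity) that the
  degree-2 time polynomials could capture but the generator never produces.
- NSD/BSB/NCNT are pass-through metadata here, so their delta features are
  nearly uninformative in synthetic cohorts.
- The Gibbs classifier's update rule is one reading of a loosely specified
  procedure (feature values copied from the drawn training vector);
  alternatives (permuting within the working vector) would differ in
  detail.
- Reported performance on synthetic cohorts reflects the generator's
  calibrated effect sizes and must not be read as expected clinical
  performance.
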