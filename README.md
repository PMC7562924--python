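# biodyn — Doppler fluctuation chemosensitivity profiling

`biodyn` is an analysis pipeline for phenotypic chemosensitivity profiling of
living tumor biopsies by biodynamic (Doppler fluctuation) spectroscopy.
Near-infrared light backscattered from living tissue picks up Doppler shifts
from intracellular motion (Δω = qv, q = 4πn/λ₀; at λ₀ = 840 nm a speed of
1 µm/s maps to ≈ 3 Hz).  Chemotherapy changes those motions, and the change
is read out as a **drug-response spectrogram**

    D(ω, t) = log₁₀ S(ω, t) − log₁₀ S(ω, 0)

— the log-ratio of the post-dose fluctuation power spectrum to the pre-dose
baseline (geometric mean of the last 4 baseline loops), on a time–frequency
grid of 82-min plate loops × log-spaced Doppler frequencies (10 mHz–12.5 Hz).
Platinum-resistant tissue responds to carboplatin/paclitaxel monotherapy with
a spectral *red shift* (density moves toward low frequencies — slowed
intracellular motion), sensitive tissue does not, and the drug combination
inhibits both broadband.

The pipeline turns per-well spectra into a per-patient resistant/sensitive
call:

1. **Spectrograms** — per-well D(ω,t) with a data-quality weight
   DQ = 2⁻ᵐ (halved per quality-control violation), replicate-averaged and
   vehicle-control (DMSO) subtracted.
2. **Biomarkers** — 18 spectrogram features per drug (inner products with
   9 global Legendre-polynomial masks and 9 local band × time-polynomial
   masks) plus 9 drug-induced changes of spectral preconditions
   (NSD, BSB, NCNT, DR, NY, KNEE, HW, S, SF): 27 × 3 drugs = 81 features.
3. **Selection** — per-drug SVD of the z-scored spectrogram features;
   components ranked by z-factor z = (μ_R − μ_S)/√(σ²_R + σ²_S); top 5 kept.
4. **Similarity network** — correlation contrast
   S_AB = (2√β/(1+β)) · (A·B)/(|A||B|), β = |A|/|B|, and a k = 3 neighbor
   graph.
5. **Ensemble classifier** — logistic perceptron (ridge λ = 0.1), a
   Gibbs-relaxation recurrent network, per-feature Gaussian log-likelihood,
   and the k-neighbor network vote, averaged into a predicted
   chemosensitivity P ∈ [−1, 1] (negative = resistant) with a standard error.
6. **Evaluation** — leave-one-out cross-validation (selection refit per
   fold), Gaussian-mixture class PDFs, ROC/AUC, and clinical decision
   metrics (sensitivity, specificity, PLR, NLR, PPV, NPV, accuracy, mean
   class separation).

Because no public per-well spectra exist, the package ships a first-class
synthetic cohort generator (`biodyn.synthetic`) that emulates the assay:
plateau–knee–power-law Doppler spectra with a Nyquist noise floor,
phenotype-dependent post-dose response ramps, metastatic specimens that
carry the resistant response signature regardless of clinical label,
17/18/18/18 replicate wells, log-normal measurement noise and injected
quality-control violations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (10 resistant + 10 sensitive training patients,
4 metastatic):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_spectrograms.py
python analysis/03_extract_features.py
python analysis/04_select_biomarkers.py
python analysis/05_similarity_network.py
python analysis/06_classify_evaluate.py --seed 1
```

Step 02 prints the phenotype-averaged band means of D — the resistant
red shift under monotherapy (positive 10–100 mHz, negative 1–10 Hz) and the
broadband inhibition under the combination:

```
 phenotype    treatment  10-100 mHz   1-10 Hz
 resistant  carboplatin       0.194    -0.005
 resistant  combination      -0.150    -0.099
 resistant   paclitaxel       0.151    -0.044
 sensitive  carboplatin      -0.012     0.015
 sensitive  combination      -0.134    -0.057
 sensitive   paclitaxel      -0.012     0.049
```

Step 04 reports the selected orthogonal biomarkers with their z-factors
(e.g. `BM1carb  z = -4.37`, `BM1tax  z = +2.06`), step 05 the block
structure of the similarity matrix (mean within-class similarity +0.53 vs
−0.57 between classes) and the metastatic specimens attaching exclusively
to resistant/metastatic neighbors, and step 06 the outcome:

```
LOOCV discrete accuracy (threshold 0): 1.000
mixture AUC: 0.997
mean class separation: 1.78 (95% CI 1.50-2.05)
   fixed threshold +0.000: sens 0.99 spec 0.96 acc 0.98 PLR 24.7 NLR 0.01 ...
metastatic specimens assigned R-class: 4/4
```

i.e. every cross-validated training patient is called correctly at the
pre-fixed zero threshold and all four metastatic specimens — clinically
labeled sensitive — receive the resistant biodynamic signature.

The same pipeline is available as a CLI (`biodyn simulate | spectrogram |
features | classify | evaluate | run-all`); `biodyn run-all --seed 1 --out
results/` chains every stage from one master seed with byte-identical
reruns.

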