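# pulmopet

Pre-radiotherapy FDG-PET lung-uptake biomarkers and radiation-pneumonitis
risk statistics.

## The problem

Radiation pneumonitis (RP) — an inflammatory lung reaction to thoracic
radiotherapy, graded 0–5 on the CTCAE scale with "symptomatic" meaning
grade ≥ 2 — is a major dose-limiting toxicity in lung-cancer treatment.
Pre-existing subclinical pulmonary inflammation shows up on a staging FDG
PET scan as diffusely elevated tracer uptake, and the upper percentiles of
the lung SUV distribution (in particular the 95th percentile, **SUV95**)
have been proposed as pre-treatment biomarkers of RP risk.

`pulmopet` is a tested, reusable implementation of that analysis chain for
imaging scientists and radiation-oncology researchers:

1. **SUV conversion** — voxelwise
   `SUV = activity [Bq/mL] × body weight [g] / decay-corrected injected dose [Bq]`,
   with the injected dose decayed to scan start via the ¹⁸F half-life
   (109.771 min).
2. **Lung segmentation** — automatic HU-histogram thresholding (Otsu on
   values clipped to [−1000, 200]), exterior-air removal, retention of the
   two largest 26-connected components, morphological closing; central-airway
   removal by 6-connected region growing below −950 HU; subtraction of
   manually contoured exclusion ROIs (PET spill-over, diaphragm cold spots,
   tumor).
3. **Biomarker panel** — mean, SD, max and the 80th/90th/95th percentiles of
   SUV (and HU) over the lung ROI, percentiles by linear interpolation of the
   empirical CDF.
4. **Dosimetry** — mean lung dose and V5/V10/V20/V30 (percent of lung
   receiving strictly more than the threshold), with proton dose converted to
   ⁶⁰Co Gray Equivalents at RBE 1.1.
5. **Outcome statistics** — chi-squared / Mann-Whitney association tests,
   univariate logistic panels with Holm adjustment, backward-AIC multiple
   logistic regression with Nagelkerke R², ROC with DeLong 95% CI and the
   Youden operating point, depth-2 Gini recursive partitioning, Kaplan-Meier
   curves across SUV95 terciles, Cox proportional-hazards regression (Efron
   ties), and Bland-Altman limits of agreement for repeat reads.

No patient data ship with the package. A first-class synthetic-data module
generates thoracic phantoms with known lung-SUV distributions (including
cardiac/tumor spill-over and diaphragm cold-spot artifacts) and simulates
cohorts whose outcomes follow known logistic and proportional-hazards
models, so every stage is verifiable against ground truth.

## Worked example

The one-command demo generates a 128³ phantom, extracts its biomarkers, and
runs the full statistics battery on a simulated 100-patient cohort:

```bash
pulmopet demo --out demo_out --seed 1
```

prints

```
phantom SUV95: measured 1.215, truth 1.200
cohort: 53/100 symptomatic; AUC = 0.84; selected terms = ['suv_95', 'age', 'v30']
inter-reader limits of agreement: +/-6.51%
outputs written to demo_out
```

Reading the output: the lung ROI recovered from the phantom CT reproduces
the designed 95th-percentile SUV to within 0.015 once the artifact exclusion
masks are applied; on the simulated cohort the backward-AIC model selection
recovers exactly the three covariates that generated the outcome (SUV95, age,
V30); the ROC AUC of the selected model and the ±6.5% inter-reader limits of
agreement are in the range expected for a 100-patient / 10-subject design.
`demo_out/` contains the univariate and multiple-regression tables (CSV),
the ROC, Kaplan-Meier, partition and Bland-Altman figures (PNG), and a
manifest with the config hash and seed.

The same steps are available individually as `pulmopet phantom`,
`pulmopet simulate-cohort`, `pulmopet extract` and `pulmopet analyze`, or as
library calls (`generate_phantom`, `extract_case`, `run_study`, ...).

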