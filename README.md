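# copdct

Quantitative chest-CT biomarkers and internally validated diagnostic models
for COPD in lung-cancer screening.

Low-dose screening CT contains more than lung nodules: the same paired
inspiratory/expiratory acquisition quantifies three imaging biomarkers of
chronic obstructive pulmonary disease, which can stand in for spirometry
when lung-function testing is not part of the screening visit.  `copdct`
implements the full analysis chain for researchers working on quantitative
CT densitometry, airway morphometry and diagnostic-model validation:

* **Emphysema index (IN₋₉₅₀)** — the percentage of inspiratory lung voxels
  with attenuation strictly below −950 HU.
* **Air trapping (E/I-ratio\_MLD)** — the ratio of expiratory to inspiratory
  mean lung density; values near 1 indicate trapped gas on expiration.
* **Bronchial wall thickness (Pi10)** — airway lumens are segmented by
  adaptive region growing, converted to a centerline model, and measured in
  cross-sections perpendicular to the local airway axis at 1-mm spacing with
  72 radial rays per section.  Across all valid sections, √(wall area) is
  regressed on lumen perimeter Pi, and

  Pi10 = intercept + 10 mm × slope

  is the √wall-area of a hypothetical airway with a 10-mm lumen perimeter.

* **Diagnostic ladder** — eight nested logistic models for spirometric COPD
  (FEV₁/FVC < 0.70): demographics alone (age, BMI, pack-years, smoking
  status), each biomarker added alone, every pair, and the full model.  Each
  model is internally validated by Harrell's optimism bootstrap (corrected
  C-statistic, calibration-slope shrinkage of the coefficients), classified
  at the cutoff maximizing TP+TN, and compared by the Net Reclassification
  Index (NRI).

A synthetic-data module generates CT phantoms (airway tubes, emphysema
clusters) with exact closed-form ground truth and subject cohorts with a
known generating model, so every stage is testable without clinical data.

## Worked example

Measuring Pi10 on a noiseless phantom with three airway tubes of known
geometry (`python examples/03_airway_pi10.py`):

```
sections measured: 48, valid: 48
  tube r=1.5 mm: true Pi = 9.42 mm, true sqrt(WA) = 3.090 mm
  tube r=2.5 mm: true Pi = 15.71 mm, true sqrt(WA) = 4.342 mm
  tube r=4.0 mm: true Pi = 25.13 mm, true sqrt(WA) = 5.889 mm
regression: sqrt(WA) = 1.522 + 0.1748 * Pi
Pi10 = 3.270 mm
closed-form oracle Pi10 = 3.244 mm
```

The measured regression reproduces the analytic Pi10 (from Pi = 2πr and
WA = π((r+t)² − r²)) to 0.026 mm.  Fitting the diagnostic ladder on a
simulated 1140-subject cohort (`python examples/04_diagnostic_ladder.py`)
prints the per-model confusion tables and validation summaries, ending with:

```
full model shrinkage factor: 0.980
full vs baseline NRI:        +43.5 % (events +37.8, non-events +5.7)
full vs inspiratory-only:    +14.3 %
```

i.e. adding the three CT biomarkers to demographics moves a net 43.5% of
subjects to the correct side of the diagnostic cutoff, and the bootstrap
finds little overfitting (2% coefficient shrinkage) at this sample size.

Other entry points: `examples/01_cohort_simulation.py` (cohort generator and
its summary), `examples/02_density_biomarkers.py` (IN₋₉₅₀ and E/I against
phantom ground truth).  A thin CLI wraps the same functions:

```bash
copdct run-all --seed 1 --out-dir out/          # phantom -> quantify -> airways -> fit
copdct simulate-cohort --n 1140 --seed 1 --out cohort.csv
copdct fit --cohort cohort.csv --bootstrap 500 --seed 7 --out ladder.json
```

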