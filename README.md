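# rsibreast

Automated assessment of breast-tumour response to neoadjuvant therapy
from multi-b-value diffusion-weighted MRI (DWI).

Manual response monitoring measures the longest tumour diameter on
contrast-enhanced MRI at every scan, which needs an expert reader and
gadolinium contrast. `rsibreast` automates the measurement from DWI
alone after a single pre-treatment delineation:

1. **Three-component signal fit** — the diffusion decay
   `S(b) = Σᵢ Cᵢ·exp(−b·ADCᵢ)` with fixed diffusivities `ADC₁<ADC₂<ADC₃`
   is inverted per voxel by exact non-negative least squares, giving
   restricted (`C1`), hindered (`C2`) and free (`C3`) signal
   contributions; maps are normalized to the 95th percentile of
   `√(C1·C2)` in a contralateral control ROI.
2. **Voxel classifier** — joint `(C1, C2)` densities from pooled
   pre-treatment cancer and control voxels define a binned posterior
   `P(cancer|C1,C2)` lookup table, applied at every time point.
3. **Automatic sizing** — the pre-treatment cancer ROI dilated by 1 cm
   (plus any classified component connected to it) bounds the search;
   the largest connected component above probability 0.5 is measured by
   its longest 3D diameter in cm.
4. **Endpoint statistics** — absolute post-treatment values and relative
   changes predict non-pCR (residual disease at surgery): Mann–Whitney
   ROC AUC with DeLong intervals, maximum-accuracy and
   specificity≥90% operating points with exact Clopper–Pearson CIs,
   exact McNemar and DeLong paired tests at α = 0.025.
5. **Phantom** — a synthetic longitudinal cohort generator (bilateral
   breast geometry, Rician noise, known shrinkage schedules and pCR
   labels) makes the whole chain testable end to end.

A conventional ADC comparator (log-linear fit over b < 1000 s/mm²,
ROI mean) is included. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from rsibreast.phantom import generate_cohort
from rsibreast.pipeline import RunConfig, run_cohort_pipeline
from rsibreast.response_stats import evaluate_cohort

cohort = generate_cohort(n_patients=27, pcr_fraction=10/27, seed=3,
                         noise_sigma=0.05)          # Rician, SNR ~ 20
dataset = run_cohort_pipeline(cohort, RunConfig())  # fit, train, measure
print(dataset.to_frame().head(4))

summary = evaluate_cohort(dataset)["absolute_post"]["modalities"]["rsi"]["summary"]
print(f"post-treatment AUC = {summary.auc:.2f}")
print(f"sens = {summary.best.sensitivity:.2f}  "
      f"spec = {summary.best.specificity:.2f}  at {summary.best.threshold:.2f} cm")
```

prints

```
  patient_id timepoint  rsi_diameter_cm  dce_diameter_cm  mean_adc    pcr
0        p00       pre         3.288237         2.963347  0.000839  False
1        p00     early         2.549510         2.569493  0.000988  False
2        p00       mid         2.549510         2.467243  0.000964  False
3        p00      post         2.061553         2.087988  0.001272  False
post-treatment AUC = 1.00
sens = 1.00  spec = 1.00  at 0.56 cm
```

Patient `p00` is a non-responder: its automatically measured diameter
shrinks only modestly from the 3.3 cm baseline and still exceeds 2 cm
after treatment, its simulated manual DCE measurement tracks it to
reader-error precision, and its pre-treatment mean ADC (0.84×10⁻³
mm²/s) is a realistic tumour magnitude. Responders in the same cohort
measure 0.0 cm at post-treatment, so classification is perfect and the
accuracy-optimal threshold falls between the classes — the phantom
validates the computational chain, not clinical performance.

The same workflow is available as a CLI over an on-disk study layout:

```bash
rsibreast simulate --out studies/ --patients 27 --seed 3
rsibreast train --studies studies/ --out lookup.json
rsibreast measure --study studies/p00 --lookup lookup.json --cohort-csv cohort.csv
rsibreast evaluate --cohort-csv cohort.csv --out results.json
```

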