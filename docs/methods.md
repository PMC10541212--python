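# Methods

## Problem setting

Neoadjuvant therapy of breast cancer is monitored by imaging; the
question at each scan is whether residual invasive tumour remains. The
clinical reference standard is manual measurement of the longest tumour
diameter on contrast-enhanced MRI at every time point, which requires an
expert reader and gadolinium contrast. `rsibreast` implements an
automatic alternative built on multi-b-value diffusion-weighted MRI
(DWI): a fixed-diffusivity multi-compartment signal model turns the raw
diffusion decay into tissue-type contrast, a pooled density-ratio
classifier converts that contrast into a voxel-wise probability of
cancer, and simple 3D geometry converts the thresholded probability map
into a longest-diameter measurement that needs manual input only at the
pre-treatment scan. The endpoint statistics compare the automatic
measurement against manual contrast-enhanced diameters and mean ADC for
predicting non-pCR (residual disease at surgery; the positive class).

All longitudinal volumes are assumed already co-registered to a common
grid; registration, distortion and motion correction are out of scope.

## Signal model and fitting

The direction-averaged diffusion signal at b-value `b` (s/mm²) is
modelled as a sum of three mono-exponential compartments with globally
fixed diffusivities:

    S(b) = C1·exp(−b·ADC1) + C2·exp(−b·ADC2) + C3·exp(−b·ADC3),
    ADC1 < ADC2 < ADC3.

`C1` captures restricted and hyper-restricted diffusion (tumour cells,
fatty tissue), `C2` hindered diffusion (tumour and fibroglandular
tissue), `C3` free/vascular water. Because the diffusivities are fixed,
the per-voxel problem is linear in `(C1, C2, C3)` and the design matrix
is shared by every voxel.

The fit is non-negative least squares by default: the contributions are
physical signal fractions, and unconstrained fits go negative under
noise (a flag restores plain OLS). The NNLS solution is computed
exactly by enumerating the 2³ candidate supports, solving each
unconstrained subproblem with a precomputed pseudoinverse, and keeping
the feasible candidate with minimal residual — for a convex problem
this is the global optimum, and it vectorizes over the whole volume.
Voxels whose unconstrained solution is already feasible skip the
enumeration. Noiseless forward signals are recovered to ~1e-12.

The component diffusivities are a required configuration input — they
are acquisition- and site-calibrated numbers, not estimable from a
4-shell acquisition. The package ships an example triple
`(1.0e-4, 1.5e-3, 1.0e-2) mm²/s` (plausible restricted / hindered /
free magnitudes) used by the phantom and tests; it carries no claim of
being a calibrated value.

## Normalization

The arbitrary scanner scale is removed per patient by dividing the
fitted maps by the 95th percentile of `sqrt(C1·C2)` inside the
contralateral healthy-breast control ROI (percentile convention:
sorted-order linear interpolation at rank `0.95·(n−1)`). All three
components are divided by the same factor so the maps stay on one
scale. The pipeline recomputes the factor at every time point from the
registered control ROI rather than reusing the pre-treatment factor:
control tissue is treatment-invariant, so this also absorbs
inter-session scanner scaling. Because the fit is linear, normalizing
the maps is equivalent to normalizing the raw signal; the end-to-end
result is invariant to any global signal scale.

## Voxel classifier

Normalized `(C1, C2)` pairs from the pre-treatment cancer and control
ROIs of **all** patients are pooled and binned on a shared 2D histogram
(default 128×128 bins spanning `[0, q]` per axis, `q` the pooled 99.5th
percentile). Each class histogram is normalized to a density and mixed
with a uniform pseudo-mass (default 0.5), with optional Gaussian
smoothing in bin units (default off). The posterior per bin is Bayes'
rule with prior `π` (default 0.5, making the posterior a pure density
ratio):

    P(cancer | C1, C2) = f_c·π / (f_c·π + f_k·(1−π)).

Mixing the pseudo-mass *after* normalization matters: adding raw
per-bin pseudocounts before normalizing skews every empty bin towards
the smaller training class (here cancer), silently classifying
background air as tumour. With the density-space mixture, bins with no
training data fall back exactly to the prior, and the strict `> 0.5`
classification threshold leaves them unclassified.

Out-of-range values clamp to the edge bins — extreme normalized
contributions beyond the training range are more plausibly edge-class
than undefined. Training uses pre-treatment data only; later time
points are pure lookups.

## Lesion geometry

The pre-treatment cancer ROI is dilated by 10 mm (Euclidean distance in
physical mm between voxel centers, anisotropic spacing respected, via a
sampled distance transform) to form the *tumor-containing region*. Any
connected component of the classified mask that intersects this region
is absorbed in full, so growth beyond the margin is not truncated. The
largest connected component of the classified mask inside the final
region is the lesion; its longest diameter is the maximum pairwise
distance between member voxel centers in mm, reported in cm.

Numerical and convention choices:

* connectivity defaults to the 26-neighbourhood (6/18 configurable);
* the diameter is the full 3D maximum chord — any 3D chord lies in some
  plane, so this realizes "longest diameter in any plane"; components
  above 400 voxels route through the convex hull (identical result,
  falling back to all-pairs for degenerate point sets);
* equal-size component ties break to the smallest minimum linear voxel
  index (determinism);
* empty and singleton components measure 0.0 cm, the natural value for
  a resolved lesion under the center-coordinate convention.

## ADC comparator

The conventional apparent diffusion coefficient uses only b < 1000
s/mm² (b = 0 and 500 with the standard acquisition): per voxel, ADC is
the negative OLS slope of `ln S` on `b`, the two-point closed form
`ln(S0/S500)/500` when exactly two shells are retained. Voxels with any
non-positive retained signal are undefined. The ROI mean runs over the
pre-treatment cancer ROI at every registered time point, excluding
undefined voxels and exact-zero values; negative values (possible under
noise) are retained unless a flag excludes them.

## Endpoint statistics

Non-pCR is the positive class. Scores are absolute post-treatment
values (all modalities, higher = positive) or relative change from
pre-treatment, `(v_t − v_pre)/v_pre` (−1.0 = lesion resolved); for
change in mean ADC the a-priori direction is inverted (an ADC increase
is assumed to mark response, so lower change = positive).

* **AUC**: Mann–Whitney probability with half-weight ties; CI by Wald
  interval on the DeLong variance (the single-curve structural
  component estimator), clipped to [0, 1].
* **Operating points**: thresholds are midpoints of adjacent distinct
  scores plus ±∞. The primary point maximizes accuracy (ties → higher
  specificity, then fewer predicted positives); a secondary point
  maximizes sensitivity subject to specificity ≥ 0.90 (ties → higher
  specificity). Sensitivity, specificity and accuracy each carry an
  exact Clopper–Pearson 95% interval from beta quantiles, the unique
  standard method that reproduces the reference tables from their
  integer counts.
* **Paired tests**: exact two-sided McNemar on discordant
  classifications among true positives (sensitivity) and true negatives
  (specificity), `p = min(1, 2·P(X ≤ min(b,c)))`, `X ~ Bin(b+c, ½)`;
  DeLong's test on correlated AUCs via the paired covariance of
  placement values. Alpha defaults to 0.025 (two primary outcomes).
  Perfectly separated curves make the DeLong variance degenerate; the
  cohort evaluator records no test in that case rather than fabricating
  a p-value.

## Synthetic phantom

The phantom emulates the study conditions so every stage is testable
without patient data: 27 patients, 10/27 labelled pCR, four time points
(pre/early/mid/post), b = {0, 500, 1500, 4000} s/mm², 2.5×2.5×5.0 mm
voxels on a 64×64×16 grid. Each patient is a bilateral breast geometry:
two fat blocks with inner fibroglandular regions and one tumour
ellipsoid (major semi-axis drawn 8–16 mm, minors 5–10 mm, centre
snapped to a voxel center), with tissue triples fat (0.8, 0.1, 0.05),
fibroglandular (0.1, 0.7, 0.15), tumour (0.55, 0.55, 0.10) — fat
C1-dominant, fibroglandular C2-dominant, tumour elevated in both, the
qualitative structure the classifier relies on. The control ROI is a
box in the contralateral breast spanning both healthy tissues.

Shrinkage schedules scale the tumour semi-axes: pCR patients shrink
30–50% (early), 60–90% (mid) and fully by post-treatment; non-pCR
patients shrink at most 20%. A simulated manual DCE diameter (true
diameter + N(0, 0.1 cm) reader error) and the pathology label accompany
each patient. Noise is Rician — `sqrt((S+g1)² + g2²)` with independent
N(0, σ²) perturbations — with σ = 0.05 (≈ SNR 20 at b = 0) as the
standard noisy condition; a Gaussian mode exists behind a flag.
Per-patient seeds derive from the master seed, so cohorts are exactly
reproducible and individual patients independent of generation order.

What the phantom does **not** emulate: real anatomy, partial-volume
boundaries, coil/EPI artifacts, registration error, or the overlap of
treated-tumour and healthy-tissue component distributions seen in vivo.
Phantom tissue classes are well separated in `(C1, C2)`, so perfect
pipeline recovery on the phantom demonstrates correctness of the
computational chain, not clinical accuracy; the published-scale
diagnostic numbers (sensitivity ~0.7 at specificity 0.9) arise from
biological overlap the phantom deliberately omits.

## Problem sizes and runtimes

The default test and acceptance cohorts use 64×64×16 grids (27
patients) or 32×32×8 (small fixtures), chosen so the complete pipeline
runs in seconds while every geometric scale (voxel diagonal 6.1 mm,
tumour diameters 1.6–3.2 cm, 10 mm dilation) keeps its study
proportions. The bootstrap oracle for DeLong's test uses 20,000
replicates at n = 40.

## Known limitations

* The fixed-diffusivity triple must come from prior calibration; the
  package provides no estimation of it.
* The histogram lookup needs enough pooled training voxels to occupy
  the tumour region of the `(C1, C2)` plane; very small cohorts should
  reduce `n_bins` or enable smoothing.
* Diameter measurement is voxel-center based: a lesion shrunk to one
  voxel reads 0.0 cm.
* DeLong and McNemar assume paired subjects; cohorts with missing
  modalities are compared on the shared subset only.
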