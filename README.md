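# adcroi

Computer-calculated reference ADC values for prostate lesions, and the
multi-reader agreement analysis that goes with them.

## The problem

Apparent diffusion coefficient (ADC) values from prostate MRI carry real
diagnostic information — clinically significant prostate cancer restricts
diffusion, and thresholds around 700–900 ×10⁻⁶ mm²/s have been proposed to
separate benign from malignant peripheral-zone tissue. But the number a
radiologist reports depends heavily on *how* the region of interest (ROI)
is drawn: its size, where it is placed, and whether the reader targets the
darkest (lowest-ADC) part of a heterogeneous lesion. This package provides:

1. **A reproducible, computer-calculated reference value** for a lesion:
   slide a small 2D ROI kernel over every placement that fits inside a 3D
   lesion mask and report the *minimum* kernel-mean ADC,

   `ref(n) = min over placements p of (1/n) Σ_{o ∈ K_n} ADC[p + o]`,

   for a ladder of kernel sizes *n* ∈ {1, 2, 3, 5, 9, 17, 25, 33, 49}
   pixels (square kernels where an odd square exists, nearest-to-center
   "near-circular" kernels otherwise). If no kernel of a given size fits
   inside the mask, the next smaller size's value is substituted. The
   whole-lesion 10th-percentile ADC and the median ADC of the
   peripheral-zone parenchyma are computed from the same masks.
2. **Agreement statistics for a multi-reader study** in which readers
   measure each lesion three ways — a free-hand 2D ROI, an instructed
   9-pixel ROI covering the lowest-ADC area, and the 10th percentile of a
   3D whole-lesion contour: multi-reader Bland-Altman 95% limits of
   agreement (1.96 × SD of reader-minus-lesion-mean differences), ICC of
   each reader against the computed reference (two-way random, absolute
   agreement, single measures by default), a Friedman omnibus across the
   three methods with Holm-adjusted Wilcoxon post-hoc tests, and unpaired
   t-tests for technical covariates (scanner model, endorectal coil).
3. **A synthetic ADC phantom and virtual-reader simulator** so the whole
   pipeline is testable without patient images: an ellipsoidal lesion of
   intermediate ADC containing a small low-ADC focus (the "sparse
   high-grade component" of a heterogeneous tumor) inside a brighter
   parenchyma background, and ten virtual radiologists with individual
   ROI-size habits, placement jitter and contouring error.

## Worked example

```python
import adcroi

# simulate the default virtual study: 40 lesions x 10 readers x 3 sessions
measurements, reference = adcroi.run_virtual_study(seed=1)

study = adcroi.AgreementStudy(measurements, reference=reference).fit()
print(study.summary())
```

prints

```
Multi-reader ADC agreement
==========================================
session 1: LoA +-  192.4  (SD   98.2, 40 lesions x 10 readers)
session 2: LoA +-  109.9  (SD   56.1, 40 lesions x 10 readers)
session 3: LoA +-  102.8  (SD   52.4, 40 lesions x 10 readers)
Friedman across methods: chi2 = 60.49, p = 7.31e-14
  session 1 vs 2: p_holm = 1.37e-15
  session 1 vs 3: p_holm = 1.98e-15
  session 2 vs 3: p_holm = 0.907
ICC vs reference (ICC2):
  session 1: range 0.234 - 0.915
  session 2: range 0.654 - 0.944
  session 3: range 0.817 - 0.964
```

Read it as: free-hand ROIs (session 1) disagree between readers by about
±192 ×10⁻⁶ mm²/s; instructing readers to use a 9-pixel ROI on the
lowest-ADC area (session 2) roughly halves that; and the instructed 2D
method is statistically indistinguishable from the much slower
whole-lesion-percentile method (session 3, Holm-adjusted p = 0.91). The
per-reader ICC ranges show the same story — every reader tracks the
computed reference better once the measurement method is pinned down.

Computing references for one image:

```bash
adcroi reference --adc adc.nii.gz --mask lesion.nii.gz --out refs.csv
adcroi simulate --seed 17 --out-dir sim/
adcroi agreement --measurements sim/measurements.csv --reference sim/reference.csv --out report.json
```

## Layout

```
src/adcroi/kernels.py     ROI kernel footprints (square / near-circular)
src/adcroi/reference.py   sliding minimum-mean, percentiles, fallback rule
src/adcroi/agreement.py   Bland-Altman, ICC, Friedman/post-hoc, t-tests
src/adcroi/phantom.py     synthetic ADC phantom + brute-force truth
src/adcroi/readers.py     virtual readers, three-session study simulator
src/adcroi/io.py          NIfTI / CSV / XLSX ingestion, reports, plots
src/adcroi/cli.py         `adcroi reference|agreement|simulate|report`
docs/methods.md           model assumptions, parameter choices, limitations
```

Coordinates are 0-based `(slice, row, col)`; ADC values are
×10⁻⁶ mm²/s throughout.
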