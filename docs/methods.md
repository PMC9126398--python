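# Methods

This note records the modelling choices behind `adcroi`: what is computed,
what the synthetic data do and do not emulate, and where genuinely open
design decisions were resolved.

## Reference computation

**Kernels.** An ROI of *n* pixels is a set of integer (row, col) offsets
around an anchor at (0, 0). Sizes with an odd integer square root
(1, 9, 25, 49) are squares; the others (2, 3, 5, 17, 33) are
"near-circular": the *n* offsets nearest the origin in Euclidean distance,
ties broken by ascending (distance, row, col). Only the pixel counts of
the non-square shapes are fixed by the measurement protocol, not their
exact footprints; k-nearest-to-center is the canonical realisation of
"near-circular", is deterministic, and guarantees the family is nested
(each kernel is a subset of every larger one). At 49 pixels the square and
near-circular families genuinely differ ((0, ±4) is nearer the center than
the square's corners); the square is the default there, and a
`shape_policy="all_near_circular"` switch exists for sensitivity analysis.

**Placement rule.** A placement is valid only if the *entire* footprint
lies inside the lesion mask on one slice (anchor-only containment is
rejected — the fallback rule below presupposes that an ROI can fail to
"fit"). Placements are evaluated independently on every slice of the 3D
mask; kernels are strictly in-plane. The reference for a size is the
minimum kernel-mean over all valid placements on all slices; ties resolve
to the first anchor in (slice, row, col) scan order. When a size fits
nowhere, the next smaller size's value is carried forward (recursively;
size 1 always fits a nonempty mask), and the result records both the
requested and the effective size.

**Implementation.** The sliding minimum is computed with shifted-array
accumulation (one padded add per kernel offset, vectorised over slices);
the winning value is then recomputed directly as the footprint mean so the
reported number is exactly the mean of the covered voxels. An independent
brute-force enumerator (`phantom.brute_force_min_mean`) exists solely as
an oracle: phantom ground truth is computed with it, never with the
optimized path, and the test suite asserts exact agreement between the two
on randomized volumes.

**Percentiles.** The whole-lesion 10th percentile and the
peripheral-zone median use linear interpolation between order statistics
(numpy's default). The convention is switchable (`lower`, `nearest`)
because histogram-tool conventions differ between vendors; at the voxel
counts involved the choice moves the value by well under 1%.

**Units.** ADC is 10⁻⁶ mm²/s everywhere in memory. NIfTI volumes stored
in mm²/s are rescaled at load time (`unit_scale=1e6`).

## Agreement statistics

**Limits of agreement.** With ten readers there is no single "other
rater" to difference against, so the Bland-Altman differences are taken
from the per-lesion mean across readers; the 95% limits are ±1.96 × SD of
all such differences, with no small-sample or reader-count inflation
factor. The SD denominator (ddof 1 vs 0) is exposed; at 400 cells the two
differ by ~0.1%.

**ICC.** Each reader is paired with the computed reference as two raters
scoring the same lesions. The default form is ICC(2,1) — two-way random
effects, absolute agreement, single measures — because a reader who is
consistently 50 units high should be penalised when judged against an
absolute reference; ICC(3,1) (consistency) is available. Estimates and
F-based 95% CIs come from pingouin; the test suite cross-checks the
estimates against the Shrout–Fleiss ANOVA formulas computed from scratch.

**Method comparison.** The Friedman omnibus runs on absolute deviations
from the per-lesion reader mean, with lesion × reader cells as blocks by
default (`friedman_block="lesion"` aggregates to per-lesion means
instead). Post-hoc pairwise comparisons default to the two-sample
Wilcoxon rank-sum with Holm adjustment; a paired signed-rank flavor is
provided, since for session-paired data signed-rank is the
design-consistent choice even though rank-sum is what reader studies of
this design conventionally report.

**Group contrasts.** Scanner-model and coil contrasts use Welch's t by
default (no equal-variance assumption); Student's t is a switch.

## The synthetic phantom

The phantom emulates the features the analysis is sensitive to, at the
scale of one lesion:

* a parenchyma background: smooth Gaussian random field,
  mean 1400 × 10⁻⁶ mm²/s, SD 100, correlation length ~4 voxels;
* an ellipsoidal lesion (default radii 2.5 slices × 9 × 9 pixels) at
  ~900, with smooth intra-lesion texture (SD ~80–160) — low-grade tumor
  is not uniform, and whole-lesion percentiles inherit that structure;
* a small low-ADC focus (sphere, ~600) inside the lesion, standing in for
  a sparsely present high-grade component — this is what makes the
  minimum-mean reference increase monotonically with ROI size;
* partial-volume blur: a Gaussian smoothing of the painted level sets,
  strongest through-slice (slices are 4–7 mm against ≤1 mm pixels). This
  matters: with crisp level-set boundaries the whole-lesion percentile is
  almost insensitive to contouring error, which would make the
  3D-percentile method look unrealistically reproducible;
* i.i.d. Gaussian voxel noise (SD 40). Gaussian, not Rician: ADC maps are
  fitted parameters, not magnitude images — a documented simplification.

Grids default to 10 × 64 × 64 at 1 mm pixel spacing, a deliberate
scale-down from clinical 256 × 256 matrices that preserves every geometric
relationship the method depends on (kernel ≪ focus ≪ lesion ≪ grid) while
keeping a 50-replicate study suite fast. Lesion-to-lesion heterogeneity
(size, ADC level, focus conspicuity, background level) is drawn per lesion
from ranges matching the reported lesion population (reference values
~650–1100 with SD ~130–190 across lesions).

Ground truth for every phantom is computed by brute force at generation
time, so recovery tests never test the optimized path against itself.

## Virtual readers

Each of the ten reader profiles has: a log-normal free-ROI area
distribution (medians 7.5–103 mm², matching the span of habitual ROI sizes
reported for real readers, including one who uses very large ROIs);
Gaussian placement jitter around the true lowest-ADC location (larger in
the free session than the instructed one); and a contouring-error model
for the whole-lesion session — an in-plane translation plus a signed
dilation/erosion of the true contour realised as a level set of the signed
Euclidean distance transform, soft-capped at ±3.5 voxels. Free-session
ROIs are anchored on the lesion but may overhang it (that is precisely how
oversized clinical ROIs dilute the low-ADC focus and acquire a positive
bias); instructed-session ROIs are snapped to the nearest fully-contained
placement, so a zero-jitter reader reproduces the computed reference
exactly, and a zero-perturbation contour reproduces the 10th percentile
exactly.

The jitter, contour and bias defaults were calibrated once so that the
default 40 × 10 study lands in the empirically reported operating regime —
limits of agreement near ±205 / ±120 / ±112 for the three sessions and
per-session ICC ranges near 0.35–0.92 / 0.74–0.95 / 0.82–0.97 — and are
then frozen; they are behavioural stand-ins, not estimates of any
individual's parameters. What passing virtual-study tests show is that the
*analysis pipeline* reproduces the expected ordering (free ROI worst,
instructed 2D ≈ whole-lesion percentile) under realistic noise; they say
nothing about any particular scanner, reader or patient population.

Randomness is structured as a `SeedSequence` tree (study → lesion → reader
→ session), so reader streams are independent and every output is
bit-reproducible from the study seed.

## Numerical conventions and degenerate inputs

* Empty masks are rejected at construction; a kernel that fits nowhere is
  a signal (`NO_FIT`), not an exception, and only `multi_size_reference`
  converts it into a fallback.
* Erosions that would empty a contour fall back to the unperturbed mask.
* Zero-variance inputs to the ICC raise (the coefficient is undefined);
  exactly identical rater columns short-circuit to 1.0.
* Identical method columns give a Friedman statistic of exactly 0 with
  p = 1 (scipy rejects the all-tied case, which is handled explicitly).
* Percentile q is validated to [0, 100]; ADC volumes must be finite and
  non-negative.

## Known limitations

* The non-square kernel footprints are a documented canonical choice, not
  a published specification; results at sizes 2, 3, 5, 17, 33 depend
  mildly on that choice.
* The phantom has one lesion per volume and no transition-zone anatomy,
  susceptibility artifacts, or scanner-dependent bias fields; scanner
  effects can only be emulated as per-lesion shifts.
* Reader behaviour is reduced to size, jitter and contour-scale
  parameters; real readers also differ in windowing, slice selection and
  fatigue, which are not modelled.
* The agreement module assumes complete block designs and will refuse
  incomplete ones rather than impute.
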