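# Methods

This note documents the models, conventions and design choices behind
`mammotex`, and what the synthetic data can and cannot show.

## ROI model and normalization

An ROI is a single-channel crop of a digital mammogram, any size ≥ 16×16,
8- or 16-bit. Intensities are min–max normalized to [0, 1] at load time
(constant images map to zeros, avoiding 0/0), which makes every downstream
stage invariant to positive affine intensity maps of the raw pixels.
Coordinates are 0-based (row, col) with the origin at the top-left.

## Haar decomposition

The 2-level 2D Haar transform uses the **orthonormal** convention: one
analysis step maps each 2×2 block [[a,b],[c,d]] to LL=(a+b+c+d)/2,
HL=(a−b+c−d)/2 (differences along rows), LH=(a+b−c−d)/2, HH=(a−b−c+d)/2.
This choice is deliberate: it makes Parseval's identity exact (total
squared-coefficient energy equals image energy), the transform exactly
invertible, and the per-band statistics scale-consistent across levels.
Odd dimensions are reflect-padded to the next even size before each step;
padding affects border coefficients only. Depth is fixed at two levels —
the eight sub-bands LL1…HH2 define the feature schema.

## Sub-band statistics (48 features)

Six descriptors per band, computed on the raw wavelet coefficients
(not rescaled to 8-bit): population mean and variance, skewness m₃/m₂^1.5,
kurtosis m₄/m₂² (raw, 3 for a Gaussian; an `excess_kurtosis` flag flips the
convention), Shannon entropy in bits over a 256-bin histogram spanning the
band's own [min, max] (configurable `nbins`), and relative smoothness
R = 1 − 1/(1+σ²) with σ² the unrescaled population variance — some texts
normalize the variance first; this package does not, and documents it.
Zero-variance bands use the degenerate conventions skew = kurt = entropy =
R = 0, so feature vectors are always finite. Feature order is frozen in
`mammotex.schema` (band-major: `Mean_LL1` … `RelSmoothness_HH2`).

## Interest-point detector (blob counting)

The detector approximates the scale-normalized determinant of the Hessian
with second-derivative box filters (lobe L/3) evaluated in constant time on
an integral image; det ≈ Dxx·Dyy − (0.9·Dxy)², with 0.9 the usual relative
weight correcting the box approximation. Filter sizes follow the standard
octave ladder (9, 15, 21, 27; 15, 27, 39, 51; …), 3 octaves × 4 scales by
default.

**Scale normalization.** Box sums are divided by 9L (constant Frobenius
norm of the kernel across sizes), not by the filter area L². This matters:
under area normalization the response of any blob decreases monotonically
with filter size, so a 3×3×3 (scale, row, col) maximum never forms and
nothing is detected. With constant-norm weighting a Gaussian blob of width
σ peaks at its matched filter size (σ ≈ 2 px ↔ L = 15), which restores
proper scale selection; the two conventions coincide at L = 9.

Detection keeps strict local maxima over the 3×3×3 neighborhood at the two
interior scales of each octave, above a threshold expressed as a fraction
(default 0.05) of the peak response of a canonical unit-amplitude σ = 2 px
bump — a scale-free calibration that survives any change of the response
units. Ties are resolved in favor of the lexicographically-first
(scale, row, col). Only the detection stage exists; descriptors,
orientation assignment and matching are intentionally out of scope since
the pipeline consumes only the count. Note that at coarse scales a cluster
of nearby spots is itself a blob and is legitimately detected as one; exact
planted-spot counting is therefore only well-posed at the spot-scale
octaves with spots separated beyond the coarsest examined filter.

## Corner detector (Shi–Tomasi)

Gradients are central differences with replicated borders; the structure
tensor is accumulated under a 5×5 Gaussian window (σ = 1, configurable,
box weighting available). Eigenvalues come from the closed form for 2×2
symmetric matrices. The count uses R_ST = min(λ₁, λ₂) with a **relative**
threshold, quality_level (default 0.01) × image maximum — chosen over an
absolute threshold so counts are intensity-scale invariant, matching the
normalized pipeline — followed by greedy strongest-first non-maximum
suppression with a Euclidean min-distance exclusion (default 3 px),
deterministic tie-break by (row, col). The Harris score
R_H = λ₁λ₂ − k(λ₁+λ₂)², k ∈ [0.04, 0.06], is implemented and tested but
the count feature uses the minimum-eigenvalue criterion.

A consequence of the relative threshold worth knowing: on a lesion-free
textured ROI no strong corner exists, so the threshold drops and hundreds
of weak texture maxima qualify, whereas bright spots raise the maximum and
suppress them. The corner count therefore separates lesion-free from
lesion-bearing ROIs in both directions of the mechanism — exactly the kind
of behavior a count-based screening feature exploits.

## Feature selection

*Filter*: per-feature two-sided Wilcoxon–Mann–Whitney test between classes;
exact null for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise; features ordered by ascending p (most informative
first), ties broken by schema order. Being rank-based, the ordering is
invariant to strictly monotone feature transforms. *Embedded*: mean
decrease in Gini impurity over a 100-tree random forest, descending.

Top-k **selection frequency** across CV training folds is tested against
the exchangeable null in which each ranking is an independent uniform
permutation (top-k inclusion probability k/50). The per-feature p-value is
the doubled smaller binomial tail, capped at 1 — two-sided, so "always
selected" and "never selected" both register as departures while a feature
at exactly the null rate gets p ≈ 1.

## Classifier and evaluation

Random forest, 100 trees, at most 20 candidate features per split (clipped
to the number of selected features); trees grow to purity, so the ensemble
probability equals the fraction of trees voting positive. Evaluation is
repeated stratified 10-fold cross-validation with the ranking recomputed
on every training fold (no selection or normalization leakage). Test-fold
vote fractions are pooled within a round and metrics computed once per
round (a flag-free design choice; per-fold averaging is the alternative).
Classification threshold is 0.5 on the vote fraction. The positive class is
the pathological one: abnormal for screening, malignant for diagnosis.
Summaries are medians with 25th–75th percentile intervals across rounds;
dispersion quantiles are configurable. Method comparisons use the rank-sum
test on per-round metric samples with Bonferroni multiplication, capped at
1. All sub-seeds (fold shuffling, per-fold ranking, per-fold forest) derive
from one master seed through `numpy.random.SeedSequence` counters, making
every run bit-reproducible.

## Synthetic study conditions

The generator emulates only what the pipeline relies on, not X-ray physics:

- **Background**: white noise smoothed with a Gaussian kernel (correlation
  length drawn per ROI from 4–8 px), renormalized to [0, 1], then mapped to
  a per-ROI intensity window (base 0.05–0.3, contrast 0.3–0.65). The
  per-ROI jitter emulates patient-to-patient parenchymal density and
  exposure variation; without it all background statistics are nearly
  constant within a class, which no real cohort exhibits.
- **Spots**: anisotropic Gaussian bumps clustered within a disk.
  Benign-like preset: 5 spots, σ 1.8–2.8 px, amplitude 0.5–0.8, cluster
  radius 14 px, low eccentricity. Malignant-like preset: 13 spots,
  σ 0.9–1.8 px, amplitude 0.45–0.8, cluster radius 20 px, strong
  eccentricity/jitter. Spot scales sit inside the detector's resolvable
  range (finest filter 9 px ↔ σ ≈ 2). Normal ROIs are background only, and
  ground-truth spot lists are empty exactly for them.
- **Composition**: 64×64 px ROIs; 130 normal / 75 benign / 55 malignant by
  default, the class balance of the clinical study population this pipeline
  targets. Per-ROI seeds derive from (master seed, class, index), so
  enlarging any class regenerates existing ROIs identically.

**What passing on synthetic data does and does not show.** The presets are
deliberately well separated: they verify that every stage — decomposition,
statistics, detectors, in-fold selection, CV bookkeeping — is correct and
leak-free (label-permuted runs sit at AUC ≈ 50; intact runs near 100).
They do not emulate the hardness of clinical mammography, where reported
performance is far from perfect; absolute detector counts and accuracies
on real data depend on acquisition and annotation and are not claimed
here. One known divergence: synthetic spots leave strong footprints in the
detail-band variance/kurtosis statistics, so the interest-point count —
although clearly class-separated — is usually outranked by texture features;
the corner count, by contrast, tops the filter ranking in every fold of
the screening problem.

## Numerical and degenerate-input conventions

- Integral-image box sums are exact to cancellation error (~1e-13 relative);
  flat-image responses are asserted to ~0 rather than exactly 0.
- AUC uses the rank statistic with half credit for ties; an evaluation fold
  or report with a single class present is rejected, not silently scored.
- Constant features get filter p = 1 and rank last; single-class training
  sets, undersized windows/filters, malformed feature tables and non-finite
  inputs are rejected with named errors.
- The reproduction script uses 10 CV rounds rather than 100 — the package's
  default choice for a single-machine run; medians are stable well before
  that, and the round count is a parameter everywhere.

## Known limitations

- No DICOM or repository client; inputs are PNG/TIFF crops with a CSV label
  file.
- Detector counts are config-dependent (thresholds, octaves); only their
  within-study contrasts are meaningful, not absolute values across tools.
- The wrapper family of selection methods and view fusion (CC/MLO) are out
  of scope.
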