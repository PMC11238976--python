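# Methods

## The index

Given a reference image `I_R` and a target image `I_T` of the same scene,
each backend produces keypoints with index-aligned binary descriptors.
Correspondences are found by exhaustive nearest-neighbour search over all
descriptor pairs using Hamming distance, keeping a pair only when each
descriptor is the other's nearest neighbour (mutual cross-check). The
cross-check guarantees a one-to-one match set and acts as the only match
filter — there is no Lowe ratio test and no distance cutoff. Ties on equal
minimal distance are broken toward the lowest index, so matching is fully
deterministic. The index is the mean Hamming distance over the `N` matched
pairs, reported in raw bits (no normalisation by the descriptor length `L`;
a normalised value/`L` is exposed on the result object for cross-backend
comparison but is never used in the replication studies). `N = 0` raises an
error carrying both keypoint counts: an undefined index must never enter a
correlation as a silent 0.

Scale note: because the index is in bits of a backend-specific descriptor
(ORB 256, BRISK 512, AKAZE 486, REF 256), values are comparable across
conditions within a backend, not across backends.

## Feature backends

The index itself is agnostic to the feature algorithm; four backends are
provided.

* **orb** — scikit-image's ORB with its defaults, including the
  500-keypoint cap (keypoints are ranked by Harris response). Descriptors
  are 256-bit rotated BRIEF.
* **brisk** — in-repo. Detection: FAST segment test (9 contiguous of 16 on
  the radius-3 Bresenham circle, intensity step 30) on a 4-octave dyadic
  pyramid, 3×3 non-maximum suppression, quadratic sub-pixel refinement of
  each peak. Description: the concentric 60-point sampling pattern (rings
  of radius 0/2.9/4.9/7.4/10.8 pattern units, per-ring Gaussian smoothing),
  orientation from the long-distance point pairs (separation > 13.67), and
  one bit per short-distance pair — the 512 closest pairs — comparing the
  smoothed intensities after rotating and scaling the pattern to the
  keypoint.
* **akaze** — in-repo. A nonlinear scale space is built per octave by
  explicit Perona–Malik (g2 conductivity) diffusion steps between the
  sub-level evolution times `t = σ²/2`, with the contrast factor `k` set to
  the 70th percentile of the smoothed gradient magnitude; four octaves of
  four sub-levels, base σ₀ = 1.6, step size 0.2 (inside the explicit
  stability limit). Keypoints are 3×3 maxima of the σ⁴-normalised
  determinant of Hessian above 1e-4 (on unit-scaled intensities),
  deduplicated across levels within a 3-px radius and refined to sub-pixel.
  The descriptor is M-LDB: over a rotated patch of half-width 10σ, cell
  means of intensity, x-derivative and y-derivative on 2×2, 3×3 and 4×4
  grids are compared pairwise per grid and channel — (6+36+120)×3 = 486
  bits. Orientation is the Gaussian-smoothed gradient direction at the
  keypoint.
* **ref** — a deliberately minimal, fully self-contained backend used as a
  library-independent oracle for the matching core: single-scale FAST
  (threshold 20, no pyramid, integer positions) plus a BRIEF-style
  descriptor comparing σ=2-smoothed intensities at 256 frozen offset pairs
  (seeded once, constant thereafter). It is upright and single-scale by
  design; its simplicity is what makes it auditable.

All backends are deterministic; two runs on the same image are
bit-identical. The per-backend descriptor lengths are asserted, since the
index's scale depends on them.

## Synthetic phantom and noise model

The phantom emulates a head CT slice in Hounsfield units on a 512² grid:
an elliptical skull ring (+800 HU, lateral aspect 0.82) around uniform
brain-like tissue (40 HU) on air (−1000 HU), with 60 non-overlapping
low-contrast ellipses at ±20 HU placed by seeded rejection sampling, the
whole lightly smoothed (σ = 0.7 px) to emulate a reconstruction kernel's
band limit. The structure count and contrast are chosen so that every
backend finds well over 50 keypoints at default parameters — small
high-curvature ellipse boundaries are what corner/blob detectors respond
to. Display windowing uses the conventional brain window (center 40 HU,
width 80 HU) with round-half-up; feature detection always runs on the
windowed 8-bit image.

Quantum noise is additive white Gaussian with
`σ(CTDI) = σ_ref · √(CTDI_ref / CTDI)`, the first-order dose dependence of
photon noise after filtered back projection, clipped at the intensity range
edges. Defaults: `CTDI_ref = 89.1 mGy` (the reference acquisition's dose
index) and `σ_ref = 3 HU`, a typical brain-CT noise level at a
generous dose. The ten-condition dose series spans 2.7–74.2 mGy, i.e.
σ from ≈17 HU down to ≈3.3 HU.

What the phantom does **not** emulate: noise correlation introduced by the
reconstruction kernel (the noise here is white), beam hardening, partial
volume effects, and anatomical texture. Passing the studies here shows the
index behaves correctly under dose-like noise scaling and blur on a
head-like scene — not that its absolute values match any particular
scanner's images.

## Studies

**Validity.** The reference is a reference-dose (89.1 mGy) acquisition of
the clean scene — even the best acquisition carries noise. Noise targets
are fresh acquisitions at each CTDI of the dose series (independent noise
seeds); blur targets apply a k×k Gaussian, k = 3…21, with
`σ(k) = 0.3·(k/2 − 1) + 0.8` to the reference itself. (The common library
convention `0.3·((k−1)/2 − 1) + 0.8` differs — k = 3 gives 0.8, not
0.95 — and is available behind a flag.) Each condition records per-backend
keypoint counts, match count and index value plus SSIM and PSNR against the
reference; per series and backend, Pearson's product-moment correlation of
the index against SSIM is tested two-sided at α = 0.05, with the p-value
from the exact `t = r√((n−2)/(1−r²))` transform. Conditions with zero
matches are excluded from correlation (never imputed) with a logged
warning; a metric that is exactly constant across a series has no defined
correlation and is likewise skipped — it is maximally stable.

**Robustness.** Targets are translations (2–40 px, applied horizontally),
rotations (1–45° about the image center) and scalings (0.75–1.25× about the
center) — operations that do not change intrinsic quality. By default the
transformed image is a *second, independently noised* reference-dose
acquisition of the scene: two scans at the same dose share the signal but
not the noise, so the index sits at its same-dose operating level and its
stability across the series is a meaningful relative statement. (With
`independent_target=False` the reference itself is transformed; integer
translations then shift content bit-identically and the index collapses to
≈0 for every backend — maximally robust, but a degenerate baseline for a
relative stability measure.) Stability is summarised as the coefficient of
variation (sample std over mean) of the index across the translation
series, contrasted with SSIM's relative range and with the persistent
strong PSNR–SSIM coupling.

Affine transforms use bilinear interpolation, rotate/scale about the
geometric centre `((w−1)/2, (h−1)/2)`, keep the output size, and fill
exposed regions with 0 (air). Positive dx moves content rightward, dy
downward, positive angles counter-clockwise. Identity parameters return
bit-identical images.

**SSIM/PSNR.** SSIM uses the standard local-statistics formulation with a
uniform 7×7 sliding window, K₁ = 0.01, K₂ = 0.03, dynamic range 255,
averaged over all window positions (population statistics; reflective
borders). A Gaussian-weighted window is available by flag. PSNR is
`10·log₁₀(255²/MSE)`, reported as +∞ at zero MSE (and excluded from
correlations there).

## Determinism and numerics

One seed governs a study; per-condition noise seeds are spawned from it
with a seeded generator, and reports (CSV and JSON, including full
parameter provenance) are byte-identical across repeated runs. Rounding of
intensity values is always round-half-up then clip. Matching uses packed
64-bit popcount arithmetic, chunked to bound memory; it is verified against
an independent O(N²) loop oracle. Sub-pixel refinement fits a 1-D parabola
per axis through each response peak, clamped to ±0.5 px, falling back to
the integer position where the curvature is not concave.

## Problem sizes

The replication studies run on the 512² phantom with all four backends:
20 validity conditions and 11 translation conditions, each condition one
detect-describe-match cycle per backend (roughly a minute per study on one
CPU). The determinism check uses a 256² phantom with compact three-condition
series, which exercises the identical code paths.

## Known limitations

* The in-repo BRISK/AKAZE backends are compact implementations of the
  published designs, not bit-compatible with any other library's output;
  keypoint counts and index values are therefore not comparable with other
  implementations even on the same image (the original publications'
  absolute tables are not reproducible without their exact acquisitions and
  library builds in any case).
* The index has no normalised theoretical range; interpreting absolute
  values requires a fixed backend and imaging protocol.
* Rotation invariance of the in-repo backends relies on simple
  gradient-based orientation estimates; under large rotations the index
  rises more for `ref` (upright by design) and `brisk`/`akaze` than a
  production implementation might show.
* The phantom's white-noise model understates the low-frequency noise
  texture of real FBP reconstructions; correlated noise would likely lower
  all keypoint counts at low dose.
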