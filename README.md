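# kpiqa — keypoint-feature image quality assessment for CT

`kpiqa` is a full-reference image quality assessment (IQA) tool for 2-D
grayscale medical images, built around a keypoint-feature index: detect
keypoints and binary feature descriptors in a reference and a target image,
find corresponding keypoints by brute-force Hamming matching with a mutual
cross-check, and report the mean Hamming distance over the matched pairs,

```
PI = (1/N) Σᵢ ‖F⃗_Rᵢ − F⃗_Tᵢ‖_Hamming ,
```

where `N` is the number of corresponding keypoint pairs and `F⃗` the binary
descriptor of a keypoint. Identical images give `PI = 0`; noise and blur
drive `PI` up in step with falling SSIM; and — unlike SSIM and PSNR —
`PI` is largely insensitive to translations, rotations and scalings that do
not change intrinsic image quality. That robustness, plus the ability to
*visualize* exactly which local structures lose their features as quality
degrades, is the point of the index. It is aimed at CT protocol
optimization tasks (dose/kernel trade-offs) where a full-reference metric
is wanted but misalignment between acquisitions would corrupt SSIM.

Four interchangeable feature backends are provided, all producing binary
descriptors compared with Hamming distance:

| backend | detector | descriptor | bits |
|---------|----------|------------|------|
| `orb`   | multi-scale FAST + Harris ranking (scikit-image) | rotated BRIEF | 256 |
| `brisk` | multi-scale FAST segment test | concentric-pattern short-pair comparisons | 512 |
| `akaze` | nonlinear-diffusion scale space, det-of-Hessian | M-LDB (intensity/dx/dy cell grids) | 486 |
| `ref`   | single-scale FAST segment test | BRIEF-style frozen sampling pattern | 256 |

The `ref` backend is deliberately small and fully self-contained; it serves
as a library-independent oracle for the matching/index core.

Because clinical CT acquisitions cannot ship with the code, the package
includes a synthetic head phantom (skull ring, brain-like interior with
low-contrast structures, air background, intensities in HU) and a
dose-indexed quantum-noise model (σ ∝ 1/√CTDI_vol), so the entire
validation runs from a seed with no external data.

## Worked example

Generate a reference slice and a low-dose (13.7 mGy) acquisition of the
same scene, then score it:

```
$ kpiqa phantom --size 512 --seed 1 --out ref.png
$ kpiqa phantom --size 512 --seed 1 --ctdi 13.7 --out tgt.png
$ kpiqa score --ref ref.png --target tgt.png --backend orb --with-ssim --with-psnr
backend: orb
keypoints_ref: 500
keypoints_tgt: 500
matches: 89
pi: 81.6067415730337
ssim: 0.6979516820558301
psnr: 24.28745170150694
```

Reading: ORB found 500 keypoints in each image (its default cap); 89 pairs
survived the mutual cross-check; on average 81.6 of the 256 descriptor bits
differ between matched keypoints — the quantum mottle at 13.7 mGy has
substantially perturbed the local features (for the identical image the
value is 0.0). SSIM 0.70 and PSNR 24.3 dB agree that quality dropped.
`kpiqa visualize --ref ref.png --target tgt.png --backend orb --out overlay.png`
draws the two images side by side with red keypoint dots and green match
lines.

The two study pipelines reproduce the whole validation:

```
$ kpiqa study --mode validity   --seed 0 --out results/validity
$ kpiqa study --mode robustness --seed 0 --out results/robustness
```

Each writes per-condition tables (CSV), Pearson correlation summaries
against SSIM at α = 0.05 (CSV), a complete JSON archive with full parameter
provenance, and scatter plots. In the validity study (ten CTDI_vol levels
from 2.7 to 74.2 mGy against an 89.1 mGy reference, and Gaussian blur
kernels 3–21 with σ(k) = 0.3·(k/2 − 1) + 0.8), `r(PI, SSIM)` is below −0.9
for every backend. In the robustness study (translations of 2–40 px,
rotations of 1–45°, scalings of 0.75–1.25×), PI stays within a few percent
of its operating level while SSIM falls by more than 25%.

The same functionality is available as a library:

```python
from kpiqa import (PhantomSpec, generate_head_phantom, to_eight_bit,
                   BRAIN_WINDOW, detect_and_describe, brute_force_match,
                   proposed_index)

img = to_eight_bit(generate_head_phantom(PhantomSpec(seed=1)), BRAIN_WINDOW)
_, desc = detect_and_describe(img, "akaze")
print(proposed_index(brute_force_match(desc, desc)).value)  # 0.0
```

`read_image` accepts single-frame DICOM (rescale slope/intercept applied,
so CT pixels are in HU) and 8/16-bit grayscale PNG/TIFF; CT images are
windowed to 8 bits with a conventional brain window (center 40 HU, width
80 HU) before feature detection.

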