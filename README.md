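# petspx

Fast tumor segmentation for 2-D PET slices using superpixels, an
eigen-analysis of superpixel statistics, and an exact binary k-means on a
distance-from-average saliency score.

PET hot spots — regions of elevated radiotracer uptake — are the imaging
signature of tumor tissue, but clustering raw pixels is slow and noisy. This
pipeline instead works at superpixel granularity: a few hundred coherent
regions summarize a slice of tens of thousands of pixels, and the tumor
regions are exactly the ones whose internal intensity statistics deviate
sharply from the slice-wide average. The package is aimed at medical-image
analysis work that needs a fast, unsupervised, fully deterministic baseline
segmenter, and ships a synthetic PET-phantom generator with pixel-level
ground truth so every stage can be validated quantitatively.

## Method

Given a grayscale slice `I` with intensities in [0, 255]:

1. **Contrast stretch.** Piecewise linear enhancement: `I_enh = I` for
   `I < 110`, and `I_enh = 55/145 · (I − 110) + 200` for `I ≥ 110`, mapping
   the hot band [110, 255] onto [200, 255] (so 110 → 200 and 255 → 255).
2. **Superpixels.** SLIC over-segmentation into N regions (localized
   k-means in joint intensity–position space; default target 700,
   compactness 10 on the 0–255 intensity scale).
3. **Size equalization.** Each superpixel's raster-order intensity
   sequence is padded with its own last value or truncated to the mean
   length `M = round(Σ nᵢ / N)`, giving the M×N superpixel matrix `S`.
4. **Eigen-analysis.** With the average superpixel `S_a = (1/N) Σ Sᵢ` and
   centered matrix `Y_c = S − S_a·1ᵀ`, the covariance
   `C_s = Y_c Y_cᵀ / (N+1)` is eigendecomposed (`C_s = P Λ Pᵀ`, computed by
   SVD of `Y_c`); the smallest K with
   `Σ_{k≤K} λ_k / Σ λ_k ≥ 0.95` defines the principal-component
   coordinate system.
5. **Saliency.** Each superpixel is projected (`Y_proj = P_Kᵀ Y_c`) and
   scored by its L1 distance from the average superpixel,
   `D_i = Σ_k |Y_proj[k, i]|`.
6. **Recognition.** The distances are split into tumor / normal by binary
   k-means, `argmin Σᵢ Σ_{x∈cᵢ} (x − μᵢ)²`, solved *exactly* by threshold
   enumeration of the sorted 1-D values; the higher-centroid cluster is
   tumor.
7. **Delineation.** Tumor superpixels become a pixel mask, cleaned by
   morphological opening (disk radius 1), traced into pixel-edge contours,
   and rendered as a per-pixel distance heatmap.

Because the slice is reduced to N superpixels and then to K ≪ M principal
components before any clustering, the whole pipeline runs in well under a
second on typical slice sizes.

## Worked example

`examples/segment_phantom.py` generates a 256×256 phantom (background 40,
two organ blobs at level 100, three tumor disks at 230, PSF blur σ 1.5,
Gaussian noise σ 5), segments it, and scores the mask against the known
truth:

```
phantom: 256x256, 3 tumor(s), 2 organ blob(s)
N = 620 superpixels of mean length M = 106 pixels
K = 7 principal components carry 95.2% of the superpixel variance
tumor cluster: 8 superpixels, 1412 pixels after morphological cleanup
against ground truth: Dice = 0.886, detected lesions = 100% of 3
wrote: contour_overlay.png heatmap.png heatmap_scale.txt mask.png report.json
```

N, M and K are the size accounting of steps 2–4: clustering operated on a
620-dimensional distance vector instead of the 65 536 pixels of the slice.
Dice is pixel overlap with the truth (1.0 = perfect); the detected-lesion
fraction counts true lesions touched by the mask. The other examples
(`contrast_stretch.py`, `pca_saliency.py`, `exact_kmeans.py`) walk through
the individual stages the same way.

The same pipeline is available from the shell:

```bash
petspx-phantom --seed 4 --out slice.png --truth truth.png
petspx-seg run --input slice.png --out results/
petspx-seg eval --pred results/mask.png --truth truth.png
```

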