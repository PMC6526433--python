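"""Eigen-analysis of superpixels: why tumor superpixels stand out.

Builds a clean phantom, extracts superpixels, equalizes them into the
M x N matrix, fits the eigen-model and prints the variance spectrum and
the L1 distances of the most salient superpixels. Superpixels covering
the hot spot sit far from the average superpixel in PC coordinates.
"""

import numpy as np

from petspx import (
    PhantomSpec,
    enhance_image,
    equalize_superpixels,
    extract_superpixels,
    fit_pca,
    generate_phantom,
    l1_distances,
    project,
)

spec = PhantomSpec(
    height=128, width=128,
    tumors=(((64.0, 64.0), 10.0, 230.0),),
    background_ripple=6.0, seed=2,
)
img, truth = generate_phantom(spec)

enhanced = enhance_image(img)
part = extract_superpixels(enhanced, target_n=170)
S = equalize_superpixels(part, enhanced)
model = fit_pca(S)

print(f"superpixel matrix: M = {S.M} x N = {S.N}")
fracs = model.eigenvalues[:4] / model.total_variance
print("top eigenvalue fractions:", np.round(fracs, 3))
print(f"K = {model.K} components reach {model.variance_fraction:.1%} variance")

D = l1_distances(project(S, model))
top = np.argsort(D)[::-1][:5]
print("most salient superpixels (label: distance, tumor overlap):")
for j in top:
    pix = part.pixel_lists[j]
    overlap = truth[pix[:, 0], pix[:, 1]].mean()
    print(f"  {j:3d}: D = {D[j]:8.1f}, {overlap:.0%} tumor pixels")
print(f"median distance over all superpixels: {np.median(D):.1f}")
# The hot-spot superpixels dominate the distance ranking by an order of
# magnitude — that separation is what the binary k-means step exploits.
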