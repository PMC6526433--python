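"""The piecewise linear contrast stretch and its anchor points.

Intensities below the threshold (110) pass through unchanged; the band
[110, 255] is compressed linearly onto [200, 255], so everything with
tumor-like uptake is pushed into the brightest band. The constants make
110 -> 200 and 255 -> 255 exactly.
"""

import numpy as np

from petspx import EnhancementParams, GrayImage, enhance_image

params = EnhancementParams()  # threshold 110, base 200, slope 55/145
print(f"threshold={params.threshold}, out_base={params.out_base}, "
      f"slope={params.slope:.4f} ({55}/{145})")

for value in [0, 40, 100, 109, 110, 150, 200, 230, 255]:
    img = GrayImage(np.full((16, 16), float(value)))
    out = enhance_image(img, params).pixels[0, 0]
    print(f"  I = {value:3d}  ->  I_enh = {out:7.3f}")
# Note the jump at the threshold: 109 stays 109 while 110 maps to 200 —
# that gap is what separates hot uptake from background after stretching.
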