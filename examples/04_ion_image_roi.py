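"""Single-ion imaging of a synthetic two-compartment tissue field.

Builds a 20x20 pixel grid in which xanthine (m/z 133.0156) dominates the
left half and indole (m/z 116.0506) the right half, extracts both ion
images, and compares ROI means across compartments.
"""

import numpy as np

import orbimet as om
from orbimet.imaging import RoiSpec, build_ion_image, overlay_channels, roi_mean

rng = np.random.default_rng(0)
XAN, IND = 133.01558, 116.05057

grid = []
for y in range(20):
    row = []
    for x in range(20):
        xan = rng.gamma(4.0, 25.0) if x < 10 else rng.gamma(1.5, 4.0)
        ind = rng.gamma(1.5, 4.0) if x < 10 else rng.gamma(4.0, 25.0)
        row.append((np.array([IND, XAN]), np.array([ind, xan])))
    grid.append(row)

img_xan = build_ion_image(grid, XAN, tolerance_ppm=5.0, pixel_size_um=3.0)
img_ind = build_ion_image(grid, IND, tolerance_ppm=5.0, pixel_size_um=3.0)

left = RoiSpec((0, 5), (10, 10), "left")    # 30x30 um at 3 um pixels
right = RoiSpec((10, 5), (10, 10), "right")
for img, name in ((img_xan, "xanthine"), (img_ind, "indole")):
    print(
        f"{name:<9} ROI means: left={roi_mean(img, left):8.2f}  "
        f"right={roi_mean(img, right):8.2f}"
    )

composite = overlay_channels(img_xan, img_ind)
print(f"overlay composite shape {composite.shape}, per-channel max = "
      f"{composite[..., 0].max():.1f}, {composite[..., 1].max():.1f}")
# The two ions show complementary spatial patterns: each compartment's ROI
# mean is an order of magnitude higher for its dominant ion.
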