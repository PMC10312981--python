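"""Adaptive tumor/stroma segmentation and region-resolved cell densities.

Builds a two-compartment image (bright tumor blob inside a leukocyte-filled
tissue disk), recovers the region masks with four-class adaptive
thresholding, assigns scattered cells to regions, and reports densities.
"""

import numpy as np
import pandas as pd

from cisa import (
    CellTable,
    assign_region,
    generate_two_compartment_image,
    region_density,
    segment_regions,
)

image, truth = generate_two_compartment_image(seed=5)
regions = segment_regions(image, "Melanoma", "CD45")

iou_t = (regions.tumor & truth.tumor).sum() / (regions.tumor | truth.tumor).sum()
iou_s = (regions.stroma & truth.stroma).sum() / (regions.stroma | truth.stroma).sum()
print(f"tumor mask IoU vs truth:  {iou_t:.3f}")
print(f"stroma mask IoU vs truth: {iou_s:.3f}")

rng = np.random.default_rng(5)
n = 300
df = pd.DataFrame(
    {
        "cell_id": np.arange(1, n + 1),
        "x_um": rng.uniform(0, 400, n),
        "y_um": rng.uniform(0, 400, n),
        "types": [frozenset({"T-cell"})] * n,
    }
)
table = assign_region(CellTable(df), regions, pixel_size_um=1.0)
counts = table.df["region"].value_counts()
print("cells by region:", {k: int(v) for k, v in counts.items()})

dens = region_density(table, regions, "T-cell", pixel_size_um=1.0)
print(f"T-cell density: intratumor = {dens['intratumor']:.0f} /mm^2, "
      f"stroma = {dens['stroma']:.0f} /mm^2")
# IoU near 1 shows the adaptive four-class threshold recovers the generating
# compartments; densities are counts over recovered mask areas.
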