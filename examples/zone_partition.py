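"""Concentric-zone partition of a single disk organoid vs the analytic areas.

A disk of radius 100 um at 0.5 um/px is partitioned with 25 um margins into
the interior (zone 1), the epithelial barrier band (zone 2) and two
extracellular margins (zones 3, 4).  Because the object is a perfect circle,
every zone area has a closed-form annulus value to compare against.
"""

import math

import numpy as np

import orgzone as oz
from orgzone.objects import OrganoidObject

radius_um, px = 100.0, 0.5
n = 701
yy, xx = np.mgrid[0:n, 0:n]
c = (n - 1) / 2
mask = (yy - c) ** 2 + (xx - c) ** 2 <= (radius_um / px) ** 2
obj = OrganoidObject(label=1, mask=mask, origin=(0, 0), field_shape=(n, n),
                     pixel_size_um=px)

zoneset = oz.build_zones(obj, margin_um=25.0)
areas = zoneset.areas_um2()
analytic = {1: math.pi * 75 ** 2, 2: math.pi * (100 ** 2 - 75 ** 2),
            3: math.pi * (125 ** 2 - 100 ** 2), 4: math.pi * (150 ** 2 - 125 ** 2)}

print("zone   measured um2   analytic um2   rel. error")
for z in (1, 2, 3, 4):
    err = abs(areas[z] - analytic[z]) / analytic[z]
    print(f"  {z}     {areas[z]:9.0f}      {analytic[z]:9.0f}      {err:6.2%}")
n_roi = int(mask.sum())
n_z12 = int(zoneset.zones[1].sum() + zoneset.zones[2].sum())
print(f"zone1+zone2 pixels = {n_z12}, ROI pixels = {n_roi} (exact partition)")
print("sub-percent errors come only from rasterizing the circle at 0.5 um/px")
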