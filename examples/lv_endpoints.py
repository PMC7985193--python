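"""Method-of-disks LV volumetry on an analytic contour.

Builds an exact half-ellipse endocardial contour (base-to-apex length
8 mm, diameter 4 mm), cuts it into twenty disks perpendicular to the
long axis, and compares the summed disk volume with the closed-form
half-ellipsoid volume pi*L*D^2/6.
"""

import numpy as np

from murineecho.cardiac_params import (
    bmode_measures,
    contour_axis_and_disks,
    disk_volume,
)
from murineecho.types import LvContour, Phase


def half_ellipse(L, D, n_arc=512):
    phi = np.linspace(np.pi / 2, -np.pi / 2, n_arc)
    verts = np.column_stack([2 + L * np.cos(phi), 5 + D / 2 * np.sin(phi)])
    return LvContour(vertices=verts, basal_indices=(0, n_arc - 1), phase=Phase.ED)


L, D = 8.0, 4.0
contour = half_ellipse(L, D)
analytic = np.pi * L * D**2 / 6

print(f"{'n_disks':>8s} {'volume uL':>10s} {'error %':>8s}")
for n in (5, 10, 20, 40, 80):
    v = disk_volume(contour_axis_and_disks(contour, n))
    print(f"{n:8d} {v:10.3f} {100 * abs(v - analytic) / analytic:8.3f}")
print(f"analytic pi*L*D^2/6 = {analytic:.2f} uL")

es = half_ellipse(7.4, 2.9)
es.phase = Phase.ES
measures = bmode_measures(contour, es, heart_rate=450.0)
print("\nfunctional endpoints, ED (8.0 x 4.0) vs ES (7.4 x 2.9) mm:")
for key in ("EDV", "ESV", "EF", "FS", "FAC", "SV", "CO"):
    print(f"  {key:4s} {measures.values[key]:8.2f}")
print(
    "\nThe disk sum converges to the analytic volume as the disk count "
    "grows; twenty disks are already within half a percent."
)
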