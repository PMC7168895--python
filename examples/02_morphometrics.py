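"""Measure the five morphological variables on a synthetic aneurysm dome.

Builds a supra-hemispherical spherical-cap dome (taller than wide at the
neck), triangulates it, and measures height, width, ostium diameter,
ostium area and surface area -- the variables used to compare small and
large aneurysms.  Analytic cap values are printed alongside.
"""

import numpy as np

from hemoflow import ShapeParams, classify_size, make_dome_mesh, measure_morphometrics

shape = ShapeParams(dome_radius=2.0, neck_offset=-1.0)  # mm; neck below the equator
mesh, neck = make_dome_mesh(shape, resolution=0.1)
m = measure_morphometrics(mesh, neck)

print(f"mesh: {len(mesh.vertices)} vertices, {len(mesh.triangles)} triangles")
print(f"height          H = {m.height:.3f} mm   (analytic {shape.height:.3f})")
print(f"width           W = {m.width:.3f} mm   (analytic {shape.width:.3f})")
print(f"ostium diameter O = {m.ostium_diameter:.3f} mm   (analytic {shape.ostium_diameter:.3f})")
print(f"ostium area       = {m.ostium_area:.3f} mm^2 (analytic {np.pi*(shape.ostium_diameter/2)**2:.3f})")
print(f"surface area      = {m.surface_area:.3f} mm^2 (analytic {2*np.pi*shape.dome_radius*shape.height:.3f})")
print(f"size class        = {classify_size(m.height)}  (5 mm height cutoff)")
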