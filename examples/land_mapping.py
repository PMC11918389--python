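"""Map vegetation and salinity on a synthetic multiband scene.

Builds a 40×40 reflectance scene with vegetation and saline patches,
computes NDVI/NDSI, segments each index with K-means and accounts the
healthy-vegetation area.
"""

from agriflow.raster_land import (
    compute_ndsi,
    compute_ndvi,
    healthy_mask,
    kmeans_segment,
    salinity_classes,
    vegetation_area,
)
from agriflow.soilbed_sim import generate_scene

stack = generate_scene(shape=(40, 40), patches=3, seed=0)
ndvi = compute_ndvi(stack)
ndsi = compute_ndsi(stack)

veg = kmeans_segment(ndvi, k=3, seed=0)
mask = healthy_mask(veg)
area = vegetation_area(mask, stack.pixel_size)
sal = salinity_classes(ndsi, seed=0)

print(f"NDVI range on valid pixels: {ndvi.values[ndvi.valid_mask].min():+.3f} "
      f"to {ndvi.values[ndvi.valid_mask].max():+.3f}")
print(f"vegetation centroids (desc): {[round(c, 3) for c in veg.centroids]}")
print(f"healthy vegetation area: {area:,.0f} m^2 = {area / 1e4:.1f} ha")
print(f"salinity centroids (desc):  {[round(c, 3) for c in sal.centroids]}")
# The top NDVI cluster is the 'healthy' class; at 30 m pixels each counted
# pixel contributes 900 m^2.  High NDSI centroids flag salt-affected ground.
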