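"""Build a single virtual folium and a small region around it.

A folium is a tube swept along a centerline; Purkinje-cell somata sit in a
jittered monolayer on a cylindrical surface inside it.  Everything is
analytic, so the region carries an exact ground-truth density.
"""

import numpy as np

from pcstereo import FoliumSpec, RegionSpec, assemble_region, generate_folium

# a gently curved folium, 20 mm long, 0.8 mm radius
x = np.linspace(0, 20_000, 80)
centerline = np.column_stack([x, 600 * np.sin(x / 4000.0), np.zeros_like(x)])
spec = FoliumSpec(
    centerline_control_points=tuple(map(tuple, centerline)),
    folium_radius=800.0,       # um, white matter core to pial surface
    pc_layer_offset=250.0,     # monolayer sits 250 um below the surface
    pc_layer_jitter_sd=40.0,   # radial scatter of somata about the layer
)
folium = generate_folium(spec)
print(f"folium length        {folium.length / 1000:.2f} mm")
print(f"folium volume        {folium.volume_um3 / 1e9:.3f} mm^3")
print(f"monolayer area       {folium.monolayer_area_um2 / 1e6:.3f} mm^2")

region = assemble_region(
    RegionSpec(
        name="crusI",
        folium_specs=(spec,),
        bounding_box=((-1200, -2000, -1200), (21_200, 2000, 1200)),
        target_surface_density=300.0,  # PC per mm^2 of monolayer
        rng_seed=1,
    )
)
print(f"somata placed        {len(region.somata)}")
print(f"reference volume     {region.volume_mm3:.1f} mm^3")
print(f"true density         {region.true_density:.1f} PC/mm^3")
# Expected count = surface density x monolayer area; the density above is
# that count spread over the boxed reference volume (tissue + white matter).
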