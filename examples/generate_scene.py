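"""Generate a synthetic town scene and inspect its vegetation structure.

Builds a 'planned_green' archetype scene (designed greenspace: large
contiguous greens and tree stands), stratifies it, and prints the
realized cover per layer against the configured targets.
"""

from canopyconn import Stratum, archetype_params, generate_scene, stratify_scene

config = archetype_params("planned_green", width_px=128, height_px=128, seed=42)
pair, canopy = generate_scene(config)
masks = stratify_scene(pair, canopy)

print(f"scene: {config.width_px}x{config.height_px} px at {config.pixel_size_m} m, "
      f"{canopy.n_levels} voxel levels of {canopy.voxel_height_m} m")
for layer in Stratum:
    realized = masks[layer].values.mean()
    target = config.target_cover.get(layer.value, None)
    target_txt = f" (target {target:.2f})" if target is not None else ""
    print(f"  {layer.value:8s} cover {realized:.3f}{target_txt}")

understorey = (masks[Stratum.GRASS].values & masks[Stratum.TREE].values).mean()
print(f"  grass-under-tree understorey: {understorey:.3f} of the scene")
# The 2D (green2d) cover exceeds every stratum because NDVI merges all
# vertical layers into one flat footprint.
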