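"""Remove color-rich background before edge detection.

Dew is nearly achromatic, so thresholding HSV saturation at alpha = 50
separates analysable pixels from colored interference (light patches,
reflections); a 25x25 closing regularises the mask and a 25x25 erosion
pulls it off region boundaries.
"""

from dewquant import SceneConfig, SegmentationConfig, generate_scene, segment_background

config = SceneConfig(
    image_width=256, image_height=256, n_droplets=4,
    droplet_diameter_range=(24, 48), background_kind="glass",
    n_noise_patches=3, noise_patch_saturation_min=255,
    border_margin_px=14, seed=7,
)
image, gt = generate_scene(config)

masked, analysis_mask = segment_background(image, SegmentationConfig())

patch = (gt.noise_patch_mask > 0) & (gt.droplet_label_map == 0)
excluded = (analysis_mask[patch] == 0).mean()
print(f"analysis region: {100 * analysis_mask.mean():.1f}% of the frame")
print(f"planted interference pixels: {patch.sum()}")
print(f"fraction of interference excluded: {100 * excluded:.1f}%")
droplet_cover = analysis_mask[gt.droplet_label_map > 0].mean()
print(f"droplet pixels retained for analysis: {100 * droplet_cover:.1f}%")
# High-saturation patches are cut away (so they cannot masquerade as
# droplet edges later) while the droplets themselves stay analysable.
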