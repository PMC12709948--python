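"""Generate synthetic paired field scenes and inspect what they contain.

Each scene is a class map (vegetation / soil / plastic film) rendered into
an RGB image and a 4-band spectral image (green, red, red-edge, NIR), plus
the ground-truth vegetation mask. "Strong noise" — the per-band spatial
misalignment a multi-lens UAV sensor leaves behind — can be injected into
the spectral bands.
"""

import numpy as np

import vegsr

spec = vegsr.SceneSpec(height=64, width=64, layout="row_crop",
                       target_veg_fraction=0.3, film_fraction=0.1, seed=7)
scene = vegsr.generate_scene(spec)

print(f"scene {spec.height}x{spec.width}, layout={spec.layout}")
print(f"  vegetation fraction: target {spec.target_veg_fraction:.2f}, "
      f"realized {scene.mask.vegetation_fraction:.3f}")
print(f"  RGB range [{scene.rgb.pixels.min():.3f}, {scene.rgb.pixels.max():.3f}], "
      f"spectral bands {scene.spectral_clean.band_names}")

# mean reflectance per band over vegetation vs background: the red-edge rise
ms = scene.spectral_clean.pixels
veg = scene.mask.labels == 1
print("  mean reflectance  green   red     red_edge nir")
print("    vegetation:    " + "  ".join(f"{ms[veg, b].mean():.3f}" for b in range(4)))
print("    background:    " + "  ".join(f"{ms[~veg, b].mean():.3f}" for b in range(4)))

# inject band misalignment: the spectral observation shifts, the mask does not
noisy = vegsr.inject_strong_noise(scene, magnitude_px=3.0, seed=1)
print("  injected per-band (dy, dx) offsets:")
for name, off in zip(scene.spectral_clean.band_names, noisy.band_offsets):
    print(f"    {name:9s} ({off[0]:+.2f}, {off[1]:+.2f}) px")
shift_rms = np.sqrt(np.mean((noisy.spectral_noisy.pixels - ms) ** 2))
print(f"  RMS change of the spectral raster after misalignment: {shift_rms:.4f}")
print("The mask stays aligned with the RGB input - only the spectral "
      "training target is displaced, which is what confuses late training.")
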