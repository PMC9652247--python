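"""Compose a compound screenshot and crop the four dataset variants.

The acquisition workstation exports one screenshot holding the B-mode
panel and the SWE panel side by side on a cluttered bezel.  The pipeline
extracts four images per screenshot — US, SWE, RE-US, RE-SWE — and
resizes each to (224, 224, 3) with anti-aliased bilinear interpolation.
"""

import numpy as np

from swefuse import (PhantomParams, compose_screenshot, crop_variants,
                     generate_phantom_pair, resize_image, ResizeSpec)

pair = generate_phantom_pair(PhantomParams(), label=1, seed=7)
shot = compose_screenshot(pair, layout_seed=3)
print(f"screenshot raster {shot.raster.shape}, US panel {shot.us_panel_box}, "
      f"SWE panel {shot.swe_panel_box}")

crops = crop_variants(shot)
for variant, img in crops.items():
    resized = resize_image(img, ResizeSpec())
    print(f"{variant.value:6s}: crop {img.shape[:2]} -> {resized.shape}")

# Cropping is pure slicing: the US panel reproduces the source image bitwise.
gray3 = np.repeat(pair.us_image[:, :, None], 3, axis=2)
print("US crop bitwise equals source:",
      np.array_equal(crops[list(crops)[0]], gray3))
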