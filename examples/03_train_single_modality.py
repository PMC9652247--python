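"""Train the classifier on one dataset variant at reduced scale.

Uses the desk-scale configuration (64x64 input, 8 epochs, lr 1e-3); the
architecture is the same four-convolution stack that runs at 224x224
with the full protocol (100 epochs, lr 1e-4).
"""

import numpy as np

from swefuse import (CropVariant, build_dcnn, generate_dataset, train_model,
                     variant_stack)
from swefuse.experiments import reduced_scale_config, scaled_phantom_params
from swefuse.preprocess import ResizeSpec

params = scaled_phantom_params(80)
samples, manifest = generate_dataset(params, 80, seed=0)
spec = ResizeSpec(target_height=64, target_width=64)
x, y = variant_stack(samples, CropVariant.SWE, spec)

rng = np.random.default_rng(0)
order = rng.permutation(len(x))
test, val, train = order[:12], order[12:24], order[24:]

config = reduced_scale_config()
model = build_dcnn(config, headless=False, seed=0)
train_model(model, (x[train], y[train]), (x[val], y[val]), seed=0)

probs = model.predict(x[test])
acc = float(np.mean((probs >= 0.5) == y[test]))
print(model.history[["epoch", "loss", "val_loss", "val_accuracy"]].round(3).to_string(index=False))
print(f"held-out accuracy on {len(test)} samples: {acc:.2f}")
# Validation loss should fall over epochs; the kept weights are those of
# the best-validation epoch.
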