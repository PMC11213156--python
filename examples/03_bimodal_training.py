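"""Train a bi-modal (sMRI + fMRI) classifier on a synthetic cohort.

Step 1a of the two-step scheme: a CN-vs-AD classifier over two encoder
channels, stratified cross-validation with weighted cross-entropy, best
fold retained by validation accuracy. The retained encoders later supply
the latent vectors on which the Cycle-GANs are trained.
"""

import numpy as np

from neurofuse.pipeline import evaluate, extract_latents, train_bimodal
from neurofuse.presets import desk_recovery_simspec, desk_scale_config
from neurofuse.simulate import simulate_inputs

spec = desk_recovery_simspec(seed=1, n_per_class={"CN": 30, "AD": 30})
config = desk_scale_config(seed=1, epochs_bimodal=25, n_folds=2)
inputs, _ = simulate_inputs(spec)

result = train_bimodal("smri-fmri", inputs, config, seed=1)
print(f"per-fold validation accuracy: {[round(a, 3) for a in result.fold_accuracy]}")
print(f"best fold: {result.best_fold}")

cnad = [mi for mi in inputs if mi.class_label in ("CN", "AD")]
ids, latents = extract_latents(result.model, cnad, "smri")
print(f"extracted sMRI latents: {latents.shape} for {len(ids)} subjects")
print(f"training-set accuracy of the retained model: {evaluate(result.model, cnad).acc:.3f}")
print("  -> the retained encoders supply the latent vectors for Cycle-GAN training")
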