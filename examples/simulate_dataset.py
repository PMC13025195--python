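"""Generate a dual-view dataset with known class structure.

Draws four emotion classes from a latent simplex, maps them into a
gaze-feature view and a pupil-feature view, and prints the class balance
and the cross-view canonical correlation the construction induces.
"""

import numpy as np

from ictd import SyntheticSpec, generate_dual_modality, linear_cca_oracle

spec = SyntheticSpec(n_classes=4, n_subjects=10, trials_per_subject=100,
                     class_separation=8.0, noise_sd=(0.5, 0.5), seed=0)
ds = generate_dual_modality(spec)

print(f"trials: {len(ds)}  gaze view: {ds.gaze_view.shape[1]} features  "
      f"pupil view: {ds.pupil_view.shape[1]} features")
print("class counts:", np.bincount(ds.labels))

corr, _ = linear_cca_oracle(ds.gaze_view, ds.pupil_view, k=3)
print("top-3 canonical correlations between the views:", corr.round(3))
# near-1 leading correlations: both views are driven by the same latent
# class structure, which is exactly what the alignment loss exploits
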