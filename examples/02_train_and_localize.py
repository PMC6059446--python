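"""Train a small two-phase model and localize landmarks on a held-out phantom.

Uses a reduced cohort and tree budget so the script runs in about a
minute; the full study configuration lives in
``colonialwalk.pipeline.desk_scale_config`` (30 training volumes).
"""

import numpy as np

import colonialwalk as cw
from colonialwalk.pipeline import desk_scale_config

train = cw.generate_dataset(6, cw.DatasetConfig(rotation_max_deg=8.0), master_seed=100)
test = cw.generate_dataset(2, cw.DatasetConfig(rotation_max_deg=8.0), master_seed=200)

print("training the global tree and the eight local trees (6 phantoms)...")
model = cw.train_two_phase(train, desk_scale_config(), seed=0)
print(f"global tree: {model.global_tree.n_leaves} leaves, "
      f"depth {model.global_tree.meta['depth']}")

for i, (vol, lm) in enumerate(test):
    pred, diag = cw.localize(model, vol, seed=i)
    phase1_err = np.linalg.norm(diag["x_g_prime"] - lm.global_point)
    print(f"\nphantom {i}: phase-1 valve point error {phase1_err:.2f} voxels "
          f"(tolerated up to 30: it only seeds phase 2)")
    for name in cw.LANDMARK_NAMES:
        err = cw.localization_error(pred[name], lm[name], vol.spacing)
        print(f"  {name:5s} error {err:5.2f} mm")
    errs = [cw.localization_error(pred[n], lm[n], vol.spacing) for n in cw.LANDMARK_NAMES]
    print(f"  overall mean {np.mean(errs):.2f} mm — each landmark found by a "
          f"200-walker colony, keeping the minimum-variance walker's mean")
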