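"""Why the minimum-variance walker is trusted: the variance-error relation.

Builds a hand-made direction tree with a deliberately misleading region,
runs a colony, and tabulates each walker's walk variance against its
localization error: misguided walks wander (high variance, high error),
converged walks hover in a dense cloud (low variance, low error).
"""

import numpy as np

import colonialwalk as cw
from colonialwalk.tree import LeafNode, SplitNode

# Volume whose intensity encodes position: data[x] = x + 1, so the feature
# with offsets (+1,0,0)/(-1,0,0) equals 2/(x+1) and thresholds select x.
nx = 64
data = np.broadcast_to(
    (np.arange(nx, dtype=np.float32) + 1.0)[:, None, None], (nx, 8, 8)
).copy()
vol = cw.Volume(data)

target_x = 40


def split_at(x_cut, left, right):
    return SplitNode(cw.FeatureParams((1, 0, 0), (-1, 0, 0)), 2.0 / (x_cut + 1.0), left, right)


def leaf(*dirs):
    d = np.asarray(dirs, dtype=float)
    return LeafNode(np.full(len(d), 1.0 / len(d)), d)


# x > 39.5: aim back; 24..39: aim forward; 16..23: a misleading 50/50
# region (an "unknown" area, e.g. heavy calcification); x < 16: forward.
tree = cw.RegressionTree([
    split_at(39.5, 1, 2),
    leaf((-1, 0, 0)),
    split_at(23.5, 3, 4),
    leaf((1, 0, 0)),
    split_at(15.5, 5, 6),
    leaf((1, 0, 0), (-1, 0, 0)),
    leaf((1, 0, 0)),
])

rng = np.random.default_rng(0)
init = cw.sample_init_points(vol, "whole-volume", 30, rng)
res = cw.colonial_walk(tree, vol, init, cw.WalkConfig(30, 2.0, 48, seed=0))

table, rho = cw.variance_error_table(res, (target_x, 4, 4), vol.spacing)
print(table.sort_values("variance").head(10).to_string(index=False))
errs = table.error_mm.to_numpy()
print(f"\nselected walker {res.selected}: error {errs[res.selected]:.2f} mm")
print(f"colony mean error {errs.mean():.2f} mm, median {np.median(errs):.2f} mm")
print(f"Spearman rank correlation (log variance vs error): {rho:.2f}")
print("-> the minimum-variance walker avoids the misled, wandering walks")
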