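"""TAVI sizing metrics from landmark sets: annulus diameter, ostia height.

Uses exact phantom ground truth perturbed by a known amount, showing how
landmark error propagates into the clinically used measurements.
"""

import numpy as np

import colonialwalk as cw

vol, lm = cw.generate_phantom(cw.PhantomConfig(seed=4, rotation=(5.0, -3.0)))
spacing = np.asarray(vol.spacing)


def mm(p):
    return np.asarray(p) * spacing


truth_ann = cw.annulus_from_hinges(mm(lm["h_r"]), mm(lm["h_n"]), mm(lm["h_l"]))
truth_ostia = cw.ostia_plane_distance(truth_ann, mm(lm["o_r"]), mm(lm["o_l"]))
print(f"ground truth: annulus diameter {truth_ann.diameter:.2f} mm, "
      f"annulus-to-ostia distance {truth_ostia:.2f} mm")

rng = np.random.default_rng(0)
for sigma in (0.5, 1.0, 2.0):
    pred = {n: lm[n] + rng.normal(0, sigma, 3) for n in cw.LANDMARK_NAMES}
    ann = cw.annulus_from_hinges(mm(pred["h_r"]), mm(pred["h_n"]), mm(pred["h_l"]))
    ostia = cw.ostia_plane_distance(ann, mm(pred["o_r"]), mm(pred["o_l"]))
    cosd = cw.plane_normal_cosine_distance(ann.normal, truth_ann.normal)
    print(f"landmark noise sigma={sigma:.1f} voxels -> "
          f"diameter error {abs(ann.diameter - truth_ann.diameter):.2f} mm, "
          f"ostia-distance error {abs(ostia - truth_ostia):.2f} mm, "
          f"plane cosine distance {cosd:.4f}")
print("-> sizing errors grow roughly in proportion to landmark error, "
      "so millimetre-level localization keeps sizing clinically usable")
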