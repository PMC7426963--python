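"""Hinge-angle parameter recovery across the observed range.

For each applied hinge rotation (the published couples span 2-37 degrees)
the generator builds ten noisy couples (coordinate noise 0.2 Å) and the
geometry module re-measures the conserved-anchor C-S-C / C-R-C angles;
the mean recovered change should match the applied rotation.
"""

import numpy as np

import fabcompare as fc

print(f"{'applied':>8} {'recovered mean':>15} {'sd':>6}")
for applied in (5.0, 15.0, 25.0, 37.0):
    recovered = []
    for seed in range(10):
        spec = fc.SyntheticSpec(
            hinge_angle_heavy=-applied, hinge_angle_light=applied,
            noise_sigma=0.2, seed=seed,
        )
        couple = fc.generate_couple(spec)
        anchors = [fc.find_anchors(c, fc.assign_regions(c)) for c in couple[:4]]
        change = fc.angle_change(
            fc.measure_angles(anchors[0], anchors[1]),
            fc.measure_angles(anchors[2], anchors[3]),
        )
        recovered.append(change.average_abs_change)
    print(f"{applied:8.1f} {np.mean(recovered):15.2f} {np.std(recovered):6.2f}")

print("\nEach row: mean +- sd of the average |hinge change| over ten "
      "independent noisy couples; agreement within a fraction of a degree "
      "shows the anchor-angle measurement recovers the true domain "
      "reorientation.")
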