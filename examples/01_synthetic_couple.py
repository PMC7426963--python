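"""Generate a synthetic free/bound Fab couple and run the full analysis.

Builds a couple with a strong hinge (heavy chain closes by 25 degrees,
light chain opens by 25) plus a 2 Å C_Loop1 displacement — the signature
of a B1-class binding change — writes it as PDB files, analyses it, and
prints the per-couple summary.
"""

from pathlib import Path

import fabcompare as fc

out = Path("scratch/example_couple")
spec = fc.spec_b1(seed=0)
couple = fc.generate_couple(spec)
paths = fc.write_couple_pdb(couple, out, prefix="b1")
print(f"wrote {paths['free']}, {paths['bound']}")

report = fc.analyze_prepared_couple(
    "B1-demo", couple.free_heavy, couple.free_light,
    couple.bound_heavy, couple.bound_light, output_dir=out,
)

change = report.angle_change
print(f"heavy hinge change : {change.delta_heavy:+.2f} deg (applied -25)")
print(f"light hinge change : {change.delta_light:+.2f} deg (applied +25)")
print(f"average |change|   : {change.average_abs_change:.2f} deg")
print(f"C_Loop1 peak       : {report.c_loop1_signal_heavy.peak:.2f} A "
      f"(applied 2.0), ratio {report.c_loop1_signal_heavy.ratio:.1f}")
print(f"class              : {report.class_label}")
print("\nRMSD under the whole-Fab overlap (A):")
print(report.rmsd_table.round(2))
print("\nLarge entire/constant cells with small variable cells show the "
      "hinge: domains stay rigid but reorient, so the class is B1.")
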