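"""Whole-chain versus per-domain RMSF and the C_Loop1 allosteric signal.

A B2-style couple (no hinge, 2 Å C_Loop1 displacement) shows the point of
per-domain overlap: under the whole-chain fit and under the CH1-domain fit
alike, the profile peaks inside C_Loop1, and the peak-to-baseline ratio
quantifies how localized the change is.
"""

import fabcompare as fc

couple = fc.generate_couple(fc.spec_b2(seed=1))
free, bound = couple.free_heavy, couple.bound_heavy

whole = fc.rmsf_profile(free, bound, scope_label="whole-chain")
ch1 = fc.rmsf_profile(free, bound, scope_span=(114, 218), scope_label="CH1")

loops = fc.DEFAULT_C_LOOP_TABLE["heavy"]
signal = fc.c_loop1_signal(ch1, loops)

print("heavy chain, C_Loop1 span", loops["C_Loop1"])
for label, prof in (("whole-chain overlap", whole), ("CH1-domain overlap", ch1)):
    stats = fc.region_summary(prof, loops["C_Loop1"])
    print(f"  {label:<20} peak {stats['max']:.2f} A at residue {stats['argmax']}")
print(f"CH1-scope signal: peak {signal.peak:.2f} A, baseline "
      f"{signal.baseline:.2f} A, ratio {signal.ratio:.1f}")
print("\nA peak near the applied 2.0 A with a ratio well above 2 marks a "
      "deviation confined to C_Loop1 — the B2 signature read as an "
      "allosteric signal toward the Fc region.")
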