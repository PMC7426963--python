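# fabcompare

Compare the **free** and **antigen-bound** crystal structures of the same
antibody Fab fragment and quantify what binding did to it — locally at the
antigen-contacting loops, and globally through the domain architecture that
relays a signal toward the Fc region.

`fabcompare` is a library for structural immunologists and antibody
engineers who want to know, before a fragment is developed into a full
antibody, whether its antigen binding merely adjusts the CDRs or also
reorients the Fab domains and deforms the first constant-domain loop
(C_Loop1) — the changes read as an allosteric path to effector function.

## What it computes

For a couple of structures (free Fab *F*, bound Fab *A*) with 100%
identical sequences, sequentially renumbered, backbone atoms only:

* **RMSD** after optimal rigid-body overlap (Kabsch superposition):

  RMSD = sqrt( (1/N) Σᵢ |r⃗ᵢ,A − r⃗ᵢ,F|² )

  evaluated for the entire chain (residues 1–218) and for the variable
  (1–105), linker (106–113) and constant (114–218) regions under a single
  whole-Fab overlap — domains are *not* re-optimised, so the table shows
  how deviation distributes across the architecture.
* **RMSF**, the per-residue local RMSD under a stated overlap scope:
  whole-chain, or each domain fitted separately.  Per-domain overlap
  subtracts rigid-body reorientation, exposing genuinely deformed
  segments; the atom-weighted RMS of a profile reproduces its scope RMSD
  exactly.
* **Hinge angles** at conserved anchors: the angle C–S–C (heavy chain),
  C–R–C (kappa) or C–Q–C (lambda) with its vertex at a conserved linker
  residue between a variable-domain and a constant-domain cysteine, plus
  Cys–Cys and linker–linker distances.
* **Classification** of the binding-induced change:
  * **B1** — average |hinge-angle change| ≥ 10° (domain reorientation;
    observed couples reach 16–37°), with a C_Loop1 deformation;
  * **B2** — angles almost unchanged (≤ ~4°) but a prominent C_Loop1
    peak in the CH1-domain-scope RMSF (peak ≥ 1.5 Å, peak/baseline ≥ 2);
  * **B3** — neither: only CDR-local change.

A synthetic Fab generator builds two-chain couples with known hinge
rotations, loop displacements and noise, so every stage is testable
without downloading structures.

## Worked example

```python
import fabcompare as fc

couple = fc.generate_couple(fc.spec_b1(seed=0))   # -25°/+25° hinge, 2 Å loop
report = fc.analyze_prepared_couple("B1-demo", *couple[:4])
print(report.angle_change.average_abs_change, report.class_label)
```

Running `python examples/01_synthetic_couple.py` prints:

```
heavy hinge change : -25.11 deg (applied -25)
light hinge change : +24.61 deg (applied +25)
average |change|   : 24.86 deg
C_Loop1 peak       : 1.77 A (applied 2.0), ratio 6.4
class              : B1

RMSD under the whole-Fab overlap (A):
          heavy  light
entire    31.25  29.10
variable   5.88   5.96
linker     9.11   8.18
constant  44.57  41.44
```

The measured hinge changes match the rotations the generator applied; the
constant-domain RMSD dwarfs the variable-domain RMSD because the domains
stayed rigid but reoriented about the linker — the B1 signature.  The
other examples demonstrate hinge-angle parameter recovery across 5–37°
(`02_hinge_recovery.py`), the C_Loop1 signal under per-domain overlap
(`03_rmsf_profiles.py`), and batch analysis of the eight published
free/bound couples by PDB accession (`04_real_couples.py`, network
required).

A thin CLI wraps the same calls:

```
fabcompare synth --hinge-heavy -25 --hinge-light 25 --loop 2 --out couple/
fabcompare analyze couple/synthetic_free.pdb couple/synthetic_bound.pdb
fabcompare batch examples/real_couples.yaml
```

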