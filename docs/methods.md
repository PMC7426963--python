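# Methods

## The comparison model

Two crystal structures of the same Fab — one free, one in complex with its
protein antigen — are treated as two static conformations of one molecule.
All measures of change are backbone-only (N, CA, C, and O when present in
both forms); side chains are excluded throughout because their packing is
the part of a crystal structure most sensitive to lattice contacts.  The
single exception is the side-chain reference atom of each conserved anchor
residue (SG for Cys, OG for Ser, CZ for Arg, CD for Gln), used only for
the hinge-angle geometry, with a CA fallback (logged) when the side chain
is missing from the model.

Chains are prepared before any metric is computed:

* **Resolution filter** — structures worse than 3.0 Å (configurable) are
  rejected; entries without a reported resolution pass with a warning.
* **Continuity** — after renumbering, every C(i)–N(i+1) distance must be
  ≤ 2.5 Å.  A formed peptide bond sits near 1.33 Å and a chain break in a
  deposited model jumps to several Å, so the threshold separates the two
  regimes with a wide margin; discontinuous chains abort the couple.
* **Sequential renumbering** — author numbering (insertion codes
  included) is replaced by 1..n in author order, so free and bound forms
  pair position by position.  Pairing additionally requires 100% sequence
  identity, computed from a global alignment with match 1 / mismatch 0 /
  gap 0 that maximises matches and, among such alignments, minimises
  columns (so one substitution is one aligned column, not a gap pair).
* **Alternate locations** — highest occupancy wins, ties go to the
  lexicographically first altloc; only the first model is read; waters,
  heteroatoms and residues missing any of N/CA/C are dropped (the count
  is reported).

## Superposition and deviation measures

Rigid-body overlap is the SVD form of the Kabsch algorithm with a
determinant correction, so reflections are never produced.  Fits over
fewer than three points, or over collinear/coincident point sets, raise a
degeneracy error rather than returning an arbitrary rotation.  Atom
correspondence is by sequential index and atom name; residues missing a
backbone atom in either form contribute only the atoms present in both,
and fully unmatched residues are dropped pairwise and counted.

A fit can be restricted to any residue *scope* and the resulting
transform applied to the whole chain.  This one mechanism yields the
region-resolved RMSD table (one whole-Fab fit over both chains jointly,
cells evaluated per region without re-fitting) and the RMSF profiles
(one fit per scope — whole chain or a single domain — then each
residue's backbone RMSD under that transform).  Re-fitting per residue
would trivially zero every profile, so it is deliberately not done.
Missing residues appear as NaN in profiles, never as zero.  The identity
"atom-weighted RMS of per-residue values = scope RMSD" holds exactly and
is asserted to 1e-9 in the tests.

Per-domain scopes are the variable and constant domains only; the
8-residue linker belongs to no domain fit and is scored only under the
whole-chain scope.

## Hinge geometry

Each chain's domain orientation is summarised by the planar angle at a
conserved linker residue (Ser heavy / Arg kappa / Gln lambda) between a
variable-domain cysteine and a constant-domain cysteine.  Default anchor
selection takes the *last* Cys of the variable domain and the *first* Cys
of the constant domain — the cysteines nearest the elbow on each side —
and the first linker residue of the required identity; all three are
overridable per chain, validated for identity and region, and recorded in
every report.  The per-couple summary is the mean of the two chains'
absolute angle changes (bound − free); both signed deltas, the Cys–Cys
distances and the heavy–light linker–linker distance are stored alongside
so alternative summaries can be recomputed from a saved report.

## Classification

B1 when the average absolute hinge-angle change reaches `tau_angle`
(default 10°, placed between the observed B1 minimum of 16° and B2
maximum of 4°); otherwise B2 when the CH1-domain-scope C_Loop1 peak
reaches `tau_loop_peak` (default 1.5 Å) **and** its ratio to the median
of the CH1 profile outside all three C_Loops reaches `tau_loop_ratio`
(default 2.0); otherwise B3.  The loop thresholds quantify a signal that
was originally identified by visual inspection of profiles, so they are
package defaults rather than published constants; all three are stored in
every report, and a report re-derives its own label from its stored
fields, which the tests check.

Default loop windows (sequential numbering): CDRs follow the canonical
Kabat definitions (heavy 31–35 / 50–65 / 95–102; light 24–34 / 50–56 /
89–97) mapped through a user-supplied offset (identity by default — a
full Kabat renumbering engine is out of scope).  The C_Loop windows
(heavy 131–141 / 157–166 / 186–196; light 134–144 / 158–167 / 187–197)
are package defaults chosen in the N-terminal half of the constant
domain; they are config-overridable and, when analysing real couples,
should be validated against the position of the CH1-scope RMSF peak.

## The synthetic generator

The generator emulates exactly the structural features the analysis
assumes: two rigid pseudo-domains per chain (105 + 105 residues, helical
traces with ~3.8 Å CA spacing) joined by an 8-residue extended linker,
ideal-geometry N/CA/C/O placement (C–N ≈ 1.3 Å), planted anchor residues
with modelled side-chain atoms, and a second chain offset by 14 Å.  The
bound form applies, in order: a rigid hinge rotation of each constant
domain about an axis through that chain's linker-anchor atom,
perpendicular to the plane of the two anchor vectors (so the applied
angle maps one-to-one onto the measured angle change, and the sign
convention "positive opens the angle" lets the B1 preset close the heavy
chain and open the light chain as observed in real couples); a
Hann-tapered displacement of the heavy chain's designated C_Loop1 (peak
displacement equal to the requested magnitude at the span centre); the
same tapered displacement on every CDR span; and finally independent
Gaussian coordinate noise on the free and bound forms (default
σ = 0.1 Å, in the range of crystallographic coordinate uncertainty),
mimicking two independent structure determinations.  Linker residues
between the anchor and the rotated domain are re-interpolated so the
chain stays continuous for any hinge angle up to ±40°.

Default anchor positions (85 / 108 / 147) sit outside every default loop
window so that loop displacements never move an anchor atom.  What the
generator does **not** emulate: immunoglobulin folds, real side chains,
crystal contacts, correlated coordinate error, or sequence variation —
so passing recovery tests demonstrates the pipeline's mathematics and
decision logic, not robustness to mis-annotated or poorly modelled real
structures.

## Numerical choices and degeneracies

* Rotations are proper orthonormal to 1e-8; fitted RMSD is symmetric in
  its arguments to 1e-9 and invariant under rigid pre-transforms.
* The hinge angle is clipped into acos's domain before evaluation and
  reported in (0, 180]; coincident anchor atoms raise a degeneracy error,
  zero anchor distances are flagged as warnings.
* Equal values in the RMSD trend tallies (|difference| ≤ 1e-9) fall into
  an explicit "equal" bucket rather than either inequality.
* Empty scoring spans raise rather than returning silent zeros.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
couples at the full 218-residue chain size.  Recovery statistics use 10
seeds per condition (hinge angles 5/15/25/37° and a 2 Å loop
displacement, both at noise σ = 0.2 Å) and 10–20 seeds per class for the
classification truth table; the exhaustive rotation-grid cross-check of
Kabsch optimality uses 6–8-point sets on a 1° axis-angle grid.  These
sizes give sub-degree and sub-0.1 Å standard errors on every recovered
quantity while keeping a full run under a minute.

## Known limitations

* Chain-type assignment (heavy / kappa / lambda) is user-supplied, not
  inferred from sequence.
* Kabat-to-sequential mapping is a constant offset; structures whose
  numbering diverges non-uniformly need user-supplied loop windows.
* The real-couple batch requires correct per-entry chain ids and, for
  multi-copy asymmetric units, an explicit copy selection; the shipped
  couples config documents where these must be checked.
* Crystal-contact effects are assumed negligible for backbone measures;
  the package does not analyse them.
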