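"""Synthetic Fab-like free/bound couples with known ground truth.

Real free/bound Fab couples come from crystal structures; to test every
stage of the comparison pipeline without downloads, this module builds
two-chain Fab-like models from scratch:

* each chain is a continuous backbone trace of two rigid helical
  pseudo-domains (variable and constant, 105 residues each by default)
  joined by an 8-residue extended linker, with ideal-geometry N/CA/C/O
  placement (consecutive C-N around 1.3 Å);
* conserved anchor residues are planted at known positions — Cys in each
  domain and Ser/Arg/Gln at the linker, with their side-chain reference
  atoms (SG/OG/CZ/CD) modelled;
* the bound form is derived from the free form by a rigid hinge rotation
  of the constant domain about an axis through the linker anchor atom,
  perpendicular to the anchor plane — chosen so the applied angle maps
  one-to-one onto the measured C-S-C (C-R-C / C-Q-C) angle change;
* a designated C_Loop1 segment and the CDR segments can be displaced with
  smooth tapering, emulating the localized loop deviations of real
  couples; and
* independent Gaussian coordinate noise is added to the free and bound
  forms last, mimicking two independent crystal determinations.

The pseudo-domains do not fold like immunoglobulin domains; what matters
for testing the pipeline's mathematics is rigidity, continuity, anchor
placement, and exactly known deformation parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .annotate import DEFAULT_C_LOOP_TABLE, DEFAULT_CDR_TABLE, RegionScheme, Span
from .errors import SpecError
from .structure_io import ChainModel, ChainType, ResidueRecord, write_chain_pdb
from .geometry import LINKER_ANCHOR_AA

#: Side-chain reference atom planted for each anchor identity.
_ANCHOR_ATOM = {"C": "SG", "S": "OG", "R": "CZ", "Q": "CD"}

# Geometry constants of the trace (Å / degrees).  Helix parameters give a
# CA-CA spacing of ~3.8 Å; the two domain rods meet at the linker with an
# opening of ~110 degrees so hinge rotations of up to +-40 degrees keep the
# measured angle well inside (0, 180).
_HELIX_RADIUS = 1.8
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
_ARM = 16.0                 # distance from the elbow to each rod's near end
_HALF_OPENING_DEG = 55.0    # each rod direction vs the vertical
_LIGHT_OFFSET = np.array([0.0, 14.0, 0.0])
_SIDECHAIN_LENGTH = 1.9
_CARBONYL_LENGTH = 1.23
_BOND_FRACTION = 0.33       # N/C offset along the CA-CA chord


@dataclass(frozen=True)
class AnchorPlan:
    """Sequential positions where the conserved anchors are planted.

    Defaults keep all three anchors clear of the default CDR and C_Loop
    windows, so loop displacements never move an anchor atom and hinge
    recovery stays exact.
    """

    v_cys: int = 85
    linker: int = 108
    c_cys: int = 147


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for one synthetic free/bound couple."""

    n_variable: int = 105
    n_linker: int = 8
    n_constant: int = 105
    hinge_angle_heavy: float = 0.0     # degrees; positive opens the angle
    hinge_angle_light: float = 0.0
    c_loop1_displacement: float = 0.0  # Å, peak displacement of heavy C_Loop1
    cdr_displacement: float = 0.0      # Å, peak displacement of each CDR
    noise_sigma: float = 0.1           # Å, per-coordinate Gaussian noise
    seed: int = 0
    anchor_plan: AnchorPlan = AnchorPlan()
    light_chain_type: ChainType = "light_kappa"

    def __post_init__(self) -> None:
        if self.n_linker < 3:
            raise SpecError("n_linker must be at least 3 (anchor plus slack)")
        if min(self.n_variable, self.n_constant) < 20:
            raise SpecError("pseudo-domains need at least 20 residues")
        if min(self.c_loop1_displacement, self.cdr_displacement,
               self.noise_sigma) < 0:
            raise SpecError("displacement magnitudes and noise must be >= 0")
        scheme = self.region_scheme()
        ap = self.anchor_plan
        if not (scheme.variable_span[0] <= ap.v_cys <= scheme.variable_span[1]):
            raise SpecError("anchor_plan.v_cys outside the variable domain")
        if not (scheme.linker_span[0] <= ap.linker <= scheme.linker_span[1] - 1):
            raise SpecError("anchor_plan.linker must sit in the linker, "
                            "with at least one residue after it")
        if not (scheme.constant_span[0] <= ap.c_cys <= scheme.constant_span[1]):
            raise SpecError("anchor_plan.c_cys outside the constant domain")

    def region_scheme(self) -> RegionScheme:
        nv, nl = self.n_variable, self.n_linker
        return RegionScheme(
            variable_span=(1, nv),
            linker_span=(nv + 1, nv + nl),
            constant_span=(nv + nl + 1, nv + nl + self.n_constant),
        )

    @property
    def n_total(self) -> int:
        return self.n_variable + self.n_linker + self.n_constant

    def designated_c_loop1(self) -> Span:
        return DEFAULT_C_LOOP_TABLE["heavy"]["C_Loop1"]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class Couple(NamedTuple):
    """A generated free/bound couple plus its ground truth."""

    free_heavy: ChainModel
    free_light: ChainModel
    bound_heavy: ChainModel
    bound_light: ChainModel
    ground_truth: dict


# Canonical study conditions: one couple per behaviour class.  B1 hinges
# strongly (heavy closing, light opening, as observed for real B1 couples)
# and carries the C_Loop1 signal; B2 keeps the Fab shape but moves C_Loop1;
# B3 moves only the CDRs.

def spec_b1(seed: int = 0, hinge: float = 25.0) -> SyntheticSpec:
    return SyntheticSpec(hinge_angle_heavy=-hinge, hinge_angle_light=hinge,
                         c_loop1_displacement=2.0, cdr_displacement=1.0,
                         seed=seed)


def spec_b2(seed: int = 0) -> SyntheticSpec:
    return SyntheticSpec(c_loop1_displacement=2.0, cdr_displacement=1.0,
                         seed=seed)


def spec_b3(seed: int = 0) -> SyntheticSpec:
    return SyntheticSpec(cdr_displacement=1.0, seed=seed)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(a) * kx + (1 - math.cos(a)) * (kx @ kx)


def _ca_trace(spec: SyntheticSpec, phase: float) -> np.ndarray:
    """CA positions of one chain: helix rod, extended linker, helix rod."""
    nv, nl, nc = spec.n_variable, spec.n_linker, spec.n_constant
    half = math.radians(_HALF_OPENING_DEG)
    e_v = np.array([-math.sin(half), 0.0, math.cos(half)])
    e_c = np.array([math.sin(half), 0.0, math.cos(half)])
    q1 = _ARM * e_v          # near end of the variable rod
    q2 = _ARM * e_c          # near end of the constant rod

    def _frame(axis):
        ref = np.array([0.0, 1.0, 0.0])
        f1 = np.cross(axis, ref)
        f1 /= np.linalg.norm(f1)
        f2 = np.cross(axis, f1)
        return f1, f2

    turn = math.radians(_HELIX_TURN_DEG)
    cas = np.zeros((spec.n_total, 3))
    # variable rod runs from far out toward the elbow (residue nv nearest)
    f1, f2 = _frame(e_v)
    for i in range(1, nv + 1):
        axial = q1 + e_v * _HELIX_RISE * (nv - i)
        ang = turn * i + phase
        cas[i - 1] = axial + _HELIX_RADIUS * (math.cos(ang) * f1 + math.sin(ang) * f2)
    # extended linker between the two rod ends
    for j in range(1, nl + 1):
        cas[nv + j - 1] = q1 + (q2 - q1) * j / (nl + 1)
    # constant rod runs from the elbow outward
    f1, f2 = _frame(e_c)
    for i in range(1, nc + 1):
        axial = q2 + e_c * _HELIX_RISE * (i - 1)
        ang = turn * i + phase + 2.0
        cas[nv + nl + i - 1] = axial + _HELIX_RADIUS * (
            math.cos(ang) * f1 + math.sin(ang) * f2)
    return cas


def _backbone_from_ca(cas: np.ndarray, index: int) -> dict[str, np.ndarray]:
    """Ideal-geometry N/CA/C/O placement for residue ``index`` (0-based)."""
    n_res = cas.shape[0]
    ca = cas[index]
    chord_prev = cas[index] - cas[index - 1] if index > 0 else cas[1] - cas[0]
    chord_next = cas[index + 1] - cas[index] if index < n_res - 1 else chord_prev
    n_atom = ca - _BOND_FRACTION * chord_prev
    c_atom = ca + _BOND_FRACTION * chord_next
    normal = np.cross(chord_next, chord_prev)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        normal = np.cross(chord_next, np.array([0.0, 0.0, 1.0]))
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            normal = np.array([1.0, 0.0, 0.0])
            norm = 1.0
    o_atom = c_atom + _CARBONYL_LENGTH * normal / norm
    return {"N": n_atom, "CA": ca, "C": c_atom, "O": o_atom}


def _sequence(spec: SyntheticSpec, chain_type: ChainType) -> list[str]:
    seq = ["A"] * spec.n_total
    ap = spec.anchor_plan
    seq[ap.v_cys - 1] = "C"
    seq[ap.linker - 1] = LINKER_ANCHOR_AA[chain_type]
    seq[ap.c_cys - 1] = "C"
    return seq


def _build_chain(spec: SyntheticSpec, chain_type: ChainType,
                 chain_id: str, phase: float,
                 offset: np.ndarray) -> ChainModel:
    cas = _ca_trace(spec, phase) + offset
    seq = _sequence(spec, chain_type)
    residues = []
    for i in range(spec.n_total):
        backbone = _backbone_from_ca(cas, i)
        aa = seq[i]
        anchor = None
        anchor_atom = None
        if aa != "A":
            # side-chain reference atom: radially away from the local chord
            chord = backbone["C"] - backbone["N"]
            perp = np.cross(chord, np.array([0.0, 1.0, 0.0]))
            if np.linalg.norm(perp) < 1e-9:
                perp = np.array([0.0, 0.0, 1.0])
            anchor = backbone["CA"] + _SIDECHAIN_LENGTH * perp / np.linalg.norm(perp)
            anchor_atom = _ANCHOR_ATOM[aa]
        residues.append(ResidueRecord(
            seq_index=i + 1,
            author_number=str(i + 1),
            aa=aa,
            backbone_coords=backbone,
            sidechain_anchor=anchor,
            sidechain_atom=anchor_atom,
        ))
    return ChainModel(chain_id=chain_id, chain_type=chain_type,
                      residues=residues, source_entry="SYNF")


def build_free_fab(spec: SyntheticSpec) -> tuple[ChainModel, ChainModel]:
    """Noise-free ideal free Fab: heavy and light chains."""
    heavy = _build_chain(spec, "heavy", "H", phase=0.0,
                         offset=np.zeros(3))
    light = _build_chain(spec, spec.light_chain_type, "L", phase=1.3,
                         offset=_LIGHT_OFFSET)
    return heavy, light


def _chain_atoms(chain: ChainModel):
    for res in chain.residues:
        for name in list(res.backbone_coords):
            yield res, name
        if res.sidechain_anchor is not None:
            yield res, "_anchor"


def _apply_hinge(chain: ChainModel, spec: SyntheticSpec, angle_deg: float) -> None:
    """Rigidly rotate the constant domain about the linker-anchor axis.

    The axis passes through the linker anchor's side-chain atom and is
    perpendicular to the plane of the two anchor vectors, so the measured
    hinge angle changes by exactly ``angle_deg`` (positive = opening).
    The linker residues between the anchor and the constant domain are
    re-interpolated so the chain stays continuous.
    """
    if angle_deg == 0.0:
        return
    ap = spec.anchor_plan
    scheme = spec.region_scheme()
    pivot = chain.residue(ap.linker).sidechain_anchor
    u = chain.residue(ap.v_cys).sidechain_anchor - pivot
    w = chain.residue(ap.c_cys).sidechain_anchor - pivot
    axis = np.cross(u, w)
    rot = _rotation_about_axis(axis, angle_deg)

    c_start = scheme.constant_span[0]
    for res in chain.residues[c_start - 1:]:
        for name, xyz in res.backbone_coords.items():
            res.backbone_coords[name] = rot @ (xyz - pivot) + pivot
        if res.sidechain_anchor is not None:
            res.sidechain_anchor = rot @ (res.sidechain_anchor - pivot) + pivot

    # re-interpolate linker CAs between the anchor and the rotated domain,
    # then rebuild ideal backbone geometry across the affected window
    first = ap.linker + 1
    ca_a = chain.residue(ap.linker).backbone_coords["CA"]
    ca_b = chain.residue(c_start).backbone_coords["CA"]
    steps = c_start - ap.linker
    new_cas = {
        i: ca_a + (ca_b - ca_a) * (i - ap.linker) / steps
        for i in range(first, c_start)
    }
    # the constant domain (including residue c_start) stays a strict rigid
    # body; only linker residues after the anchor are rebuilt
    window = list(range(ap.linker - 1, c_start + 1))  # context incl. neighbours
    cas = np.array([
        new_cas.get(i, chain.residue(i).backbone_coords["CA"]) for i in window
    ])
    for k, i in enumerate(window):
        if i < first - 1 or i >= c_start:
            continue
        rebuilt = _backbone_from_ca(cas, k)
        res = chain.residue(i)
        if i == first - 1:           # anchor residue: only its C/O chord changed
            res.backbone_coords["C"] = rebuilt["C"]
            res.backbone_coords["O"] = rebuilt["O"]
        else:
            res.backbone_coords.update(rebuilt)


def _displace_span(chain: ChainModel, span: Span, magnitude: float) -> None:
    """Displace a loop span with a smooth sine taper (peak at the centre)."""
    if magnitude == 0.0:
        return
    lo, hi = span
    lo = max(lo, 1)
    hi = min(hi, len(chain))
    n = hi - lo + 1
    if n <= 0:
        return
    t = (chain.residue(hi).backbone_coords["CA"]
         - chain.residue(lo).backbone_coords["CA"])
    direction = np.cross(t, np.array([0.0, 1.0, 0.0]))
    if np.linalg.norm(direction) < 1e-9:
        direction = np.array([1.0, 0.0, 0.0])
    direction = direction / np.linalg.norm(direction)
    for k, i in enumerate(range(lo, hi + 1), start=1):
        # Hann-style taper: zero at the loop ends, exactly ``magnitude`` at
        # the centre, and a small integrated pull on the domain fit
        shift = magnitude * math.sin(math.pi * k / (n + 1)) ** 2 * direction
        res = chain.residue(i)
        for name in res.backbone_coords:
            res.backbone_coords[name] = res.backbone_coords[name] + shift
        if res.sidechain_anchor is not None:
            res.sidechain_anchor = res.sidechain_anchor + shift


def _add_noise(chain: ChainModel, sigma: float, rng: np.random.Generator) -> None:
    if sigma == 0.0:
        return
    for res in chain.residues:
        for name in res.backbone_coords:
            res.backbone_coords[name] = (
                res.backbone_coords[name] + rng.normal(0.0, sigma, 3))
        if res.sidechain_anchor is not None:
            res.sidechain_anchor = res.sidechain_anchor + rng.normal(0.0, sigma, 3)


def derive_bound_fab(
    free: tuple[ChainModel, ChainModel],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ChainModel, ChainModel]:
    """Derive the (noisy) bound form from an ideal free Fab.

    Deformations are applied in order: hinge rotation per chain, heavy
    C_Loop1 displacement, CDR displacements on both chains, then Gaussian
    noise.  ``rng`` defaults to a generator seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    heavy = free[0].copy()
    light = free[1].copy()
    heavy.source_entry = light.source_entry = "SYNB"
    _apply_hinge(heavy, spec, spec.hinge_angle_heavy)
    _apply_hinge(light, spec, spec.hinge_angle_light)
    _displace_span(heavy, spec.designated_c_loop1(), spec.c_loop1_displacement)
    if spec.cdr_displacement > 0:
        for span in DEFAULT_CDR_TABLE["heavy"].values():
            _displace_span(heavy, span, spec.cdr_displacement)
        for span in DEFAULT_CDR_TABLE[light.chain_type].values():
            _displace_span(light, span, spec.cdr_displacement)
    _add_noise(heavy, spec.noise_sigma, rng)
    _add_noise(light, spec.noise_sigma, rng)
    return heavy, light


def generate_couple(spec: SyntheticSpec) -> Couple:
    """Build a full couple: noisy free form, deformed noisy bound form.

    Noise is drawn independently for the two forms (two independent
    determinations of "the same" molecule), from streams derived from
    ``spec.seed``; a fixed seed reproduces the couple bit for bit.
    """
    ideal_heavy, ideal_light = build_free_fab(spec)
    rng_free = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rng_bound = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    bound_heavy, bound_light = derive_bound_fab(
        (ideal_heavy, ideal_light), spec, rng=rng_bound)
    free_heavy, free_light = ideal_heavy.copy(), ideal_light.copy()
    _add_noise(free_heavy, spec.noise_sigma, rng_free)
    _add_noise(free_light, spec.noise_sigma, rng_free)
    truth = {
        "spec": spec.to_dict(),
        "hinge_angle_heavy_deg": spec.hinge_angle_heavy,
        "hinge_angle_light_deg": spec.hinge_angle_light,
        "c_loop1_displacement_A": spec.c_loop1_displacement,
        "c_loop1_span": list(spec.designated_c_loop1()),
        "cdr_displacement_A": spec.cdr_displacement,
        "noise_sigma_A": spec.noise_sigma,
        "anchor_plan": asdict(spec.anchor_plan),
    }
    return Couple(free_heavy, free_light, bound_heavy, bound_light, truth)


def write_couple_pdb(
    couple: Couple,
    directory: str | Path,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write the couple as two PDB files plus a ground-truth JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    free_path = directory / f"{prefix}_free.pdb"
    bound_path = directory / f"{prefix}_bound.pdb"
    truth_path = directory / f"{prefix}_ground_truth.json"
    write_chain_pdb([couple.free_heavy, couple.free_light], free_path,
                    entry_id="SYNF", resolution=2.0)
    write_chain_pdb([couple.bound_heavy, couple.bound_light], bound_path,
                    entry_id="SYNB", resolution=2.0)
    truth_path.write_text(json.dumps(couple.ground_truth, indent=2))
    return {"free": free_path, "bound": bound_path, "ground_truth": truth_path}
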