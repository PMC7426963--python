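"""Conserved-anchor hinge angles and distances between Fab domains.

The relative orientation of the variable versus constant domain of each
chain is summarised by one angle per chain, measured at three conserved
residues: a cysteine in the variable domain, a cysteine in the constant
domain, and a conserved linker residue between them — serine in heavy
chains, arginine in kappa light chains, glutamine in lambda light chains.
The angle (C-S-C, C-R-C or C-Q-C) has its vertex at the linker residue.
Distances between the two cysteines of each chain, and between the two
chains' linker anchors, complement the angles; an increase of the
linker-linker distance accompanies the large-reorientation class.

Anchor coordinates use each residue's side-chain reference atom (SG for
Cys, OG for Ser, CZ for Arg, CD for Gln), falling back to CA with a logged
warning when the side chain is missing from the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotate import RegionAnnotation
from .errors import (
    AnchorIdentityError,
    AnchorMismatchError,
    AnchorNotFoundError,
    DegenerateError,
)
from .structure_io import ChainModel, ChainType

logger = logging.getLogger(__name__)

#: Conserved linker anchor identity per chain type.
LINKER_ANCHOR_AA: dict[str, str] = {
    "heavy": "S",
    "light_kappa": "R",
    "light_lambda": "Q",
}


@dataclass
class AnchorPoint:
    seq_index: int
    aa: str
    atom: str                 # atom actually used (side-chain ref or CA)
    coord: np.ndarray


@dataclass
class AnchorSet:
    """The three conserved anchors of one chain."""

    chain_type: ChainType
    v_cys: AnchorPoint
    linker_anchor: AnchorPoint
    c_cys: AnchorPoint
    chain_id: str = ""

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.v_cys.seq_index, self.linker_anchor.seq_index,
                self.c_cys.seq_index)


@dataclass
class AngleMetrics:
    """Hinge angles and anchor distances of one Fab (both chains)."""

    heavy_angle: float                 # degrees, C-S-C
    light_angle: float                 # degrees, C-R-C or C-Q-C
    cys_cys_distance_heavy: float      # Å
    cys_cys_distance_light: float      # Å
    linker_linker_distance: float      # Å
    heavy_anchor_indices: tuple[int, int, int] = (0, 0, 0)
    light_anchor_indices: tuple[int, int, int] = (0, 0, 0)

    def to_dict(self) -> dict:
        return {
            "heavy_angle_deg": self.heavy_angle,
            "light_angle_deg": self.light_angle,
            "cys_cys_distance_heavy_A": self.cys_cys_distance_heavy,
            "cys_cys_distance_light_A": self.cys_cys_distance_light,
            "linker_linker_distance_A": self.linker_linker_distance,
            "heavy_anchor_indices": list(self.heavy_anchor_indices),
            "light_anchor_indices": list(self.light_anchor_indices),
        }


@dataclass
class AngleChange:
    """Signed per-chain hinge-angle changes, bound minus free."""

    delta_heavy: float
    delta_light: float
    average_abs_change: float
    delta_linker_linker: float = 0.0

    def to_dict(self) -> dict:
        return {
            "delta_heavy_deg": self.delta_heavy,
            "delta_light_deg": self.delta_light,
            "average_abs_change_deg": self.average_abs_change,
            "delta_linker_linker_A": self.delta_linker_linker,
        }


def _anchor_point(chain: ChainModel, seq_index: int, expect_aa: str) -> AnchorPoint:
    res = chain.residue(seq_index)
    if res.aa != expect_aa:
        raise AnchorIdentityError(
            f"{chain.source_entry}:{chain.chain_id} residue {seq_index} is "
            f"'{res.aa}', expected '{expect_aa}'"
        )
    if res.sidechain_anchor is not None:
        return AnchorPoint(seq_index, res.aa, res.sidechain_atom or "?",
                           res.sidechain_anchor.copy())
    logger.warning(
        "%s:%s residue %d (%s) lacks its side-chain anchor atom; using CA",
        chain.source_entry, chain.chain_id, seq_index, res.aa,
    )
    return AnchorPoint(seq_index, res.aa, "CA", res.backbone_coords["CA"].copy())


def find_anchors(
    chain: ChainModel,
    annotation: RegionAnnotation,
    overrides: dict[str, int] | None = None,
) -> AnchorSet:
    """Locate the three conserved anchors of a chain.

    Default selection: the *last* cysteine in the variable domain, the
    *first* cysteine in the constant domain (the two cysteines nearest the
    elbow on either side), and the first linker residue of the conserved
    identity for the chain type.  ``overrides`` ({"v_cys": i, "linker": j,
    "c_cys": k}) replaces any of these after validating residue identity.
    """
    overrides = overrides or {}
    linker_aa = LINKER_ANCHOR_AA[chain.chain_type]
    scheme = annotation.scheme

    def _search(span, aa, which, last=False):
        lo, hi = span
        rng = range(min(hi, len(chain)), lo - 1, -1) if last else \
            range(lo, min(hi, len(chain)) + 1)
        for i in rng:
            if chain.residue(i).aa == aa:
                return i
        raise AnchorNotFoundError(
            f"{chain.source_entry}:{chain.chain_id}: no '{aa}' found for "
            f"{which} anchor in span {span}"
        )

    def _pick(key, span, aa, which, last=False):
        if key in overrides:
            idx = int(overrides[key])
            lo, hi = span
            if not (lo <= idx <= hi):
                raise AnchorNotFoundError(
                    f"override {key}={idx} lies outside its region {span}"
                )
            return idx
        return _search(span, aa, which, last=last)

    v_idx = _pick("v_cys", scheme.variable_span, "C", "variable-domain Cys", last=True)
    l_idx = _pick("linker", scheme.linker_span, linker_aa, "linker")
    c_idx = _pick("c_cys", scheme.constant_span, "C", "constant-domain Cys")
    return AnchorSet(
        chain_type=chain.chain_type,
        v_cys=_anchor_point(chain, v_idx, "C"),
        linker_anchor=_anchor_point(chain, l_idx, linker_aa),
        c_cys=_anchor_point(chain, c_idx, "C"),
        chain_id=chain.chain_id,
    )


def hinge_angle(anchors: AnchorSet) -> float:
    """Planar angle at the linker anchor, in degrees within (0, 180]."""
    u = anchors.v_cys.coord - anchors.linker_anchor.coord
    w = anchors.c_cys.coord - anchors.linker_anchor.coord
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise DegenerateError("coincident anchor atoms: angle undefined")
    cosang = float(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def anchor_distances(heavy: AnchorSet, light: AnchorSet) -> dict[str, float]:
    """Cys-Cys distance within each chain and the linker-linker distance."""
    d_h = float(np.linalg.norm(heavy.v_cys.coord - heavy.c_cys.coord))
    d_l = float(np.linalg.norm(light.v_cys.coord - light.c_cys.coord))
    d_link = float(np.linalg.norm(
        heavy.linker_anchor.coord - light.linker_anchor.coord))
    for name, d in (("cys_cys_heavy", d_h), ("cys_cys_light", d_l),
                    ("linker_linker", d_link)):
        if d < 1e-9:
            logger.warning("degenerate %s distance: anchor atoms coincide", name)
    return {
        "cys_cys_distance_heavy": d_h,
        "cys_cys_distance_light": d_l,
        "linker_linker_distance": d_link,
    }


def measure_angles(heavy: AnchorSet, light: AnchorSet) -> AngleMetrics:
    """All hinge angles and anchor distances of one Fab."""
    dists = anchor_distances(heavy, light)
    return AngleMetrics(
        heavy_angle=hinge_angle(heavy),
        light_angle=hinge_angle(light),
        cys_cys_distance_heavy=dists["cys_cys_distance_heavy"],
        cys_cys_distance_light=dists["cys_cys_distance_light"],
        linker_linker_distance=dists["linker_linker_distance"],
        heavy_anchor_indices=heavy.indices,
        light_anchor_indices=light.indices,
    )


def angle_change(free: AngleMetrics, bound: AngleMetrics) -> AngleChange:
    """Signed hinge-angle changes (bound - free) and their mean magnitude.

    The single per-couple summary is the mean of the two chains' absolute
    angle changes; both signed deltas are kept alongside it so alternative
    summaries can be recomputed from a stored report.
    """
    if (free.heavy_anchor_indices != bound.heavy_anchor_indices
            or free.light_anchor_indices != bound.light_anchor_indices):
        raise AnchorMismatchError(
            "free and bound forms were measured at different anchor residues: "
            f"free {free.heavy_anchor_indices}/{free.light_anchor_indices}, "
            f"bound {bound.heavy_anchor_indices}/{bound.light_anchor_indices}"
        )
    dh = bound.heavy_angle - free.heavy_angle
    dl = bound.light_angle - free.light_angle
    return AngleChange(
        delta_heavy=dh,
        delta_light=dl,
        average_abs_change=(abs(dh) + abs(dl)) / 2.0,
        delta_linker_linker=(bound.linker_linker_distance
                             - free.linker_linker_distance),
    )
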