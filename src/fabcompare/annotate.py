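"""Region annotation: variable / linker / constant spans, CDRs and C_Loops.

A prepared Fab chain is partitioned, in sequential numbering, into the
variable domain (residues 1-105), the inter-domain linker (106-113) and the
constant domain (114-218); residues past 218 are flagged as tail and kept
out of every metric.  On top of that partition, six loops are marked: the
three complementarity-determining regions (CDR1-3) on the variable domain
and the three constant-domain loops (C_Loop1-3), numbered N- to C-terminal.

Default CDR windows follow the canonical Kabat definitions (heavy 31-35 /
50-65 / 95-102, light 24-34 / 50-56 / 89-97), mapped onto the sequential
numbering through a user-supplied offset (identity by default).  The
C_Loop windows are package defaults chosen near the N-terminal part of the
constant domain and are fully overridable from config; every report records
the spans actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import SpanError
from .structure_io import ChainModel, ChainType

Span = tuple[int, int]        # inclusive 1-based residue window

DEFAULT_CDR_TABLE: dict[str, dict[str, Span]] = {
    "heavy": {"CDR1": (31, 35), "CDR2": (50, 65), "CDR3": (95, 102)},
    "light_kappa": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
    "light_lambda": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
}

DEFAULT_C_LOOP_TABLE: dict[str, dict[str, Span]] = {
    "heavy": {"C_Loop1": (131, 141), "C_Loop2": (157, 166), "C_Loop3": (186, 196)},
    "light_kappa": {"C_Loop1": (134, 144), "C_Loop2": (158, 167), "C_Loop3": (187, 197)},
    "light_lambda": {"C_Loop1": (134, 144), "C_Loop2": (158, 167), "C_Loop3": (187, 197)},
}


def _check_span(span: Span, name: str) -> None:
    lo, hi = span
    if lo < 1 or hi < lo:
        raise SpanError(f"{name}: invalid span {span}")


@dataclass(frozen=True)
class RegionScheme:
    """Sequential-numbering boundaries of the three Fab chain regions."""

    variable_span: Span = (1, 105)
    linker_span: Span = (106, 113)
    constant_span: Span = (114, 218)

    def __post_init__(self) -> None:
        for name in ("variable_span", "linker_span", "constant_span"):
            _check_span(getattr(self, name), name)
        if not (
            self.variable_span[1] + 1 == self.linker_span[0]
            and self.linker_span[1] + 1 == self.constant_span[0]
        ):
            raise SpanError(
                "regions must be adjacent: variable, then linker, then constant"
            )

    @property
    def entire_span(self) -> Span:
        return (self.variable_span[0], self.constant_span[1])

    def span(self, region: str) -> Span:
        if region == "entire":
            return self.entire_span
        try:
            return getattr(self, f"{region}_span")
        except AttributeError:
            raise SpanError(f"unknown region '{region}'") from None

    def region_of(self, seq_index: int) -> str:
        if self.variable_span[0] <= seq_index <= self.variable_span[1]:
            return "variable"
        if self.linker_span[0] <= seq_index <= self.linker_span[1]:
            return "linker"
        if self.constant_span[0] <= seq_index <= self.constant_span[1]:
            return "constant"
        return "tail"


@dataclass
class RegionAnnotation:
    """Regions plus loop spans for one chain."""

    scheme: RegionScheme
    chain_type: ChainType
    cdr_spans: dict[str, Span] = field(default_factory=dict)
    c_loop_spans: dict[str, Span] = field(default_factory=dict)
    n_residues: int = 0

    def region_of(self, seq_index: int) -> str:
        return self.scheme.region_of(seq_index)

    def scored_indices(self, region: str = "entire") -> list[int]:
        """Sequential indices belonging to ``region``, clipped to the chain."""
        lo, hi = self.scheme.span(region)
        return list(range(lo, min(hi, self.n_residues) + 1))

    def tail_indices(self) -> list[int]:
        return list(range(self.scheme.entire_span[1] + 1, self.n_residues + 1))


def assign_regions(chain: ChainModel, scheme: RegionScheme | None = None) -> RegionAnnotation:
    """Partition a chain into variable/linker/constant (+ excluded tail).

    Raises :class:`SpanError` when the chain is too short to contain the
    variable domain and linker — such a fragment cannot be analysed under
    the fixed region boundaries.
    """
    scheme = scheme or RegionScheme()
    if len(chain) < scheme.linker_span[1]:
        raise SpanError(
            f"chain {chain.chain_id} has {len(chain)} residues; regions require "
            f"at least {scheme.linker_span[1]}"
        )
    return RegionAnnotation(scheme=scheme, chain_type=chain.chain_type,
                            n_residues=len(chain))


def _validated_loops(
    spans: Mapping[str, Span], container: Span, prefix: str
) -> dict[str, Span]:
    ordered = dict(sorted(spans.items()))
    prev_hi = 0
    for name, (lo, hi) in ordered.items():
        _check_span((lo, hi), name)
        if lo <= prev_hi:
            raise SpanError(f"{name}: loop spans must be disjoint and ascending")
        if lo < container[0] or hi > container[1]:
            raise SpanError(
                f"{name}: span {(lo, hi)} outside its {prefix} domain {container}"
            )
        prev_hi = hi
    return ordered


def annotate_cdrs(
    annotation: RegionAnnotation,
    table: Mapping[str, Mapping[str, Span]] | None = None,
    offset: int = 0,
) -> dict[str, Span]:
    """Attach CDR1-3 spans for the chain type; Kabat defaults, overridable.

    ``offset`` shifts the table's (Kabat) numbering onto sequential
    numbering when the two differ by a constant.
    """
    table = table or DEFAULT_CDR_TABLE
    raw = table[annotation.chain_type]
    shifted = {name: (lo + offset, hi + offset) for name, (lo, hi) in raw.items()}
    annotation.cdr_spans = _validated_loops(
        shifted, annotation.scheme.variable_span, "variable"
    )
    return annotation.cdr_spans


def annotate_c_loops(
    annotation: RegionAnnotation,
    table: Mapping[str, Mapping[str, Span]] | None = None,
    offset: int = 0,
) -> dict[str, Span]:
    """Attach C_Loop1-3 spans on the constant domain; defaults overridable."""
    table = table or DEFAULT_C_LOOP_TABLE
    raw = table[annotation.chain_type]
    shifted = {name: (lo + offset, hi + offset) for name, (lo, hi) in raw.items()}
    annotation.c_loop_spans = _validated_loops(
        shifted, annotation.scheme.constant_span, "constant"
    )
    return annotation.c_loop_spans


def annotate(
    chain: ChainModel,
    scheme: RegionScheme | None = None,
    cdr_table: Mapping[str, Mapping[str, Span]] | None = None,
    c_loop_table: Mapping[str, Mapping[str, Span]] | None = None,
) -> RegionAnnotation:
    """Full annotation: regions, CDRs and C_Loops in one call."""
    ann = assign_regions(chain, scheme)
    annotate_cdrs(ann, cdr_table)
    annotate_c_loops(ann, c_loop_table)
    return ann


def load_boundary_tables(path: str | Path) -> dict:
    """Read CDR / C_Loop boundary overrides from a YAML config file.

    Expected layout::

        cdr:
          heavy: {CDR1: [31, 35], CDR2: [50, 65], CDR3: [95, 102]}
        c_loop:
          heavy: {C_Loop1: [131, 141], ...}

    Missing sections fall back to the package defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}

    def _to_table(section, defaults):
        table = {k: dict(v) for k, v in defaults.items()}
        for chain_type, spans in (section or {}).items():
            table.setdefault(chain_type, {})
            for name, span in spans.items():
                table[chain_type][name] = (int(span[0]), int(span[1]))
        return table

    return {
        "cdr": _to_table(data.get("cdr"), DEFAULT_CDR_TABLE),
        "c_loop": _to_table(data.get("c_loop"), DEFAULT_C_LOOP_TABLE),
    }
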