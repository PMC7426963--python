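"""Per-residue deviation (RMSF) profiles between free and bound chains.

For two static structures, the RMSF is the local RMSD reported residue by
residue: the chains are overlapped once, over a stated *scope* (the whole
chain, or one domain fitted separately), and each residue's value is the
RMSD of its own backbone atoms under that single scope transform.  The
chain-level RMSD is thus "divided" across residues: the atom-weighted RMS
of the per-residue values reproduces the scope RMSD exactly, which is
asserted in the test suite as a consistency identity.

Residues missing backbone atoms in either form are reported as NaN, never
as zero — a missing residue is unknown, not rigid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import RegionAnnotation, Span
from .errors import EmptySpanError
from .structure_io import BACKBONE_ATOMS, ChainModel
from .superpose import SuperpositionResult, fit_scope


@dataclass
class RMSFProfile:
    """Per-residue deviations for one chain under one overlap scope."""

    scope: str                      # "whole-chain" or a domain name
    seq_indices: list[int]
    values: np.ndarray              # Å; NaN where a residue could not be scored
    atom_counts: np.ndarray         # backbone atoms scored per residue
    fit: SuperpositionResult
    chain_id: str = ""
    couple_id: str = ""

    def value_at(self, seq_index: int) -> float:
        return float(self.values[self.seq_indices.index(seq_index)])

    def in_span(self, span: Span) -> np.ndarray:
        lo, hi = span
        mask = [(lo <= i <= hi) for i in self.seq_indices]
        return self.values[np.array(mask, dtype=bool)]

    def weighted_rms(self) -> float:
        """Atom-weighted RMS of the profile; equals the scope RMSD."""
        ok = ~np.isnan(self.values)
        w = self.atom_counts[ok]
        return float(np.sqrt(np.sum(w * self.values[ok] ** 2) / np.sum(w)))


@dataclass
class LoopSignal:
    """Strength of a localized loop deviation within a domain profile."""

    peak: float                 # max RMSF inside the loop span, Å
    peak_index: int             # seq_index of the peak
    baseline: float             # median RMSF of the domain outside all loops, Å
    ratio: float                # peak / baseline (1.0 when both are zero)


def rmsf_profile(
    free: ChainModel,
    bound: ChainModel,
    scope_span: Span | None = None,
    scope_label: str = "whole-chain",
    couple_id: str = "",
) -> RMSFProfile:
    """Per-residue RMSD profile under a single scope overlap.

    The bound chain is superposed onto the free chain using backbone atoms
    of residues inside ``scope_span`` (whole chain when ``None``); the
    profile then scores each in-scope residue's own backbone atoms under
    that transform.  No per-residue re-fitting takes place — that would
    zero the profile by construction.
    """
    transform = fit_scope(free, bound, scope=scope_span, scope_label=scope_label)
    if scope_span is None:
        indices = list(range(1, min(len(free), len(bound)) + 1))
    else:
        lo, hi = scope_span
        indices = list(range(lo, min(hi, len(free), len(bound)) + 1))
    values = np.full(len(indices), np.nan)
    counts = np.zeros(len(indices), dtype=int)
    for k, i in enumerate(indices):
        rf = free.residue(i).backbone_coords
        rb = bound.residue(i).backbone_coords
        names = [n for n in BACKBONE_ATOMS if n in rf and n in rb]
        if not names:
            continue
        a = transform.transform(np.array([rb[n] for n in names]))
        b = np.array([rf[n] for n in names])
        values[k] = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        counts[k] = len(names)
    return RMSFProfile(
        scope=scope_label,
        seq_indices=indices,
        values=values,
        atom_counts=counts,
        fit=transform,
        chain_id=free.chain_id,
        couple_id=couple_id,
    )


def region_summary(profile: RMSFProfile, span: Span) -> dict:
    """Mean / max / argmax of the profile over a residue span."""
    lo, hi = span
    pairs = [
        (i, v)
        for i, v in zip(profile.seq_indices, profile.values)
        if lo <= i <= hi and not np.isnan(v)
    ]
    if not pairs:
        raise EmptySpanError(f"no scored residues in span {span} "
                             f"(profile scope '{profile.scope}')")
    idx, vals = zip(*pairs)
    vals = np.array(vals)
    k = int(np.argmax(vals))
    return {"mean": float(vals.mean()), "max": float(vals.max()), "argmax": idx[k]}


def c_loop1_signal(
    profile: RMSFProfile,
    c_loop_spans: dict[str, Span],
) -> LoopSignal:
    """C_Loop1 deviation strength in a constant-domain-scope profile.

    ``profile`` must come from a per-domain overlap of the constant domain
    (CH1 for the heavy chain); the peak is taken over the C_Loop1 span and
    referenced against the median of the domain profile outside all three
    C_Loops.  A large peak with a large ratio is the signature read as an
    allosteric signal toward the Fc region.
    """
    span1 = c_loop_spans["C_Loop1"]
    peak_stats = region_summary(profile, span1)
    in_any_loop = set()
    for lo, hi in c_loop_spans.values():
        in_any_loop.update(range(lo, hi + 1))
    baseline_vals = np.array([
        v
        for i, v in zip(profile.seq_indices, profile.values)
        if i not in in_any_loop and not np.isnan(v)
    ])
    if baseline_vals.size == 0:
        raise EmptySpanError("no baseline residues outside the C_Loops")
    baseline = float(np.median(baseline_vals))
    peak = peak_stats["max"]
    if baseline > 0:
        ratio = peak / baseline
    else:
        ratio = 1.0 if peak == 0 else float("inf")
    return LoopSignal(
        peak=peak,
        peak_index=peak_stats["argmax"],
        baseline=baseline,
        ratio=ratio,
    )


def profiles_to_frame(
    profiles: Sequence[RMSFProfile],
    chains: dict[str, ChainModel] | None = None,
    annotations: dict[str, RegionAnnotation] | None = None,
) -> pd.DataFrame:
    """Tidy long-format table of profiles, ready for CSV export / plotting."""
    rows = []
    for p in profiles:
        chain = (chains or {}).get(p.chain_id)
        ann = (annotations or {}).get(p.chain_id)
        for i, v, w in zip(p.seq_indices, p.values, p.atom_counts):
            rows.append({
                "couple_id": p.couple_id,
                "chain_id": p.chain_id,
                "scope": p.scope,
                "seq_index": i,
                "aa": chain.residue(i).aa if chain else "",
                "region": ann.region_of(i) if ann else "",
                "n_atoms": int(w),
                "rmsf_A": float(v) if not np.isnan(v) else None,
            })
    return pd.DataFrame(rows)


def write_profiles_csv(path: str | Path, profiles: Sequence[RMSFProfile],
                       **kwargs) -> Path:
    path = Path(path)
    profiles_to_frame(profiles, **kwargs).to_csv(path, index=False)
    return path
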