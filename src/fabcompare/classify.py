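"""Per-couple metric assembly and B1/B2/B3 classification.

Binding-induced conformational change falls into three classes:

* **B1** — the Fab's diamond-like shape distorts: the domains keep their
  internal structure but reorient by hinging at the linkers, giving a
  large average hinge-angle change (observed cases sit at 16° and above),
  together with a strong C_Loop1 deviation in the CH1 domain.
* **B2** — the overall shape is preserved (angle changes of a few
  degrees) but the C_Loop1 deviation is still prominent.
* **B3** — only the antigen-contacting CDRs move; no C_Loop1 signal.

The decision rule quantifies that reading: B1 when the average absolute
hinge-angle change reaches ``tau_angle`` (default 10°, between the
observed B1 minimum of 16° and B2 maximum of 4°); otherwise B2 when the
CH1-scope C_Loop1 peak reaches ``tau_loop_peak`` AND the peak-to-baseline
ratio reaches ``tau_loop_ratio``; otherwise B3.  All thresholds are stored
in every report so a stored report re-derives its own label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import RegionScheme
from .geometry import AngleChange, AngleMetrics
from .rmsf import LoopSignal
from .structure_io import ChainModel
from .superpose import fit_scope, scoped_rmsd

REGIONS = ("entire", "variable", "linker", "constant")


@dataclass(frozen=True)
class ClassThresholds:
    """Decision constants for the B1/B2/B3 rule (all must be positive)."""

    tau_angle: float = 10.0        # degrees of average |hinge change| for B1
    tau_loop_peak: float = 1.5     # Å of CH1-scope C_Loop1 peak for B2
    tau_loop_ratio: float = 2.0    # peak / baseline ratio for B2

    def __post_init__(self) -> None:
        if min(self.tau_angle, self.tau_loop_peak, self.tau_loop_ratio) <= 0:
            raise ValueError("classification thresholds must be positive")


def classify_couple(
    average_abs_change: float,
    loop_signal: LoopSignal | None,
    thresholds: ClassThresholds = ClassThresholds(),
) -> str:
    """Assign B1/B2/B3 from the angle summary and the C_Loop1 signal."""
    if not np.isfinite(average_abs_change):
        raise ValueError("average_abs_change must be finite")
    if average_abs_change >= thresholds.tau_angle:
        return "B1"
    if loop_signal is not None and (
        loop_signal.peak >= thresholds.tau_loop_peak
        and loop_signal.ratio >= thresholds.tau_loop_ratio
    ):
        return "B2"
    return "B3"


def rmsd_table(
    free_heavy: ChainModel,
    free_light: ChainModel,
    bound_heavy: ChainModel,
    bound_light: ChainModel,
    scheme: RegionScheme | None = None,
) -> tuple[pd.DataFrame, "SuperpositionResult"]:
    """Region x chain RMSD matrix under a single whole-Fab overlap.

    The fit uses the union of both chains' backbone atoms over the entire
    span; the per-region cells are evaluated under that one transform —
    individual domains are *not* separately optimised here.
    """
    scheme = scheme or RegionScheme()
    transform = fit_scope(
        [free_heavy, free_light], [bound_heavy, bound_light],
        scope=scheme.entire_span, scope_label="whole-Fab",
    )
    data = {}
    for chain_label, f, b in (("heavy", free_heavy, bound_heavy),
                              ("light", free_light, bound_light)):
        col = {}
        for region in REGIONS:
            value, _ = scoped_rmsd(f, b, transform, scheme.span(region))
            col[region] = value
        data[chain_label] = col
    table = pd.DataFrame(data).loc[list(REGIONS)]
    return table, transform


@dataclass
class CoupleReport:
    """Everything measured for one free/bound couple, plus its class."""

    couple_id: str
    angle_metrics_free: AngleMetrics
    angle_metrics_bound: AngleMetrics
    angle_change: AngleChange
    rmsd_table: pd.DataFrame              # regions x {heavy, light}
    c_loop1_signal_heavy: LoopSignal
    c_loop1_signal_light: LoopSignal | None
    class_label: str
    thresholds_used: ClassThresholds
    rmsf_summaries: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def rederive_class(self) -> str:
        """Recompute the label from stored fields only (auditability)."""
        return classify_couple(
            self.angle_change.average_abs_change,
            self.c_loop1_signal_heavy,
            self.thresholds_used,
        )

    def to_dict(self) -> dict:
        return {
            "couple_id": self.couple_id,
            "angle_metrics_free": self.angle_metrics_free.to_dict(),
            "angle_metrics_bound": self.angle_metrics_bound.to_dict(),
            "angle_change": self.angle_change.to_dict(),
            "rmsd_table_A": {c: self.rmsd_table[c].to_dict()
                             for c in self.rmsd_table.columns},
            "c_loop1_signal_heavy": asdict(self.c_loop1_signal_heavy),
            "c_loop1_signal_light": (
                asdict(self.c_loop1_signal_light)
                if self.c_loop1_signal_light else None
            ),
            "class_label": self.class_label,
            "thresholds_used": asdict(self.thresholds_used),
            "rmsf_summaries": self.rmsf_summaries,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_row(self) -> dict:
        """One flat row per couple, mirroring the summary-table columns."""
        return {
            "couple_id": self.couple_id,
            "delta_heavy_deg": self.angle_change.delta_heavy,
            "delta_light_deg": self.angle_change.delta_light,
            "average_abs_change_deg": self.angle_change.average_abs_change,
            "class": self.class_label,
            "c_loop1_peak_A": self.c_loop1_signal_heavy.peak,
            "c_loop1_ratio": self.c_loop1_signal_heavy.ratio,
            "delta_linker_linker_A": self.angle_change.delta_linker_linker,
            "rmsd_entire_heavy_A": self.rmsd_table.loc["entire", "heavy"],
            "rmsd_entire_light_A": self.rmsd_table.loc["entire", "light"],
            "rmsd_variable_heavy_A": self.rmsd_table.loc["variable", "heavy"],
            "rmsd_variable_light_A": self.rmsd_table.loc["variable", "light"],
            "rmsd_constant_heavy_A": self.rmsd_table.loc["constant", "heavy"],
            "rmsd_constant_light_A": self.rmsd_table.loc["constant", "light"],
        }


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def trend_summary(reports: Sequence[CoupleReport], atol: float = 1e-9) -> dict:
    """Tallies of the RMSD inequalities across couples.

    Counts, per couple: whole-chain light vs heavy RMSD; CL vs VL; CH vs
    VH — all read from the whole-Fab-overlap RMSD table.  Exact ties (to
    ``atol``) fall in the "none" bucket.
    """
    if not reports:
        raise ValueError("trend_summary needs at least one report")
    tallies = {
        "light_gt_heavy": 0, "light_lt_heavy": 0, "light_eq_heavy": 0,
        "cl_gt_vl": 0, "cl_lt_vl": 0, "cl_eq_vl": 0,
        "ch_gt_vh": 0, "ch_lt_vh": 0, "ch_eq_vh": 0,
    }
    members: dict[str, list[str]] = {k: [] for k in tallies}

    def _bucket(a, b):
        if abs(a - b) <= atol:
            return "eq"
        return "gt" if a > b else "lt"

    for r in reports:
        t = r.rmsd_table
        cid = r.couple_id
        for key in (
            f"light_{_bucket(t.loc['entire', 'light'], t.loc['entire', 'heavy'])}_heavy",
            f"cl_{_bucket(t.loc['constant', 'light'], t.loc['variable', 'light'])}_vl",
            f"ch_{_bucket(t.loc['constant', 'heavy'], t.loc['variable', 'heavy'])}_vh",
        ):
            tallies[key] += 1
            members[key].append(cid)
    return {"counts": tallies, "couples": members, "n": len(reports)}
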