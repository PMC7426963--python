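"""End-to-end analysis of free/bound Fab couples and batch reporting.

``analyze_couple`` runs the full comparison for one couple: parse both
structures, apply the resolution and continuity filters, pair chains by
100% sequence identity, annotate regions and loops, locate the conserved
anchors, measure hinge angles and distances, build the whole-Fab RMSD
table, compute RMSF profiles (whole-chain plus all four per-domain
scopes), extract the C_Loop1 signal and assign the B1/B2/B3 class.  Every
default and override used (anchor indices, spans, thresholds, dropped
residues, copy selection) is recorded in the report's provenance block.

``run_all`` drives a batch of couples from a single config, producing a
summary table (one row per couple) and the cross-couple RMSD trend
tallies; individual failures are reported without aborting the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .annotate import (
    DEFAULT_C_LOOP_TABLE,
    DEFAULT_CDR_TABLE,
    RegionScheme,
    annotate_c_loops,
    annotate_cdrs,
    assign_regions,
    load_boundary_tables,
)
from .classify import ClassThresholds, CoupleReport, classify_couple, rmsd_table, trend_summary
from .errors import FabCompareError, PairingError, ResolutionError
from .geometry import angle_change, find_anchors, measure_angles
from .rmsf import c_loop1_signal, region_summary, rmsf_profile, write_profiles_csv
from .structure_io import (
    ChainModel,
    check_resolution,
    extract_chain,
    fetch_pdb,
    parse_structure,
    sequence_identity,
)

logger = logging.getLogger(__name__)


@dataclass
class CoupleConfig:
    """Input description of one free/bound couple."""

    couple_id: str
    free: str                       # path to a PDB file, or 4-char accession
    bound: str
    heavy_chain_id: str = "H"
    light_chain_id: str = "L"
    light_chain_type: str = "light_kappa"
    # optional 1-based author-order windows selecting one Fab copy per chain
    fab_copy: dict[str, tuple[int, int]] = dc_field(default_factory=dict)
    # anchor overrides: {"free_heavy": {"v_cys": 92, ...}, "bound_light": ...}
    anchor_overrides: dict[str, dict[str, int]] = dc_field(default_factory=dict)

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "CoupleConfig":
        fab_copy = {
            k: tuple(v) for k, v in (m.get("fab_copy") or {}).items()
        }
        return cls(
            couple_id=m.get("couple_id") or f"{m['free']}/{m['bound']}",
            free=str(m["free"]),
            bound=str(m["bound"]),
            heavy_chain_id=str(m.get("heavy_chain_id", "H")),
            light_chain_id=str(m.get("light_chain_id", "L")),
            light_chain_type=str(m.get("light_chain_type", "light_kappa")),
            fab_copy=fab_copy,
            anchor_overrides={k: dict(v) for k, v in
                              (m.get("anchor_overrides") or {}).items()},
        )


@dataclass
class RunConfig:
    """Batch configuration: couples plus shared analysis settings."""

    couples: list[CoupleConfig]
    scheme: RegionScheme = dc_field(default_factory=RegionScheme)
    cdr_table: dict = dc_field(default_factory=lambda: DEFAULT_CDR_TABLE)
    c_loop_table: dict = dc_field(
        default_factory=lambda: DEFAULT_C_LOOP_TABLE)
    thresholds: ClassThresholds = dc_field(default_factory=ClassThresholds)
    max_resolution: float = 3.0
    output_dir: Path | None = None
    cache_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        couples = [CoupleConfig.from_mapping(c) for c in data.get("couples", [])]
        scheme = RegionScheme()
        if "regions" in data:
            r = data["regions"]
            scheme = RegionScheme(
                variable_span=tuple(r["variable"]),
                linker_span=tuple(r["linker"]),
                constant_span=tuple(r["constant"]),
            )
        thresholds = ClassThresholds(**data.get("thresholds", {}))
        tables = {
            "cdr": DEFAULT_CDR_TABLE,
            "c_loop": DEFAULT_C_LOOP_TABLE,
        }
        if "boundaries" in data and data["boundaries"]:
            tables = load_boundary_tables(data["boundaries"]) \
                if isinstance(data["boundaries"], str) else _tables_from_mapping(
                    data["boundaries"])
        return cls(
            couples=couples,
            scheme=scheme,
            cdr_table=tables["cdr"],
            c_loop_table=tables["c_loop"],
            thresholds=thresholds,
            max_resolution=float(data.get("max_resolution", 3.0)),
            output_dir=Path(data["output_dir"]) if data.get("output_dir") else None,
            cache_dir=Path(data["cache_dir"]) if data.get("cache_dir") else None,
        )


def _tables_from_mapping(data: Mapping) -> dict:
    def _conv(section, defaults):
        table = {k: dict(v) for k, v in defaults.items()}
        for ct, spans in (section or {}).items():
            table.setdefault(ct, {})
            for name, span in spans.items():
                table[ct][name] = (int(span[0]), int(span[1]))
        return table
    return {
        "cdr": _conv(data.get("cdr"), DEFAULT_CDR_TABLE),
        "c_loop": _conv(data.get("c_loop"), DEFAULT_C_LOOP_TABLE),
    }


def _load_structure(source: str, label: str, cache_dir: Path | None):
    p = Path(source)
    if p.exists():
        return parse_structure(p.read_text(), entry_id=p.stem.upper())
    if len(source) == 4 and source.isalnum():
        return parse_structure(fetch_pdb(source, cache_dir=cache_dir),
                               entry_id=source.upper())
    raise FileNotFoundError(f"{label}: '{source}' is neither an existing file "
                            "nor a 4-character PDB accession")


def _prepare_fab(record, cfg: CoupleConfig, form: str) -> dict[str, ChainModel]:
    chains = {}
    for role, chain_id, chain_type in (
        ("heavy", cfg.heavy_chain_id, "heavy"),
        ("light", cfg.light_chain_id, cfg.light_chain_type),
    ):
        span = cfg.fab_copy.get(f"{form}_{role}") or cfg.fab_copy.get(role)
        if span is not None:
            logger.info("%s %s/%s: selecting Fab copy window %s",
                        cfg.couple_id, form, role, span)
        chains[role] = extract_chain(record, chain_id, chain_type, span=span)
    return chains


def analyze_couple(
    cfg: CoupleConfig,
    scheme: RegionScheme | None = None,
    cdr_table: Mapping | None = None,
    c_loop_table: Mapping | None = None,
    thresholds: ClassThresholds = ClassThresholds(),
    max_resolution: float = 3.0,
    output_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
) -> CoupleReport:
    """Full analysis of one couple described by ``cfg``.

    Raises :class:`ResolutionError` when a structure fails the resolution
    filter and :class:`PairingError` when the free and bound chains are
    not 100% identical in sequence; parse/continuity/anchor errors
    propagate with couple context.
    """
    free_rec = _load_structure(cfg.free, f"{cfg.couple_id} free", cache_dir)
    bound_rec = _load_structure(cfg.bound, f"{cfg.couple_id} bound", cache_dir)
    for rec in (free_rec, bound_rec):
        verdict = check_resolution(rec, max_resolution)
        if not verdict.passed:
            raise ResolutionError(
                f"{cfg.couple_id}: {rec.entry_id} resolution "
                f"{verdict.resolution:.2f} Å exceeds {max_resolution} Å"
            )
    free = _prepare_fab(free_rec, cfg, "free")
    bound = _prepare_fab(bound_rec, cfg, "bound")

    for role in ("heavy", "light"):
        ident = sequence_identity(free[role], bound[role])
        if ident < 1.0:
            raise PairingError(
                f"{cfg.couple_id}: {role} chains share only "
                f"{100 * ident:.1f}% sequence identity; couples require 100%"
            )

    return analyze_prepared_couple(
        cfg.couple_id, free["heavy"], free["light"],
        bound["heavy"], bound["light"],
        scheme=scheme, cdr_table=cdr_table, c_loop_table=c_loop_table,
        thresholds=thresholds, anchor_overrides=cfg.anchor_overrides,
        output_dir=output_dir,
        extra_provenance={
            "free_entry": free_rec.entry_id,
            "bound_entry": bound_rec.entry_id,
            "free_resolution_A": free_rec.resolution,
            "bound_resolution_A": bound_rec.resolution,
            "fab_copy_selection": {k: list(v) for k, v in cfg.fab_copy.items()},
        },
    )


def analyze_prepared_couple(
    couple_id: str,
    free_heavy: ChainModel,
    free_light: ChainModel,
    bound_heavy: ChainModel,
    bound_light: ChainModel,
    scheme: RegionScheme | None = None,
    cdr_table: Mapping | None = None,
    c_loop_table: Mapping | None = None,
    thresholds: ClassThresholds = ClassThresholds(),
    anchor_overrides: Mapping[str, Mapping[str, int]] | None = None,
    output_dir: str | Path | None = None,
    extra_provenance: Mapping | None = None,
) -> CoupleReport:
    """Analysis core for already-prepared chains (used by tests/synthetics)."""
    scheme = scheme or RegionScheme()
    anchor_overrides = anchor_overrides or {}
    chains = {
        ("free", "heavy"): free_heavy, ("free", "light"): free_light,
        ("bound", "heavy"): bound_heavy, ("bound", "light"): bound_light,
    }
    annotations = {}
    anchors = {}
    for (form, role), chain in chains.items():
        a = assign_regions(chain, scheme)
        annotate_cdrs(a, cdr_table)
        annotate_c_loops(a, c_loop_table)
        annotations[(form, role)] = a
        anchors[(form, role)] = find_anchors(
            chain, a, overrides=anchor_overrides.get(f"{form}_{role}"))

    metrics_free = measure_angles(anchors[("free", "heavy")],
                                  anchors[("free", "light")])
    metrics_bound = measure_angles(anchors[("bound", "heavy")],
                                   anchors[("bound", "light")])
    change = angle_change(metrics_free, metrics_bound)

    table, fab_fit = rmsd_table(free_heavy, free_light,
                                bound_heavy, bound_light, scheme)

    profiles = []
    rmsf_summaries: dict[str, dict] = {}
    domain_profiles = {}
    for role, f, b in (("heavy", free_heavy, bound_heavy),
                       ("light", free_light, bound_light)):
        whole = rmsf_profile(f, b, scope_span=None, scope_label="whole-chain",
                             couple_id=couple_id)
        profiles.append(whole)
        rmsf_summaries[f"{role}_whole_chain"] = region_summary(
            whole, scheme.entire_span)
        for region in ("variable", "constant"):
            label = {"variable": "V", "constant": "C"}[region] + \
                ("H" if role == "heavy" else "L")
            prof = rmsf_profile(f, b, scope_span=scheme.span(region),
                                scope_label=label, couple_id=couple_id)
            profiles.append(prof)
            domain_profiles[label] = prof
            rmsf_summaries[f"{role}_{region}_domain_scope"] = region_summary(
                prof, scheme.span(region))

    loop_heavy = c_loop1_signal(
        domain_profiles["CH"], annotations[("free", "heavy")].c_loop_spans)
    loop_light = c_loop1_signal(
        domain_profiles["CL"], annotations[("free", "light")].c_loop_spans)

    label = classify_couple(change.average_abs_change, loop_heavy, thresholds)

    provenance = {
        "region_scheme": {
            "variable": list(scheme.variable_span),
            "linker": list(scheme.linker_span),
            "constant": list(scheme.constant_span),
        },
        "cdr_spans": {
            role: {k: list(v) for k, v in
                   annotations[("free", role)].cdr_spans.items()}
            for role in ("heavy", "light")
        },
        "c_loop_spans": {
            role: {k: list(v) for k, v in
                   annotations[("free", role)].c_loop_spans.items()}
            for role in ("heavy", "light")
        },
        "anchors": {
            f"{form}_{role}": list(anchors[(form, role)].indices)
            for form in ("free", "bound") for role in ("heavy", "light")
        },
        "anchor_overrides": {k: dict(v) for k, v in anchor_overrides.items()},
        "whole_fab_fit_n_atoms": fab_fit.n_atoms,
        "whole_fab_fit_residues_dropped": fab_fit.n_residues_dropped,
    }
    if extra_provenance:
        provenance.update(extra_provenance)

    report = CoupleReport(
        couple_id=couple_id,
        angle_metrics_free=metrics_free,
        angle_metrics_bound=metrics_bound,
        angle_change=change,
        rmsd_table=table,
        c_loop1_signal_heavy=loop_heavy,
        c_loop1_signal_light=loop_light,
        class_label=label,
        thresholds_used=thresholds,
        rmsf_summaries=rmsf_summaries,
        provenance=provenance,
    )

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        safe_id = couple_id.replace("/", "_")
        report.to_json(output_dir / f"{safe_id}_report.json")
        write_profiles_csv(
            output_dir / f"{safe_id}_rmsf.csv", profiles,
            chains={"H": free_heavy, "L": free_light},
            annotations={
                free_heavy.chain_id: annotations[("free", "heavy")],
                free_light.chain_id: annotations[("free", "light")],
            },
        )
    return report


def run_all(config: RunConfig) -> dict:
    """Analyse every couple in the config; never abort on one failure.

    Returns ``{"summary": DataFrame, "reports": [...], "failures": {...},
    "trends": {...}}``; writes summary CSV and per-couple outputs when the
    config names an output directory.  Row order follows config order.
    """
    if not config.couples:
        raise ValueError("config lists no couples")
    reports: list[CoupleReport] = []
    failures: dict[str, str] = {}
    for couple_cfg in config.couples:
        try:
            reports.append(analyze_couple(
                couple_cfg,
                scheme=config.scheme,
                cdr_table=config.cdr_table,
                c_loop_table=config.c_loop_table,
                thresholds=config.thresholds,
                max_resolution=config.max_resolution,
                output_dir=config.output_dir,
                cache_dir=config.cache_dir,
            ))
        except (FabCompareError, FileNotFoundError, OSError) as exc:
            logger.error("%s failed: %s", couple_cfg.couple_id, exc)
            failures[couple_cfg.couple_id] = str(exc)
    if not reports:
        raise FabCompareError(
            "all couples failed: " + "; ".join(failures.values()))
    summary = pd.DataFrame([r.summary_row() for r in reports])
    trends = trend_summary(reports)
    if config.output_dir is not None:
        config.output_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(config.output_dir / "summary.csv", index=False)
        pd.Series(trends["counts"]).to_csv(
            config.output_dir / "rmsd_trends.csv", header=["count"])
    return {"summary": summary, "reports": reports,
            "failures": failures, "trends": trends}
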