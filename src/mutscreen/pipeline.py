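"""Whole-funnel orchestration from a single YAML config.

Stages: simulate (or load user files) -> classify variants into a disruptive
mutation matrix -> normalize counts -> mutation-stratified expression screen
-> best-cutoff survival scan of the selected genes -> druggability filter.
Every stage writes its artifact under the run directory and the funnel counts
are collected into a :class:`FunnelReport`; a manifest records inputs,
parameters and the seed so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .druggability import filter_actionable, load_druggability_table
from .io import (
    read_count_matrix, read_mutation_matrix, read_survival_table,
    write_count_matrix, write_frame, write_mutation_matrix, write_size_factors,
    write_survival_table,
)
from .normalize import estimate_size_factors, normalize_counts
from .screen import ScreenParams, run_screen
from .simulate import SyntheticCohortConfig, generate_cohort, generate_variant_records
from .survival import best_cutoff_scan, kaplan_meier
from .variants import (
    MutationCategory, apply_quality_filters, build_mutation_matrix,
    parse_vcf_dir, select_canonical,
)

logger = logging.getLogger(__name__)

__all__ = ["FunnelReport", "run_pipeline", "write_km_plot_data", "default_config"]


@dataclass
class FunnelReport:
    """Per-driver gene counts at each funnel stage plus overall totals.

    Within each driver the counts are non-increasing along
    tested -> significant_up -> selected, and selected partitions into the
    survival outcome classes plus genes missing from the survival input.
    """

    per_driver: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)

    def finalize(self):
        keys = ["tested", "significant_up", "selected", "worse", "better",
                "not_significant", "missing", "actionable"]
        self.totals = {k: sum(d.get(k, 0) for d in self.per_driver.values())
                       for k in keys}
        for driver, d in self.per_driver.items():
            if not (d["tested"] >= d["significant_up"] >= d["selected"]):
                raise AssertionError(f"funnel counts not monotone for {driver}: {d}")
        return self

    def to_json(self) -> str:
        return json.dumps({"per_driver": self.per_driver, "totals": self.totals},
                          indent=1, sort_keys=True)


def default_config(out_dir="runs/demo", seed=0) -> dict:
    """A complete synthetic-cohort pipeline config (every published threshold
    as a named key with its default)."""
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "simulate": {"enabled": True},
        "classify": {"min_depth": 40, "min_alt_reads": 5,
                     "category": "disruptive", "exclude": ["TTN"], "top_drivers": 10},
        "screen": {"alpha": 0.01, "fc_cutoff": 1.44, "top_k": 50,
                   "pseudocount": 0.5, "direction": "up"},
        "survival": {"statistic": "cox", "alpha": 0.05},
        "druggable": {"table": None},
    }


_SCHEMA_KEYS = {"seed", "out_dir", "simulate", "classify", "screen", "survival",
                "druggable", "inputs"}


def _validate_config(cfg: dict):
    unknown = set(cfg) - _SCHEMA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in cfg:
        raise ValueError("config requires out_dir")
    inputs = cfg.get("inputs", {})
    if not cfg.get("simulate", {}).get("enabled", False):
        for key in ("vcf_dir", "counts", "survival"):
            if key not in inputs:
                raise ValueError(f"config without simulate.enabled requires inputs.{key}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"inputs.{key}: no such path {inputs[key]}")
    table = cfg.get("druggable", {}).get("table")
    if table is not None and not Path(table).exists():
        raise FileNotFoundError(f"druggable.table: no such path {table}")


def run_pipeline(config) -> FunnelReport:
    """Run the full funnel from a YAML path or config dict; returns the
    funnel report (also written as ``funnel.json`` in the run directory)."""
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    ccfg = cfg.get("classify", {})
    scfg = cfg.get("screen", {})
    vcfg = cfg.get("survival", {})

    # ----- stage: inputs (synthetic or user files)
    if cfg.get("simulate", {}).get("enabled", False):
        sim_kwargs = {k: v for k, v in cfg.get("simulate", {}).items()
                      if k not in ("enabled",)}
        sim_cfg = SyntheticCohortConfig(seed=seed, **sim_kwargs)
        cohort = generate_cohort(sim_cfg, seed=seed)
        vcf_dir = out / "vcf"
        _, truth = generate_variant_records(sim_cfg, seed=seed, out_dir=vcf_dir)
        (out / "ground_truth.json").write_text(truth.to_json())
        counts = cohort.counts
        survival = cohort.survival
        patient_ids = sim_cfg.patient_ids
        gene_universe = sim_cfg.mutation_genes
        write_count_matrix(counts, out / "counts.tsv")
        write_survival_table(survival, out / "survival.tsv")
    else:
        inputs = cfg["inputs"]
        vcf_dir = Path(inputs["vcf_dir"])
        counts = read_count_matrix(inputs["counts"])
        survival = read_survival_table(inputs["survival"])
        patient_ids = list(counts.columns)
        gene_universe = None  # derive from annotations

    # ----- stage: classify
    variants = parse_vcf_dir(vcf_dir, sample_map=cfg.get("inputs", {}).get("sample_map"))
    variants = apply_quality_filters(variants,
                                     min_depth=int(ccfg.get("min_depth", 40)),
                                     min_alt_reads=int(ccfg.get("min_alt_reads", 5)))
    variants = select_canonical(variants)
    if gene_universe is None:
        gene_universe = sorted({a.gene_symbol for v in variants for a in v.annotations})
    matrix = build_mutation_matrix(variants,
                                   MutationCategory(ccfg.get("category", "disruptive")),
                                   patient_ids, gene_universe)
    write_mutation_matrix(matrix, out / "mutation_matrix.tsv")
    from .variants import rank_mutation_frequency
    ranking = rank_mutation_frequency(matrix, exclude=ccfg.get("exclude", ["TTN"]),
                                      top_k=int(ccfg.get("top_drivers", 10)))
    write_frame(ranking, out / "driver_ranking.tsv")
    drivers = list(ranking["gene"])

    # ----- stage: normalize
    sf = estimate_size_factors(counts, poscounts=bool(cfg.get("simulate", {})
                                                      .get("enabled", False)))
    normalized = normalize_counts(counts, sf)
    write_size_factors(sf, out / "size_factors.tsv")
    write_count_matrix(normalized.values, out / "normalized.tsv")

    # ----- stage: screen
    params = ScreenParams(
        alpha=float(scfg.get("alpha", 0.01)),
        fc_cutoff=float(scfg.get("fc_cutoff", 1.44)),
        top_k=int(scfg.get("top_k", 50)),
        pseudocount=float(scfg.get("pseudocount", 0.5)),
        direction=scfg.get("direction", "up"),
    )
    screen_res = run_screen(normalized, matrix, drivers, params)
    for driver, grp in screen_res.records.groupby("driver_gene"):
        write_frame(grp, out / "screen" / f"{driver}.tsv")

    # ----- stage: survival scan on the selected genes
    surv_alpha = float(vcfg.get("alpha", 0.05))
    statistic = vcfg.get("statistic", "cox")
    expr_index = set(normalized.values.index)
    scan_rows = []
    report = FunnelReport()
    scanned: dict = {}
    for driver in drivers:
        sel = screen_res.selected.get(driver, [])
        sub = screen_res.records[screen_res.records["driver_gene"] == driver]
        counts_d = {
            "tested": int(len(sub)),
            "significant_up": int(sub["significant"].sum()),
            "selected": len(sel),
            "worse": 0, "better": 0, "not_significant": 0, "missing": 0,
            "actionable": 0,
        }
        for gene in sel:
            if gene not in expr_index:
                counts_d["missing"] += 1
                continue
            if gene not in scanned:
                scanned[gene] = best_cutoff_scan(
                    normalized.values.loc[gene], survival,
                    statistic=statistic, alpha=surv_alpha, gene=gene)
            res = scanned[gene]
            counts_d[res.outcome_class] += 1
            scan_rows.append({"driver_gene": driver, **dataclasses.asdict(res)})
        report.per_driver[driver] = counts_d
    scan_df = pd.DataFrame(scan_rows)
    write_frame(scan_df, out / "survival_scan.tsv")

    # ----- stage: druggability
    table_path = cfg.get("druggable", {}).get("table")
    worse_by_driver = {
        d: [r["gene"] for r in scan_rows
            if r["driver_gene"] == d and r["outcome_class"] == "worse"]
        for d in drivers
    }
    if table_path:
        table = load_druggability_table(table_path)
        actionable_rows = []
        for driver in drivers:
            worse = worse_by_driver[driver]
            if not worse:
                continue
            actionable, evidence = filter_actionable(worse, table)
            report.per_driver[driver]["actionable"] = len(actionable)
            for g in actionable:
                actionable_rows.append({"driver_gene": driver, "gene": g})
        write_frame(pd.DataFrame(actionable_rows), out / "actionable.tsv")

    # ----- KM coordinates + report + manifest
    write_km_plot_data(list(scanned.values()), normalized.values, survival,
                       out / "km")
    report.finalize()
    (out / "funnel.json").write_text(report.to_json())
    manifest = {"config": cfg, "seed": seed, "mutscreen_version": __version__,
                "n_patients": len(patient_ids), "n_genes_expression": int(len(counts)),
                "drivers": drivers}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                  default=str))
    return report


def write_km_plot_data(scan_results, expression: pd.DataFrame,
                       survival: pd.DataFrame, out_dir) -> list:
    """Write per-gene two-curve Kaplan–Meier coordinates (plot-library-
    agnostic TSV: group, time, survival, n_at_risk); returns written paths."""
    out_dir = Path(out_dir)
    surv = survival.set_index("patient_id")
    paths = []
    for res in scan_results:
        gene = res.gene
        if gene not in expression.index:
            continue
        expr = expression.loc[gene]
        common = [p for p in surv.index if p in expr.index]
        high = expr.loc[common].to_numpy() > res.best_cutoff
        times = surv.loc[common, "time_months"].to_numpy(dtype=float)
        events = surv.loc[common, "event"].to_numpy(dtype=int)
        rows = []
        for label, mask in (("high", high), ("low", ~high)):
            if mask.sum() == 0:
                continue
            t, s = kaplan_meier(times[mask], events[mask])
            at_risk = [(times[mask] >= ti).sum() for ti in t]
            for ti, si, ri in zip(t, s, at_risk):
                rows.append({"group": label, "time": ti, "survival": si,
                             "n_at_risk": ri})
        path = out_dir / f"{gene}.tsv"
        write_frame(pd.DataFrame(rows), path)
        paths.append(path)
    return paths
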