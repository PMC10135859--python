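"""Configuration and orchestration of the full selection workflow.

Stages: uniformity screening over one or more expression datasets →
composite shortlist with CV filter → (optional) primer-pair vetting →
(optional) assay QC gate → expression-stability consensus on Cq data.
Stages run only when their inputs are configured; each writes its own TSV
report plus a JSON summary into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assay_qc, io, primer_rules, screening, stability, synthetic

logger = logging.getLogger("refgenekit")

__all__ = ["PipelineConfig", "run_selection_pipeline", "simulate_workspace"]


@dataclass
class PipelineConfig:
    """Paths and thresholds of a pipeline run; unset inputs skip their stage."""

    out_dir: str = "refgenekit_out"
    seed: int = 0
    # screening inputs
    datasets: list[dict] = field(default_factory=list)
    # each: {path, format: series_matrix|tsv, groups, platform?, symbol_column?, dataset_id?}
    candidates: str | None = None
    shortlist_size: int = 18
    cv_threshold: float = 45.0
    significance: float = 0.05
    collapse_rule: str = "min_padj"
    # primer inputs
    primer_table: str | None = None
    primer_policy: dict = field(default_factory=dict)
    # assay QC inputs
    dilution_table: str | None = None
    replicates_table: str | None = None
    efficiency_min: float = 90.0
    efficiency_max: float = 110.0
    min_logs: int = 5
    # stability inputs
    cq_table: str | None = None
    cq_groups: str | None = None
    efficiency_table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_dataset(spec: dict) -> screening.ExpressionDataset:
    fmt = spec.get("format", "series_matrix")
    if fmt == "series_matrix":
        ds = io.parse_series_matrix(spec["path"])
    elif fmt == "tsv":
        ds = io.read_expression_tsv(spec["path"], dataset_id=spec.get("dataset_id"))
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")
    if spec.get("dataset_id"):
        ds.dataset_id = spec["dataset_id"]
    if spec.get("groups"):
        ds.groups = io.read_groups_tsv(spec["groups"])
    if spec.get("platform"):
        platform = io.parse_platform_table(spec["platform"])
        ds.probe_to_gene = io.map_probes_to_genes(
            platform, spec.get("symbol_column", "GENE_SYMBOL")
        )
        # re-normalise through the dataclass hook
        ds.__post_init__()
    return ds


def _screen_stage(config: PipelineConfig, out: Path) -> dict:
    if not config.candidates:
        raise ValueError("screening requested but 'candidates' path is not set")
    candidates = io.read_candidate_list(config.candidates)
    datasets = [_load_dataset(spec) for spec in config.datasets]
    report, records = screening.screen_datasets(
        datasets,
        candidates,
        shortlist_size=config.shortlist_size,
        cv_threshold=config.cv_threshold,
        significance=config.significance,
        collapse_rule=config.collapse_rule,
    )
    report.to_csv(out / "screen_report.tsv", sep="\t")
    summary = {
        "n_candidates": len(candidates),
        "n_missing": sum(r.status == "missing_in_some_dataset" for r in records.values()),
        "n_cv_excluded": sum(r.status == "excluded_cv" for r in records.values()),
        "shortlisted": [g for g, r in records.items() if r.status == "shortlisted"],
    }
    (out / "screen_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("screening: %d candidates, %d shortlisted",
                summary["n_candidates"], len(summary["shortlisted"]))
    return summary


def _primer_stage(config: PipelineConfig, out: Path) -> dict:
    records = io.read_primer_table(config.primer_table)
    policy = primer_rules.PrimerPolicy(**config.primer_policy)
    by_gene: dict[str, list] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    rows, summary = [], {}
    for gene, cands in by_gene.items():
        result = primer_rules.select_first_passing(cands, policy)
        summary[gene] = {
            "found": result.found,
            "chosen_index": result.chosen_index,
            "relaxation_stage": result.relaxation_stage,
        }
        rows.extend(result.audit)
    io.pd.DataFrame(rows).to_csv(out / "primer_audit.tsv", sep="\t", index=False)
    (out / "primer_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _qc_stage(config: PipelineConfig, out: Path) -> dict:
    series = io.read_dilution_tsv(config.dilution_table)
    fits = {}
    for gene, ds in series.items():
        fit = assay_qc.fit_standard_curve(ds)
        fit.n_logs_linear, fit.dynamic_range_ok = assay_qc.assess_dynamic_range(ds)
        fits[gene] = fit
    gate = assay_qc.qc_gate(
        fits,
        efficiency_min=config.efficiency_min,
        efficiency_max=config.efficiency_max,
        min_logs=config.min_logs,
    )
    rows = []
    for gene, fit in fits.items():
        rows.append(
            {
                "gene": gene,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "efficiency_percent": fit.efficiency_percent,
                "n_logs_linear": fit.n_logs_linear,
                "pass": gate[gene]["pass"],
                "reasons": ",".join(gate[gene]["reasons"]),
            }
        )
    if config.replicates_table:
        reps = io.read_replicates_tsv(config.replicates_table)
        by_gene: dict[str, list] = {}
        for s in reps:
            by_gene.setdefault(s.gene, []).append(s)
        cv = {
            g: assay_qc.pooled_replicate_cv(sets) for g, sets in by_gene.items()
        }
        for row in rows:
            row["replicate_cv_percent"] = cv.get(row["gene"], np.nan)
    io.pd.DataFrame(rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    summary = {g: gate[g] for g in gate}
    (out / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stability_stage(config: PipelineConfig, out: Path) -> dict:
    cq = io.read_cq_table(
        config.cq_table,
        groups_path=config.cq_groups,
        efficiency_path=config.efficiency_table,
    )
    result = stability.rank_stability(cq)
    result.report().to_csv(out / "stability_report.tsv", sep="\t")
    summary = {
        "final_ranking": list(result.consensus.index),
        "genorm_exclusion_order": result.genorm_exclusion_order,
        "genorm_pairwise_v": result.genorm_pairwise_v,
    }
    (out / "stability_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_selection_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the per-stage summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages = [
        ("screening", bool(config.datasets), _screen_stage),
        ("primers", bool(config.primer_table), _primer_stage),
        ("assay_qc", bool(config.dilution_table), _qc_stage),
        ("stability", bool(config.cq_table), _stability_stage),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            logger.info("stage %s skipped (no inputs configured)", name)
            continue
        try:
            results[name] = fn(config, out)
        except (ValueError, io.ParseError) as exc:
            raise RuntimeError(f"stage {name}: {exc}") from exc
    return results


def simulate_workspace(out_dir, seed: int = 0) -> PipelineConfig:
    """Write a complete demo workspace of simulated inputs and its config.

    The simulated study mirrors the shape of the real one: two expression
    datasets (a two-group case/control design and a five-group multi-stage
    design) screened for 36 candidates — 10 uniform, 8 uniform but
    over-dispersed (they reach the top-18 shortlist and fall to the CV
    filter), 18 differential; a 15-assay dilution battery in which two
    candidate assays fail the efficiency gate (one running hot at ~124%) and
    one fails the 5-log range, leaving 7 candidates plus 5 "classical" genes;
    a 12-gene Cq panel with stable candidates and noisy, group-shifted
    classical genes; technical replicates; and a primer-candidate table
    exercising the 15-failure relaxation walk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    uniform = tuple(f"STAB{i + 1}" for i in range(10))
    high_cv = tuple(f"WIDE{i + 1}" for i in range(8))
    de = {f"DIFF{i + 1}": 4.0 for i in range(18)}
    base = dict(
        planted_uniform=uniform, planted_high_cv=high_cv, planted_de=de,
        probe_multiplicity=2,
    )
    cfg_a = synthetic.SimulationConfig(seed=seed, n_groups=2, n_per_group=7, **base)
    cfg_b = synthetic.SimulationConfig(seed=seed + 1, n_groups=5, n_per_group=8, **base)
    ds_specs = []
    for cfg, ds_id in ((cfg_a, "SIMSET1"), (cfg_b, "SIMSET2")):
        ds, _truth = synthetic.simulate_expression_dataset(cfg, dataset_id=ds_id)
        io.write_series_matrix(ds, out / f"{ds_id}.txt")
        io.write_groups_tsv(ds.groups, out / f"{ds_id}_groups.tsv")
        platform = io.pd.DataFrame(
            {
                "ID": list(ds.probe_to_gene),
                "GENE_SYMBOL": ["///".join(g) for g in ds.probe_to_gene.values()],
            }
        )
        platform.to_csv(out / f"{ds_id}_platform.tsv", sep="\t", index=False)
        ds_specs.append(
            {
                "path": str(out / f"{ds_id}.txt"),
                "format": "series_matrix",
                "dataset_id": ds_id,
                "groups": str(out / f"{ds_id}_groups.tsv"),
                "platform": str(out / f"{ds_id}_platform.tsv"),
                "symbol_column": "GENE_SYMBOL",
            }
        )
    io.write_candidate_list(
        sorted(uniform) + sorted(high_cv) + sorted(de), out / "candidates.txt"
    )

    stable = {f"STAB{i + 1}": 0.1 for i in range(7)}
    unstable = {f"CLASSIC{i + 1}": 1.0 for i in range(5)}
    cq_cfg = synthetic.SimulationConfig(
        seed=seed + 2,
        n_groups=2,
        n_per_group=6,
        cq_noise_sd={**stable, **unstable},
        cq_group_shift={g: 1.5 for g in unstable},
    )
    cq, _ = synthetic.simulate_cq_matrix(cq_cfg)
    io.write_cq_table(cq, out / "cq.tsv")
    io.write_groups_tsv(cq.groups, out / "cq_groups.tsv")

    assay_plan = {f"STAB{i + 1}": (2.0, False) for i in range(10)}
    assay_plan["STAB8"] = (2.237, False)   # ~123.7% efficiency, fails the gate
    assay_plan["STAB9"] = (1.7, False)     # ~70% efficiency, fails the gate
    assay_plan["STAB10"] = (2.0, True)     # 4-log assay (most dilute level drops out)
    assay_plan.update({g: (2.0, False) for g in unstable})
    dilutions = {
        gene: synthetic.simulate_dilution_series(
            gene, e_true=e, noise_sd=0.05, dropout_most_dilute=drop, seed=seed + 3
        )
        for gene, (e, drop) in assay_plan.items()
    }
    io.write_dilution_tsv(dilutions, out / "dilutions.tsv")

    reps = []
    for gene in dilutions:
        reps.extend(
            synthetic.simulate_replicates(gene, cv_target=0.8, n=3, runs=3, seed=seed + 4)
        )
    io.write_replicates_tsv(reps, out / "replicates.tsv")

    schedule = ["snp_3prime"] * 15 + ["snp_3prime_rare"]
    records, _ = synthetic.simulate_primer_table(schedule, gene="STAB1", seed=seed + 5)
    clean, _ = synthetic.simulate_primer_table(["pass"], gene="STAB2", seed=seed + 6)
    io.write_primer_table(records + clean, out / "primers.tsv")

    config = PipelineConfig(
        out_dir=str(out / "reports"),
        seed=seed,
        datasets=ds_specs,
        candidates=str(out / "candidates.txt"),
        primer_table=str(out / "primers.tsv"),
        dilution_table=str(out / "dilutions.tsv"),
        replicates_table=str(out / "replicates.tsv"),
        cq_table=str(out / "cq.tsv"),
        cq_groups=str(out / "cq_groups.tsv"),
    )
    (out / "config.yaml").write_text(
        yaml.safe_dump(
            {k: getattr(config, k) for k in config.__dataclass_fields__},
            sort_keys=False,
        )
    )
    return config
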