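"""Synthetic study generators with known ground truth.

Every pipeline stage can be exercised without downloads: multi-group
expression matrices with planted uniform / differential / high-dispersion
genes (stand-ins for the GEO-style case-control and multi-stage cohort
designs), Cq matrices with a planted stability ordering, dilution series with
known amplification efficiency, technical replicates with a target CV, and
primer-candidate tables scheduled to violate specific exclusion rules.

All generators are bit-reproducible from (seed, config).  Noise models are
the field's standard ones: Gaussian on log2 intensities and on Cq cycles;
dropout is a missing Cq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from zlib import crc32

from .assay_qc import DilutionSeries, ReplicateSet
from .primer_rules import (
    EditingSite,
    PrimerPairRecord,
    SnpAnnotation,
)
from .screening import ExpressionDataset
from .stability import CqMatrix

__all__ = [
    "SimulationConfig",
    "simulate_expression_dataset",
    "simulate_cq_matrix",
    "simulate_dilution_series",
    "simulate_replicates",
    "simulate_primer_table",
]


@dataclass
class SimulationConfig:
    """Ground-truth layout of a simulated study.

    Expression fields: ``planted_uniform`` genes have zero group effect with
    ``noise_sd`` log2 noise; ``planted_high_cv`` genes are also uniform but
    with ``high_cv_noise_sd`` log2 noise (linear CV well above the 45%
    screening threshold); ``planted_de`` maps genes to group-shift effect
    sizes in units of the residual SD.  ``probe_multiplicity`` probes are
    emitted per gene, plus ``n_background_probes`` unmapped null probes so
    the platform-wide variance moderation and BH adjustment see a realistic
    ensemble.

    Cq fields: ``cq_noise_sd`` maps genes to per-gene cycle noise (default
    0.1 for stable, 1.0 for unstable genes), ``cq_group_shift`` maps genes to
    between-group cycle shifts, ``cq_baseline`` is the centre of the per-gene
    baseline Cq range.
    """

    seed: int = 0
    n_groups: int = 2
    n_per_group: int = 10
    planted_uniform: tuple[str, ...] = ()
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_high_cv: tuple[str, ...] = ()
    noise_sd: float = 0.25            # log2 units
    high_cv_noise_sd: float = 1.3     # log2 units; linear CV ~ 110%
    sample_scaling_sd: float = 0.1    # per-sample loading offset, log2
    probe_multiplicity: int = 1
    n_background_probes: int = 200
    cq_baseline: float = 26.0         # cycles
    cq_noise_sd: dict[str, float] = field(default_factory=dict)
    cq_group_shift: dict[str, float] = field(default_factory=dict)
    cq_sample_effect_sd: float = 0.3  # cycles, shared RT/loading effect

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if any(e < 0 for e in self.planted_de.values()):
            raise ValueError("effect sizes must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _group_labels(config: SimulationConfig) -> dict[str, str]:
    groups = {}
    for g in range(config.n_groups):
        for i in range(config.n_per_group):
            groups[f"S{g * config.n_per_group + i + 1:03d}"] = f"grp{g + 1}"
    return groups


def simulate_expression_dataset(
    config: SimulationConfig, dataset_id: str = "SIM1"
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Linear-scale intensity matrix with planted uniform/DE/high-CV genes.

    Intensities are log-normal: per-gene baseline log2 level ~ U(6, 12),
    per-sample scaling offset, Gaussian log2 noise, and for DE genes a group
    shift of ``effect x noise_sd`` log2 units applied to the later half of
    the groups.  Returns the dataset (linear scale, so the auto-log heuristic
    fires, as with typical microarray matrices) and a per-gene truth table.
    """
    rng = config.rng(1)
    groups = _group_labels(config)
    samples = list(groups)
    labels = np.array(list(groups.values()))
    group_names = list(dict.fromkeys(labels))
    shifted_groups = set(group_names[len(group_names) // 2 :])

    genes: list[tuple[str, str, float, float]] = []  # gene, status, noise, shift
    for g in config.planted_uniform:
        genes.append((g, "uniform", config.noise_sd, 0.0))
    for g in config.planted_high_cv:
        genes.append((g, "high_cv", config.high_cv_noise_sd, 0.0))
    for g, eff in config.planted_de.items():
        genes.append((g, "de", config.noise_sd, eff * config.noise_sd))

    sample_offset = rng.normal(0.0, config.sample_scaling_sd, size=len(samples))
    rows, probe_ids, probe_map = [], [], {}
    for gene, _status, noise, shift in genes:
        base = rng.uniform(6.0, 12.0)
        for t in range(config.probe_multiplicity):
            probe = f"{gene}_p{t + 1}"
            log2_vals = base + sample_offset + rng.normal(0.0, noise, len(samples))
            log2_vals += np.where(np.isin(labels, list(shifted_groups)), shift, 0.0)
            rows.append(np.exp2(log2_vals))
            probe_ids.append(probe)
            probe_map[probe] = (gene.upper(),)
    for b in range(config.n_background_probes):
        base = rng.uniform(6.0, 12.0)
        log2_vals = base + sample_offset + rng.normal(0.0, config.noise_sd, len(samples))
        rows.append(np.exp2(log2_vals))
        probe_ids.append(f"BG_{b + 1:04d}")

    values = pd.DataFrame(rows, index=probe_ids, columns=samples)
    dataset = ExpressionDataset(
        dataset_id=dataset_id,
        values=values,
        groups=groups,
        probe_to_gene=probe_map,
        log2_applied=False,
    )
    truth = pd.DataFrame(
        [
            {"gene": g.upper(), "status": s, "noise_sd": no, "log2_shift": sh}
            for g, s, no, sh in genes
        ]
    ).set_index("gene")
    return dataset, truth


def simulate_cq_matrix(config: SimulationConfig) -> tuple[CqMatrix, list[str]]:
    """Cq matrix with planted per-gene noise and group shifts.

    Cq[i, j] = baseline_j + sample_effect_i + group_shift_j(group of i)
    + N(0, noise_sd_j).  Planted group shifts alternate in sign from gene to
    gene (each deregulated gene moves its own way, rather than the whole
    panel co-shifting, which would contaminate the per-sample reference every
    stability method relies on).  The truth ordering lists genes from most to
    least stable by planted instability (noise_sd + |shift|/2, the shift
    split evenly across groups).
    """
    genes = sorted(set(config.cq_noise_sd) | set(config.cq_group_shift))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with planted Cq parameters")
    rng = config.rng(2)
    groups = _group_labels(config)
    samples = list(groups)
    labels = np.array(list(groups.values()))
    group_names = list(dict.fromkeys(labels))
    shifted = set(group_names[len(group_names) // 2 :])

    sample_effect = rng.normal(0.0, config.cq_sample_effect_sd, len(samples))
    cols = {}
    instability = {}
    shift_sign = 1
    for j, gene in enumerate(genes):
        noise = config.cq_noise_sd.get(gene, 0.1)
        shift = config.cq_group_shift.get(gene, 0.0)
        if shift:
            shift *= shift_sign
            shift_sign = -shift_sign
        baseline = config.cq_baseline + rng.uniform(-3.0, 3.0)
        cq = baseline + sample_effect + rng.normal(0.0, noise, len(samples))
        cq += np.where(np.isin(labels, list(shifted)), shift, 0.0)
        cols[gene] = cq
        instability[gene] = noise + abs(shift) / 2.0
    matrix = pd.DataFrame(cols, index=samples)
    truth = sorted(genes, key=lambda g: (instability[g], g))
    return CqMatrix(cq=matrix, groups=groups), truth


def simulate_dilution_series(
    gene: str,
    e_true: float = 2.0,
    cq_at_undiluted: float = 15.0,
    noise_sd: float = 0.1,
    reps: int = 3,
    n_levels: int = 5,
    dropout_most_dilute: bool = False,
    curvature_at_last: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Serial dilution with known efficiency.

    Level mean Cq follows the ideal line with slope -1/log10(E_true); each
    replicate gets Gaussian cycle noise.  ``dropout_most_dilute`` plants a
    4-log assay by failing all replicates at the most dilute level;
    ``curvature_at_last`` adds that many cycles to the most dilute level to
    plant a linearity breach instead.
    """
    if not 1.0 < e_true < 3.0:
        raise ValueError("e_true must lie in (1, 3)")
    rng = np.random.default_rng((seed, crc32(gene.encode())))
    slope = -1.0 / np.log10(e_true)
    points: dict[float, list[float]] = {}
    levels = [-(i + 1) for i in range(n_levels)]
    for level in levels:
        mean = cq_at_undiluted + slope * level
        if level == levels[-1]:
            mean += curvature_at_last
        cqs = (mean + rng.normal(0.0, noise_sd, reps)).tolist()
        if dropout_most_dilute and level == levels[-1]:
            cqs = [np.nan] * reps
        points[float(level)] = cqs
    return DilutionSeries(gene=gene, points=points)


def simulate_replicates(
    gene: str,
    mean_cq: float = 28.0,
    cv_target: float = 1.0,
    n: int = 6,
    runs: int = 1,
    seed: int = 0,
) -> list[ReplicateSet]:
    """Technical replicates with SD = cv_target * mean / 100 per run."""
    if cv_target < 0:
        raise ValueError("cv_target must be >= 0")
    rng = np.random.default_rng((seed, crc32(gene.encode()), 3))
    sd = cv_target * mean_cq / 100.0
    return [
        ReplicateSet(
            gene=gene,
            run_id=f"run{r + 1}",
            cq_values=(mean_cq + rng.normal(0.0, sd, n)).tolist(),
        )
        for r in range(runs)
    ]


_PRIMER_RULE_BUILDERS = {
    "pass",
    "amplicon_size",
    "exon_junction",
    "snp_3prime",
    "snp_3prime_rare",
    "editing_site",
    "hairpin_tm",
    "dimer_dg",
}


def _random_primer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_primer_table(
    schedule: list[str], gene: str = "GENE1", seed: int = 0
) -> tuple[list[PrimerPairRecord], list[str]]:
    """Candidate primer pairs violating exactly the scheduled rules.

    ``schedule`` lists, per candidate, the rule it violates ("pass" or None
    for a clean record).  ``snp_3prime_rare`` plants a 3'-window SNP with
    unknown frequency: it fails the strict policy but passes once rare SNPs
    are tolerated.  Returns the records and the echoed schedule (truth).
    """
    rng = np.random.default_rng((seed, 4))
    records = []
    truth = []
    for i, rule in enumerate(schedule):
        rule = rule or "pass"
        if rule not in _PRIMER_RULE_BUILDERS:
            raise ValueError(f"unknown rule name {rule!r}")
        rec = PrimerPairRecord(
            gene=gene,
            forward=_random_primer(rng),
            reverse=_random_primer(rng),
            amplicon_bp=int(rng.integers(80, 116)),
            spans_exon_junction=True,
            hairpin_tm={"F": float(rng.uniform(35, 55)), "R": float(rng.uniform(35, 55))},
            homodimer_dg={"F": float(rng.uniform(-8, -2)), "R": float(rng.uniform(-8, -2))},
            heterodimer_dg=float(rng.uniform(-8, -2)),
        )
        if rule == "amplicon_size":
            rec.amplicon_bp = int(rng.choice([45, 150]))
        elif rule == "exon_junction":
            rec.spans_exon_junction = False
        elif rule == "snp_3prime":
            rec.snps = [SnpAnnotation("F", int(rng.integers(1, 6)), 0.01)]
        elif rule == "snp_3prime_rare":
            rec.snps = [SnpAnnotation("R", int(rng.integers(1, 6)), None)]
        elif rule == "editing_site":
            rec.editing_sites = [EditingSite("F", int(rng.integers(1, 21)))]
        elif rule == "hairpin_tm":
            rec.hairpin_tm["F"] = float(rng.uniform(61, 75))
        elif rule == "dimer_dg":
            rec.heterodimer_dg = float(rng.uniform(-18, -11))
        records.append(rec)
        truth.append(rule)
    return records, truth
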