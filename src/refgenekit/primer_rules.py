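"""Deterministic vetting of candidate primer pairs.

Encodes the exclusion rules applied to annotated primer-pair records:
amplicon size window, exon-junction requirement, known SNPs in the last five
3' positions of either primer, A-to-I RNA editing sites within either primer's
annealing footprint, hairpin melting temperature, and homo-/hetero-dimer free
energy.  Annotations (SNP positions and frequencies, editing sites, Tm, dG)
are inputs — no thermodynamics or database queries happen here.

A selection walk evaluates an ordered candidate list under a strict policy
and, after a run of consecutive failures (15 by default), progressively
relaxes it: first tolerating rare or unknown-frequency SNPs, then waiving the
exon-junction requirement (order configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SnpAnnotation",
    "EditingSite",
    "PrimerPairRecord",
    "PrimerPolicy",
    "Verdict",
    "SelectionResult",
    "evaluate_primer_pair",
    "select_first_passing",
    "RULE_NAMES",
]

_DNA = set("ACGT")

RULE_NAMES = (
    "amplicon_size",
    "exon_junction",
    "snp_3prime",
    "editing_site",
    "hairpin_tm",
    "dimer_dg",
)


@dataclass(frozen=True)
class SnpAnnotation:
    primer: str                    # "F" or "R"
    pos_from_3prime: int           # 1 = 3'-terminal base
    allele_frequency: float | None = None  # fraction; None = unknown


@dataclass(frozen=True)
class EditingSite:
    primer: str
    pos_from_3prime: int


@dataclass
class PrimerPairRecord:
    gene: str
    forward: str
    reverse: str
    amplicon_bp: int
    spans_exon_junction: bool = True
    snps: list[SnpAnnotation] = field(default_factory=list)
    editing_sites: list[EditingSite] = field(default_factory=list)
    hairpin_tm: dict[str, float] = field(default_factory=dict)   # degC per primer
    homodimer_dg: dict[str, float] = field(default_factory=dict)  # kcal/mol per primer
    heterodimer_dg: float | None = None                           # kcal/mol

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or set(seq) - _DNA:
                raise ValueError(f"{self.gene}: {name} primer is not a DNA sequence")
        if self.amplicon_bp <= max(len(self.forward), len(self.reverse)):
            raise ValueError(f"{self.gene}: amplicon shorter than a primer")
        for ann in list(self.snps) + list(self.editing_sites):
            if ann.primer not in ("F", "R"):
                raise ValueError(f"{self.gene}: annotation primer must be F or R")
            length = len(self.forward if ann.primer == "F" else self.reverse)
            if not 1 <= ann.pos_from_3prime <= length:
                raise ValueError(
                    f"{self.gene}: position {ann.pos_from_3prime} outside primer"
                )


@dataclass(frozen=True)
class PrimerPolicy:
    """Thresholds and switches of the rule engine.

    ``dimer_dg_min`` is the most negative acceptable free energy; by default a
    dimer stronger (more negative) than -10 kcal/mol fails.  The
    ``literal_dg_rule`` switch inverts this to reject dG > -10 instead.
    ``rare_freq_threshold`` is the allele-frequency bound (1 per 250,000
    alleles) below which a 3'-window SNP is tolerated once
    ``tolerate_rare_snps`` is on; unknown frequencies count as rare.
    """

    amplicon_min: int = 70
    amplicon_max: int = 120
    require_junction: bool = True
    snp_3prime_window: int = 5
    rare_freq_threshold: float = 1.0 / 250_000
    tolerate_rare_snps: bool = False
    hairpin_tm_max: float = 60.0
    dimer_dg_min: float = -10.0
    literal_dg_rule: bool = False
    relaxation_after: int = 15
    relaxation_order: tuple[str, ...] = ("rare_snps", "junction")

    def __post_init__(self) -> None:
        if self.amplicon_min >= self.amplicon_max:
            raise ValueError("amplicon_min must be below amplicon_max")
        if self.snp_3prime_window < 1:
            raise ValueError("snp_3prime_window must be >= 1")
        bad = set(self.relaxation_order) - {"rare_snps", "junction"}
        if bad:
            raise ValueError(f"unknown relaxation steps {sorted(bad)}")

    def relaxed(self, stage: int) -> "PrimerPolicy":
        """Policy after applying the first ``stage`` relaxation steps."""
        policy = self
        for step in self.relaxation_order[:stage]:
            if step == "rare_snps":
                policy = replace(policy, tolerate_rare_snps=True)
            elif step == "junction":
                policy = replace(policy, require_junction=False)
        return policy


@dataclass
class Verdict:
    gene: str
    passed: bool
    reasons: frozenset[str]


def evaluate_primer_pair(record: PrimerPairRecord, policy: PrimerPolicy) -> Verdict:
    """Apply every exclusion rule; pass iff no rule is violated.

    Reasons are a set (rule order is immaterial): ``amplicon_size``,
    ``exon_junction``, ``snp_3prime``, ``editing_site``, ``hairpin_tm``,
    ``dimer_dg``.
    """
    reasons: set[str] = set()

    if not policy.amplicon_min <= record.amplicon_bp <= policy.amplicon_max:
        reasons.add("amplicon_size")

    if policy.require_junction and not record.spans_exon_junction:
        reasons.add("exon_junction")

    for snp in record.snps:
        if snp.pos_from_3prime <= policy.snp_3prime_window:
            rare = snp.allele_frequency is None or (
                snp.allele_frequency < policy.rare_freq_threshold
            )
            if not (policy.tolerate_rare_snps and rare):
                reasons.add("snp_3prime")

    if record.editing_sites:
        reasons.add("editing_site")

    for tm in record.hairpin_tm.values():
        if tm > policy.hairpin_tm_max:
            reasons.add("hairpin_tm")

    dgs = list(record.homodimer_dg.values())
    if record.heterodimer_dg is not None:
        dgs.append(record.heterodimer_dg)
    for dg in dgs:
        if policy.literal_dg_rule:
            if dg > policy.dimer_dg_min:
                reasons.add("dimer_dg")
        elif dg < policy.dimer_dg_min:
            reasons.add("dimer_dg")

    return Verdict(gene=record.gene, passed=not reasons, reasons=frozenset(reasons))


@dataclass
class SelectionResult:
    chosen: PrimerPairRecord | None
    chosen_index: int | None        # 1-based position in the candidate list
    relaxation_stage: int           # 0 = strict policy
    audit: list[dict]               # one entry per candidate examined

    @property
    def found(self) -> bool:
        return self.chosen is not None


def select_first_passing(
    candidates: list[PrimerPairRecord], policy: PrimerPolicy | None = None
) -> SelectionResult:
    """Walk an ordered candidate list, relaxing the policy after failures.

    Candidates are evaluated in order under the strict policy; after
    ``policy.relaxation_after`` consecutive failures the next relaxation step
    is switched on (default order: tolerate rare/unknown-frequency SNPs, then
    drop the exon-junction requirement) and the walk continues.  Returns the
    first passing record together with a per-candidate audit log; if the list
    is exhausted, a no-primer-found result carrying the full audit.
    """
    policy = policy or PrimerPolicy()
    stage = 0
    consecutive_failures = 0
    audit: list[dict] = []
    for idx, record in enumerate(candidates, start=1):
        current = policy.relaxed(stage)
        verdict = evaluate_primer_pair(record, current)
        audit.append(
            {
                "index": idx,
                "gene": record.gene,
                "passed": verdict.passed,
                "reasons": sorted(verdict.reasons),
                "relaxation_stage": stage,
            }
        )
        if verdict.passed:
            return SelectionResult(record, idx, stage, audit)
        consecutive_failures += 1
        if (
            consecutive_failures >= policy.relaxation_after
            and stage < len(policy.relaxation_order)
        ):
            stage += 1
            consecutive_failures = 0
    return SelectionResult(None, None, stage, audit)
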