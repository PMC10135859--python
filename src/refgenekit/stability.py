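"""Expression-stability ranking of candidate reference genes from Cq data.

Implements the four established stability algorithms — geNorm (stepwise
exclusion on the M value, plus the V(n/n+1) pairwise variation), NormFinder
(variance-components stability value), BestKeeper (dispersion of raw Cq and
correlation with a geometric-mean index), and the comparative delta-Ct method —
and aggregates their rankings into a geometric-mean consensus in the style of
the RefFinder tool.

All algorithms work on a :class:`CqMatrix` (samples x genes quantification
cycles).  geNorm, NormFinder and the consensus operate on relative quantities
Q = E^(minCq - Cq); BestKeeper and delta-Ct work on raw Cq.  Log base 2
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqMatrix",
    "StabilityResult",
    "cq_to_relative_quantity",
    "genorm",
    "GenormResult",
    "genorm_pairwise_variation",
    "normfinder",
    "bestkeeper",
    "delta_ct_stability",
    "reffinder_consensus",
    "rank_stability",
]

DEFAULT_EFFICIENCY = 2.0


@dataclass
class CqMatrix:
    """Sample x gene quantification-cycle matrix with optional metadata.

    ``cq`` holds cycles (typically 10-45; NaN = missing / non-amplified),
    ``groups`` optionally maps samples to experimental groups, and
    ``efficiency`` maps genes to their amplification base E (fold increase per
    cycle, 2.0 = perfect doubling).
    """

    cq: pd.DataFrame
    groups: dict[str, str] | None = None
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cq.index.has_duplicates or self.cq.columns.has_duplicates:
            raise ValueError("duplicate sample or gene identifiers")
        arr = self.cq.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise ValueError("Cq values must be positive")
        for g, e in self.efficiency.items():
            if not 1.0 < e < 3.0:
                raise ValueError(f"efficiency for {g} must lie in (1, 3), got {e}")

    @property
    def samples(self) -> list[str]:
        return list(self.cq.index)

    @property
    def genes(self) -> list[str]:
        return list(self.cq.columns)

    def efficiency_vector(self) -> pd.Series:
        return pd.Series(
            {g: self.efficiency.get(g, DEFAULT_EFFICIENCY) for g in self.genes}
        )

    def complete(self) -> pd.DataFrame:
        """Rows without any missing Cq."""
        return self.cq.dropna(axis=0, how="any")


def _rank_ascending(values: dict[str, float]) -> dict[str, float]:
    genes = list(values)
    ranks = stats.rankdata([values[g] for g in genes], method="average")
    return dict(zip(genes, ranks.tolist()))


def cq_to_relative_quantity(cq: CqMatrix) -> pd.DataFrame:
    """Relative quantities Q = E^(minCq - Cq), per-gene maximum 1.

    The sample with a gene's lowest observed Cq (most template) gets Q = 1;
    every extra cycle divides Q by the gene's amplification base E.  Missing
    Cq stays missing.
    """
    E = cq.efficiency_vector()
    min_cq = cq.cq.min(axis=0)
    return E.to_numpy() ** (min_cq - cq.cq)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    m_values: dict[str, float]            # M at the iteration the gene left (or final pair)
    first_pass_m: dict[str, float]        # M of every gene in the full panel
    exclusion_order: list[str]            # worst first
    ranking: dict[str, float]             # gene -> rank (final pair ties at 1.5)
    pairwise_v: list[float] = field(default_factory=list)  # V(2/3), V(3/4), ...
    ranked_genes: list[str] = field(default_factory=list)  # best first


def _genorm_m(Q: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD_i log2(Q_j / Q_k)."""
    logq = np.log2(Q.to_numpy(dtype=float))
    n = logq.shape[1]
    M = np.empty(n)
    for j in range(n):
        diffs = logq[:, [j]] - logq   # samples x genes, column k = log ratio j/k
        sds = diffs.std(axis=0, ddof=1)
        M[j] = np.delete(sds, j).mean()
    return pd.Series(M, index=Q.columns)


def genorm(Q: pd.DataFrame, final_pair_rank: str = "tied") -> GenormResult:
    """geNorm stepwise-exclusion stability ranking.

    At each iteration the gene with the highest M (mean SD of pairwise log2
    ratios against all remaining genes) is removed, until two genes remain.
    The ranking is the reverse exclusion order; with ``final_pair_rank="tied"``
    (default) the final pair shares averaged rank 1.5, with ``"split"`` they
    get ranks 1 and 2 by ascending final M.

    Samples with any missing value are dropped; needs >=3 genes and >=3
    complete samples.
    """
    Q = Q.dropna(axis=0, how="any")
    if Q.shape[1] < 3:
        raise ValueError("geNorm needs at least 3 genes")
    if Q.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 complete samples")
    if np.any(Q.to_numpy(dtype=float) <= 0):
        raise ValueError("relative quantities must be positive")

    remaining = Q.copy()
    exclusion: list[str] = []
    m_at_exit: dict[str, float] = {}
    first_pass = _genorm_m(Q).to_dict()
    while remaining.shape[1] > 2:
        M = _genorm_m(remaining)
        worst = M.sort_values(kind="mergesort").index[-1]
        exclusion.append(worst)
        m_at_exit[worst] = float(M[worst])
        remaining = remaining.drop(columns=[worst])
    final_m = _genorm_m(remaining)
    for g in remaining.columns:
        m_at_exit[g] = float(final_m[g])

    ranking: dict[str, float] = {}
    pair = list(remaining.columns)
    if final_pair_rank == "tied":
        for g in pair:
            ranking[g] = 1.5
    else:
        ordered = final_m.sort_values(kind="mergesort").index
        ranking[ordered[0]], ranking[ordered[1]] = 1.0, 2.0
    for pos, g in enumerate(reversed(exclusion), start=3):
        ranking[g] = float(pos)

    ranked = sorted(ranking, key=lambda g: (ranking[g], g))
    result = GenormResult(
        m_values=m_at_exit,
        first_pass_m=first_pass,
        exclusion_order=exclusion,
        ranking=ranking,
        ranked_genes=ranked,
    )
    result.pairwise_v = genorm_pairwise_variation(Q, ranked)
    return result


def genorm_pairwise_variation(Q: pd.DataFrame, ranking: list[str]) -> list[float]:
    """Pairwise variation V(n/n+1) of normalization factors for n = 2..G-1.

    NF_n is the per-sample geometric mean of the top-n genes' quantities;
    V(n/n+1) is the sample SD of log2(NF_n / NF_{n+1}).  Guides how many
    reference genes suffice (the classic inclusion cutoff is V < 0.15).
    """
    Q = Q.dropna(axis=0, how="any")
    genes = [g for g in ranking if g in Q.columns]
    if len(genes) < 3:
        return []
    logq = np.log2(Q[genes].to_numpy(dtype=float))
    out = []
    for n in range(2, len(genes)):
        nf_n = logq[:, :n].mean(axis=1)
        nf_n1 = logq[:, : n + 1].mean(axis=1)
        out.append(float((nf_n - nf_n1).std(ddof=1)))
    return out


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(
    Q: pd.DataFrame, groups: dict[str, str] | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Model-based stability value per gene (variance-components form).

    Expression is taken to log2 and centred within each sample across genes,
    removing sample-specific loading; a gene's stability is the standard
    deviation of what remains.  With group labels, the intergroup variance of
    the group means (corrected for sampling noise) is added to the mean
    intragroup variance before the square root, so genes that shift between
    groups are penalised even when tight within groups.  Lower = more stable.

    Returns (gene -> stability value, gene -> rank ascending).
    """
    Q = Q.dropna(axis=0, how="any")
    if Q.shape[0] < 3 or Q.shape[1] < 2:
        raise ValueError("NormFinder needs >=3 complete samples and >=2 genes")
    y = np.log2(Q.to_numpy(dtype=float))
    z = y - y.mean(axis=1, keepdims=True)        # centre each sample across genes
    genes = list(Q.columns)

    usable_groups = None
    if groups is not None:
        labels = [groups.get(s) for s in Q.index]
        if None not in labels:
            sizes = pd.Series(labels).value_counts()
            if len(sizes) >= 2 and (sizes >= 2).all():
                usable_groups = np.array(labels)
        if usable_groups is None and len(set(labels) - {None}) > 1:
            warnings.warn(
                "NormFinder: some group has <2 samples; falling back to "
                "ungrouped stability",
                stacklevel=2,
            )

    if usable_groups is None:
        stab = z.std(axis=0, ddof=1)
    else:
        names = pd.unique(usable_groups)
        k = len(names)
        stab = np.empty(len(genes))
        overall = z.mean(axis=0)
        for j in range(len(genes)):
            d2 = 0.0
            v_over_n = []
            v_grp = []
            for g in names:
                m = usable_groups == g
                zg = z[m, j]
                d2 += (zg.mean() - overall[j]) ** 2
                v = zg.var(ddof=1)
                v_grp.append(v)
                v_over_n.append(v / m.sum())
            if k > 1:
                gamma = max(0.0, d2 / (k - 1) - float(np.mean(v_over_n)))
            else:
                gamma = 0.0
            stab[j] = np.sqrt(gamma + float(np.mean(v_grp)))

    values = dict(zip(genes, stab.tolist()))
    return values, _rank_ascending(values)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(
    cq: CqMatrix, use_sample_sd: bool = False
) -> tuple[pd.DataFrame, dict[str, float]]:
    """BestKeeper descriptive stability statistics on raw Cq.

    Per gene: SD_cq (mean absolute deviation from the arithmetic mean, the
    original tool's definition; sample SD via ``use_sample_sd``), CV_percent
    = 100*SD/mean, and the Pearson correlation of the gene's Cq with the
    BestKeeper index (per-sample geometric mean of Cq over all genes).
    Ranking is ascending on SD_cq.
    """
    X = cq.complete()
    if X.shape[0] < 3:
        raise ValueError("BestKeeper needs at least 3 complete samples")
    arr = X.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    if use_sample_sd:
        sd = arr.std(axis=0, ddof=1)
    else:
        sd = np.abs(arr - mean).mean(axis=0)
    cv = 100.0 * sd / mean
    index = stats.gmean(arr, axis=1)
    r = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        if index.std() == 0 or arr[:, j].std() == 0:
            r[j] = np.nan
        else:
            r[j] = stats.pearsonr(arr[:, j], index)[0]
    table = pd.DataFrame(
        {"SD_cq": sd, "CV_percent": cv, "r_vs_index": r}, index=X.columns
    )
    ranks = _rank_ascending(dict(zip(X.columns, sd.tolist())))
    return table, ranks


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_stability(cq: CqMatrix) -> tuple[dict[str, float], dict[str, float]]:
    """Mean pairwise SD of Cq differences per gene (comparative delta-Ct).

    For every gene pair (j, k) the per-sample difference Cq_j - Cq_k is
    formed; gene j's stability is the mean over k != j of the sample SD of
    that difference.  With all efficiencies equal to 2 this coincides exactly
    with the geNorm M of the first iteration.
    """
    X = cq.complete()
    if X.shape[1] < 3:
        raise ValueError("delta-Ct needs at least 3 genes")
    if X.shape[0] < 3:
        raise ValueError("delta-Ct needs at least 3 complete samples")
    arr = X.to_numpy(dtype=float)
    n = arr.shape[1]
    S = np.empty(n)
    for j in range(n):
        diffs = arr[:, [j]] - arr
        sds = diffs.std(axis=0, ddof=1)
        S[j] = np.delete(sds, j).mean()
    values = dict(zip(X.columns, S.tolist()))
    return values, _rank_ascending(values)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def reffinder_consensus(
    per_method_ranks: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Geometric-mean consensus of per-method rankings (RefFinder style).

    All rank mappings must cover the same gene set.  Returns a frame indexed
    by gene with each method's rank, the geometric mean of ranks, and the
    final consensus rank (ascending by geomean, ties averaged; final ordering
    deterministic by (geomean, gene)).
    """
    methods = list(per_method_ranks)
    gene_sets = [set(per_method_ranks[m]) for m in methods]
    if not gene_sets or any(s != gene_sets[0] for s in gene_sets):
        raise ValueError("all methods must rank the same gene set")
    genes = sorted(gene_sets[0])
    mat = np.array([[per_method_ranks[m][g] for m in methods] for g in genes])
    geo = stats.gmean(mat, axis=1)
    final = stats.rankdata(geo, method="average")
    out = pd.DataFrame(mat, index=genes, columns=[f"rank_{m}" for m in methods])
    out["geomean_rank"] = geo
    out["final_rank"] = final
    return out.sort_values(["geomean_rank", "final_rank"]).rename_axis("gene")


@dataclass
class StabilityResult:
    per_method: dict[str, dict[str, dict[str, float]]]
    genorm_exclusion_order: list[str]
    genorm_pairwise_v: list[float]
    consensus: pd.DataFrame

    def report(self) -> pd.DataFrame:
        """One row per gene: each method's value and rank, geomean, final rank."""
        rows = {}
        for method, per_gene in self.per_method.items():
            for g, d in per_gene.items():
                rows.setdefault(g, {})[f"{method}_value"] = d["stability_value"]
                rows.setdefault(g, {})[f"{method}_rank"] = d["rank"]
        out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")
        out = out.join(self.consensus[["geomean_rank", "final_rank"]])
        return out.sort_values("final_rank")


def rank_stability(cq: CqMatrix) -> StabilityResult:
    """Run all four stability algorithms and the geomean consensus."""
    Q = cq_to_relative_quantity(cq)
    gn = genorm(Q)
    nf_values, nf_ranks = normfinder(Q, cq.groups)
    bk_table, bk_ranks = bestkeeper(cq)
    dc_values, dc_ranks = delta_ct_stability(cq)

    per_method = {
        "geNorm": {
            g: {"stability_value": gn.m_values[g], "rank": gn.ranking[g]}
            for g in gn.ranking
        },
        "NormFinder": {
            g: {"stability_value": nf_values[g], "rank": nf_ranks[g]} for g in nf_ranks
        },
        "BestKeeper": {
            g: {"stability_value": float(bk_table.loc[g, "SD_cq"]), "rank": bk_ranks[g]}
            for g in bk_ranks
        },
        "deltaCt": {
            g: {"stability_value": dc_values[g], "rank": dc_ranks[g]} for g in dc_ranks
        },
    }
    consensus = reffinder_consensus(
        {m: {g: d["rank"] for g, d in per_method[m].items()} for m in per_method}
    )
    return StabilityResult(
        per_method=per_method,
        genorm_exclusion_order=gn.exclusion_order,
        genorm_pairwise_v=gn.pairwise_v,
        consensus=consensus,
    )
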