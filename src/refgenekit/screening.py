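"""In-silico uniformity screening of candidate reference genes.

Given one or more expression datasets with sample group labels (e.g. diagnostic
groups of a clinical cohort), every probe is tested for between-group
differential expression with an empirical-Bayes moderated one-way F test, the
p-values are Benjamini-Hochberg adjusted platform-wide, and candidate genes are
ranked by adjusted p-value: the *highest* p_adj (closest to 1, least evidence
of group differences) gets rank 1 and is the best reference-gene candidate.
Per-dataset ranks are summed into a composite rank, and a coefficient-of-
variation filter removes genes that are non-differential yet widely dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "GeneScreenRecord",
    "auto_log2",
    "moderated_group_test",
    "benjamini_hochberg",
    "collapse_probes",
    "rank_by_padj",
    "composite_rank",
    "expression_cv",
    "filter_by_cv",
    "screen_datasets",
]


@dataclass
class ExpressionDataset:
    """A probe x sample expression matrix with group labels.

    Parameters
    ----------
    dataset_id : str
        Label for the dataset (e.g. a GEO accession).
    values : pandas.DataFrame
        Probes in rows, samples in columns, platform-unit intensities.
    groups : dict
        Mapping sample id -> group label. May be empty right after parsing a
        series-matrix file; screening requires at least two groups with two
        samples each.
    probe_to_gene : dict
        Mapping probe id -> gene symbol or tuple of symbols (partial allowed).
    log2_applied : bool
        Whether ``values`` is already on the log2 scale.
    metadata : dict
        Free-form header lines kept for group-assignment hints.
    """

    dataset_id: str
    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    probe_to_gene: dict[str, tuple[str, ...]] = field(default_factory=dict)
    log2_applied: bool = False
    metadata: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate probe identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample identifiers")
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(
                f"{self.dataset_id}: group labels for unknown samples {sorted(unknown)}"
            )
        # normalise mapping values to tuples of upper-case symbols
        norm: dict[str, tuple[str, ...]] = {}
        for probe, syms in self.probe_to_gene.items():
            if isinstance(syms, str):
                syms = (syms,)
            norm[probe] = tuple(s.strip().upper() for s in syms if s and s.strip())
        self.probe_to_gene = norm

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    def group_sizes(self) -> pd.Series:
        return pd.Series(self.groups).value_counts()

    def require_groups(self) -> None:
        sizes = self.group_sizes()
        if len(sizes) < 2 or (sizes >= 2).sum() < 2:
            raise ValueError(
                f"{self.dataset_id}: screening needs >=2 groups with >=2 samples each, "
                f"got {sizes.to_dict()}"
            )


@dataclass
class GeneScreenRecord:
    """Per-gene screening outcome across datasets."""

    gene: str
    per_dataset: dict[str, dict] = field(default_factory=dict)
    composite_rank: float | None = None
    status: str = "ranked"  # ranked | missing_in_some_dataset | excluded_cv | shortlisted


# ---------------------------------------------------------------------------
# log transform heuristic
# ---------------------------------------------------------------------------

def auto_log2(values: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Decide whether a matrix looks linear-scale and log2 it if so.

    Quantile heuristic in the style of the GEO2R portal: with matrix quantiles
    q0, q25, q99, q100, the transform is applied when q99 > 100, or when
    (q100 - q0 > 50 and q25 > 0).  Negative values are shifted to zero before
    ``log2(x + 1)``.

    Returns the (possibly transformed) matrix and a flag saying whether the
    transform was applied.
    """
    flat = values.to_numpy(dtype=float).ravel()
    flat = flat[np.isfinite(flat)]
    if flat.size == 0:
        return values, False
    q0, q25, q99, q100 = np.percentile(flat, [0, 25, 99, 100])
    if q99 > 100 or (q100 - q0 > 50 and q25 > 0):
        shifted = values if q0 >= 0 else values - q0
        return np.log2(shifted + 1.0), True
    return values, False


# ---------------------------------------------------------------------------
# moderated one-way test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_f_dist(variances: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F prior to an ensemble of residual variances.

    Works on log variances: e = log s^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2),
    which yields prior df d0 and prior variance s0^2.  Returns (d0, s0sq);
    d0 may be inf when the variances are essentially exchangeable.
    """
    ok = variances > 0
    if ok.sum() < 2:
        pos = variances[ok]
        return np.inf, float(np.median(pos)) if pos.size else 1.0
    v = variances[ok]
    d = df[ok].astype(float)
    z = np.log(v)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_group_test(
    dataset: ExpressionDataset,
    prior_df: float | None = None,
    moderated: bool = True,
    apply_auto_log: bool = True,
) -> pd.DataFrame:
    """One-way group-difference test per probe with variance moderation.

    Each probe's residual variance is shrunk toward a common prior variance
    estimated from the whole platform (method-of-moments fit of a scaled-F
    distribution to the ensemble of residual variances); the moderated F is
    the between-group mean square over the shrunken variance, referred to an
    F distribution with the residual df augmented by the prior df.  p-values
    are Benjamini-Hochberg adjusted across all tested probes.

    Parameters
    ----------
    prior_df : float, optional
        Override the estimated prior df; ``0`` gives the ordinary one-way
        ANOVA F, ``numpy.inf`` fully pools residual variances.
    moderated : bool
        ``False`` is shorthand for ``prior_df=0``.

    Returns
    -------
    pandas.DataFrame indexed by probe with columns F_stat, p_value, p_adj,
    df_between, df_resid, zero_resid_df (flag).
    """
    dataset.require_groups()
    values = dataset.values[list(dataset.groups)]
    if apply_auto_log and not dataset.log2_applied:
        values, _ = auto_log2(values)

    labels = np.array([dataset.groups[s] for s in values.columns])
    X = values.to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)

    group_names = pd.unique(labels)
    masks = [labels == g for g in group_names]
    k = len(group_names)
    n = X.shape[1]

    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    grand = X.mean(axis=1)
    for m in masks:
        gm = X[:, m].mean(axis=1)
        ss_between += m.sum() * (gm - grand) ** 2
        ss_within += ((X[:, m] - gm[:, None]) ** 2).sum(axis=1)
    df_between = k - 1
    df_resid = n - k
    zero_df = np.full(X.shape[0], df_resid <= 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ss_within / max(df_resid, 1)
        ms_between = ss_between / df_between

    usable = complete & ~zero_df
    if not moderated:
        prior_df = 0.0
    if prior_df is None:
        d0, s0sq = _fit_f_dist(s2[usable], np.full(usable.sum(), df_resid))
    else:
        d0 = float(prior_df)
        _, s0sq = _fit_f_dist(s2[usable], np.full(usable.sum(), df_resid))
    if d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(s2_post > 0, ms_between / s2_post, np.where(ms_between > 0, np.inf, 0.0))
    dfd = 1e9 if np.isinf(df_total) else df_total
    p = stats.f.sf(F, df_between, dfd)
    p = np.where(np.isfinite(F), p, np.nan)
    p[np.nan_to_num(F, nan=1.0) == 0] = 1.0

    F = np.where(usable, F, np.nan)
    p = np.where(usable, p, np.nan)

    p_adj = np.full_like(p, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        p_adj[tested] = benjamini_hochberg(p[tested])

    return pd.DataFrame(
        {
            "F_stat": F,
            "p_value": p,
            "p_adj": p_adj,
            "df_between": df_between,
            "df_resid": df_resid,
            "zero_resid_df": zero_df,
            "mean_expr": np.where(complete, grand, np.nan),
        },
        index=values.index,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg FDR adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# probe -> gene collapsing and ranking
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_stats: pd.DataFrame,
    probe_to_gene: dict[str, tuple[str, ...]],
    rule: str = "min_padj",
) -> pd.DataFrame:
    """Collapse probe-level statistics to one record per gene.

    ``rule`` selects the representative probe among a gene's mapped probes:
    ``min_padj`` (default; the worst-case instability evidence wins),
    ``max_padj``, or ``max_mean`` (highest mean expression, needs a
    ``mean_expr`` column).  Genes whose probes all lack a finite p_adj are
    dropped (treated as having no expression data).
    """
    if rule not in {"min_padj", "max_padj", "max_mean"}:
        raise ValueError(f"unknown collapse rule {rule!r}")
    gene_rows: dict[str, tuple[str, float]] = {}
    for probe, genes in probe_to_gene.items():
        if probe not in probe_stats.index:
            continue
        row = probe_stats.loc[probe]
        padj = row["p_adj"]
        if not np.isfinite(padj):
            continue
        key = row.get("mean_expr", np.nan) if rule == "max_mean" else padj
        for gene in genes:
            cur = gene_rows.get(gene)
            better = (
                cur is None
                or (rule == "min_padj" and key < cur[1])
                or (rule == "max_padj" and key > cur[1])
                or (rule == "max_mean" and key > cur[1])
            )
            if better:
                gene_rows[gene] = (probe, key)
    out = pd.DataFrame(
        {
            "probe_used": {g: p for g, (p, _) in gene_rows.items()},
        }
    )
    if out.empty:
        return pd.DataFrame(columns=["probe_used", "p_adj"])
    out["p_adj"] = [probe_stats.loc[p, "p_adj"] for p in out["probe_used"]]
    return out.sort_index()


def rank_by_padj(gene_padj: dict[str, float]) -> dict[str, float]:
    """Rank genes by adjusted p-value, rank 1 = highest p_adj; ties averaged."""
    if not gene_padj:
        raise ValueError("empty gene -> p_adj mapping")
    genes = list(gene_padj)
    vals = np.array([gene_padj[g] for g in genes], dtype=float)
    ranks = stats.rankdata(-vals, method="average")
    return dict(zip(genes, ranks.tolist()))


def composite_rank(
    per_dataset_ranks: dict[str, dict[str, float]],
) -> tuple[dict[str, float], set[str]]:
    """Sum per-dataset uniformity ranks; genes absent anywhere are excluded.

    Returns (gene -> composite rank, sorted ascending by rank then symbol;
    set of genes missing from at least one dataset).
    """
    if not per_dataset_ranks:
        raise ValueError("need at least one dataset ranking")
    universe: set[str] = set()
    for ranks in per_dataset_ranks.values():
        universe |= set(ranks)
    missing = {
        g for g in universe if any(g not in r for r in per_dataset_ranks.values())
    }
    composite = {
        g: float(sum(r[g] for r in per_dataset_ranks.values()))
        for g in universe - missing
    }
    ordered = dict(sorted(composite.items(), key=lambda kv: (kv[1], kv[0])))
    return ordered, missing


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def expression_cv(
    dataset: ExpressionDataset, gene: str, probe: str | None = None
) -> float:
    """CV% of a gene's linear-scale expression across all samples (pooled).

    100 x sample SD (n-1) / mean of the selected probe's values; computed on
    the linear scale even when the matrix is stored as log2.  Returns NaN when
    the mean is non-positive or fewer than two values are present.
    """
    gene = gene.strip().upper()
    if probe is None:
        candidates = [p for p, gs in dataset.probe_to_gene.items() if gene in gs]
        if not candidates:
            return np.nan
        probe = candidates[0]
    x = dataset.values.loc[probe].to_numpy(dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return np.nan
    if dataset.log2_applied:
        x = np.exp2(x)
    m = x.mean()
    if m <= 0:
        return np.nan
    return float(100.0 * x.std(ddof=1) / m)


def filter_by_cv(
    cv_table: dict[str, dict[str, float]], threshold: float = 45.0
) -> tuple[list[str], dict[str, list[str]]]:
    """Exclude genes whose CV% strictly exceeds ``threshold`` in any dataset.

    ``cv_table`` maps gene -> {dataset_id -> cv_percent}.  Returns the
    retained genes (input order) and, for excluded genes, the offending
    dataset ids.
    """
    retained, excluded = [], {}
    for gene, per_ds in cv_table.items():
        bad = [ds for ds, cv in per_ds.items() if np.isfinite(cv) and cv > threshold]
        if bad:
            excluded[gene] = bad
        else:
            retained.append(gene)
    return retained, excluded


# ---------------------------------------------------------------------------
# end-to-end screen
# ---------------------------------------------------------------------------

def screen_datasets(
    datasets: list[ExpressionDataset],
    candidates: list[str],
    shortlist_size: int = 18,
    cv_threshold: float = 45.0,
    significance: float = 0.05,
    collapse_rule: str = "min_padj",
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, dict[str, GeneScreenRecord]]:
    """Run the whole uniformity screen over one or more datasets.

    Tests every probe, collapses to candidate genes, ranks per dataset by
    p_adj, sums ranks into a composite, shortlists the ``shortlist_size`` best
    composites, and applies the CV filter to the shortlist.  Returns a tidy
    report table (one row per candidate gene) plus the per-gene records.
    """
    candidates = [c.strip().upper() for c in candidates]
    per_ds_stats: dict[str, pd.DataFrame] = {}
    per_ds_ranks: dict[str, dict[str, float]] = {}
    records = {g: GeneScreenRecord(gene=g) for g in candidates}

    for ds in datasets:
        probe_stats = moderated_group_test(ds, prior_df=prior_df)
        gene_stats = collapse_probes(probe_stats, ds.probe_to_gene, rule=collapse_rule)
        present = gene_stats.loc[gene_stats.index.intersection(candidates)]
        ranks = rank_by_padj(present["p_adj"].to_dict()) if len(present) else {}
        per_ds_stats[ds.dataset_id] = present
        per_ds_ranks[ds.dataset_id] = ranks
        for g in candidates:
            if g in present.index:
                records[g].per_dataset[ds.dataset_id] = {
                    "probe_used": present.loc[g, "probe_used"],
                    "p_adj": float(present.loc[g, "p_adj"]),
                    "uniformity_rank": ranks[g],
                    "cv_percent": expression_cv(ds, g, probe=present.loc[g, "probe_used"]),
                    "significant": bool(present.loc[g, "p_adj"] < significance),
                }

    composite, missing = composite_rank(per_ds_ranks) if per_ds_ranks else ({}, set())
    for g in candidates:
        if g in composite:
            records[g].composite_rank = composite[g]
        else:
            records[g].status = "missing_in_some_dataset"

    shortlist = [g for g in composite if g in records][:shortlist_size]
    cv_table = {
        g: {
            ds: rec["cv_percent"]
            for ds, rec in records[g].per_dataset.items()
        }
        for g in shortlist
    }
    retained, cv_excluded = filter_by_cv(cv_table, threshold=cv_threshold)
    for g in shortlist:
        records[g].status = "excluded_cv" if g in cv_excluded else "shortlisted"

    rows = []
    for g in candidates:
        rec = records[g]
        row: dict = {"gene": g, "composite_rank": rec.composite_rank, "status": rec.status}
        for ds in per_ds_stats:
            d = rec.per_dataset.get(ds, {})
            row[f"{ds}:p_adj"] = d.get("p_adj")
            row[f"{ds}:rank"] = d.get("uniformity_rank")
            row[f"{ds}:cv_percent"] = d.get("cv_percent")
        rows.append(row)
    report = pd.DataFrame(rows).set_index("gene")
    report = report.sort_values(
        by="composite_rank", na_position="last", kind="mergesort"
    )
    return report, records
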