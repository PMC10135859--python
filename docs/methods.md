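# Methods

## Scope and model of the problem

RT-qPCR quantification is only as good as its normalization. The package
operationalizes a selection strategy for reference genes in a given setting
(here: a clinical cohort with diagnostic groups): first find genes whose
expression is *uniform across groups* in existing transcriptomic data, then
confirm that a well-behaved PCR assay can be built for them, and finally
rank them for *stability* in actual Cq measurements against the classical
housekeeping genes they are meant to replace.

## Uniformity screening

**Test statistic.** Each probe gets a one-way group-difference F statistic
with empirical-Bayes variance moderation: per-probe residual variances
`s²_g` (df `d = n − k`) are shrunk toward a prior variance `s₀²` with prior
df `d₀`, both estimated from the platform-wide ensemble of residual
variances by moment-matching a scaled-F distribution on the log-variance
scale (mean and excess variance of `log s²` give `s₀²` and `d₀` through the
digamma/trigamma functions). The moderated F is the between-group mean
square over the shrunken variance `s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d)`,
referred to `F(k−1, d + d₀)`. `prior_df=0` (or `moderated=False`) recovers
the ordinary one-way ANOVA F, which is also what the oracle-equivalence
tests compare against; `prior_df=inf` fully pools. Probes with zero residual
df are flagged and excluded from the moderation fit.

**Multiplicity.** Benjamini–Hochberg step-up adjustment (via statsmodels)
across **all** tested probes of a platform, not just candidate genes —
candidate p_adj values are extracted afterwards. Adjusting platform-wide
matters: the candidate list is a tiny, biased subset and adjusting within it
would misstate the FDR relative to how portal-style analyses compute it.

**Scale heuristic.** Matrices are auto-log2-transformed before testing when
their quantiles look linear-scale (q99 > 100, or range > 50 with q25 > 0),
with negatives shifted to zero before `log2(x+1)`; the rule is overridable.
The CV filter deliberately works on the **linear** scale (delogging if
needed), since 45%-of-the-mean dispersion is a linear-scale notion.

**Ranking.** Per dataset, rank 1 = highest p_adj, ties averaged. Composite
rank = sum of per-dataset ranks; a gene missing from any dataset is excluded
from the composite and reported. The shortlist (default size 18) is then
filtered: CV strictly greater than the threshold (default 45%) in **at
least one** dataset excludes the gene. Probe→gene collapsing defaults to
the probe with the smallest p_adj — the worst-case instability evidence
wins — with largest-p_adj and highest-mean-expression rules available; the
"statistically different" reporting cutoff defaults to p_adj < 0.05.

## Stability algorithms

All algorithms consume a samples × genes Cq matrix. Relative quantities are
`Q = E^(minCq − Cq)` per gene (per-gene maximum 1), with amplification base
E defaulting to 2.0 and per-gene measured efficiencies accepted. Log base 2
throughout. Samples with any missing Cq are dropped before ranking (at least
3 complete samples required).

- **geNorm.** `M_j` = mean over partners k of the sample SD of
  `log2(Q_j/Q_k)`; the highest-M gene is removed each iteration until a
  pair remains, which shares averaged rank 1.5 (a 1/2 split is available —
  consensus-tool reimplementations differ here). Pairwise variation
  `V(n/n+1)` is the SD of `log2(NF_n/NF_{n+1})` with NF the geometric mean
  of the top-n genes.
- **NormFinder (variance-components form).** `y = log2 Q` is centred within
  each sample across genes; ungrouped stability is the SD of the centred
  values. With groups, the intergroup variance of group means (corrected by
  the mean sampling variance `v/n`, floored at 0) is added to the mean
  intragroup variance before the square root. This is the self-contained
  variance-components reading of the model; Andersen's exact finite-gene
  bias-corrected estimator is a deliberate extension point
  (`andersen-exact`), not the default, so no claim of bit parity with the
  original tool or with web consensus services is made.
- **BestKeeper.** Dispersion of raw Cq as the **mean absolute deviation**
  from the arithmetic mean (the original tool's "SD"; a sample-SD switch
  exists), CV% relative to mean Cq, and Pearson correlation with the
  BestKeeper index (per-sample geometric mean of Cq). Ranking is by
  dispersion.
- **Comparative ΔCt.** Mean over partners of the sample SD of pairwise Cq
  differences. With all efficiencies at 2, `log2(Q_j/Q_k)` equals
  `(Cq_k − Cq_j)` plus a constant, so this coincides *exactly* with the
  first-pass geNorm M — asserted to 1e-12 in the tests as an algebraic
  cross-check of both implementations.
- **Consensus.** Geometric mean of the four ranks; final ordering ascending
  by geomean with ties averaged and `(geomean, gene)` as a deterministic
  tie-break.

## Assay QC

Standard curves are ordinary least squares of **level-mean** Cq against
log10 dilution (classic practice; an all-replicates switch exists).
Efficiency `E% = (10^(−1/slope) − 1) × 100` for negative slopes; a
non-negative slope is reported but flagged invalid. Dynamic range: starting
from all levels, a span passes when every level has all replicates
amplified, R² ≥ 0.98, and no level-mean residual exceeds 0.5 cycles;
otherwise the most dilute level is dropped and the fit retried — the rule
set is configurable because published work rarely states how a 4-log vs
5-log call was made. Replicate CV is `100 × SD/mean` of Cq; inter-assay CV
pools all replicates across runs by default (CV-of-run-means is the
alternative). The acceptance gate passes an assay iff its linear range
spans ≥ 5 logs **and** efficiency lies in the inclusive interval
[90%, 110%].

## Primer rule engine

Rules operate on annotated records (SNPs, editing sites, hairpin Tm, dimer
ΔG are inputs; no thermodynamics or database queries are performed).
Boundary conventions: hairpin fails strictly above 60 °C; amplicon window
inclusive; 3′ positions are 1-based from the terminus, the SNP window being
positions 1–5. The dimer rule defaults to rejecting ΔG **below** −10
kcal/mol — a more negative ΔG means a more stable, more troublesome dimer —
with a `literal_dg_rule` switch for the opposite reading, since the
inequality is sometimes quoted inverted. "Rare" SNPs are those below 1 per
250,000 alleles; unknown frequency counts as rare. The selection walk
relaxes after 15 consecutive failures, by default tolerating rare SNPs
first and waiving the exon-junction requirement second (the order is a
policy field; either is defensible and both are selectable). Relaxation is
monotone: anything passing strict passes relaxed.

## Synthetic data: what it emulates, what it does not

Expression matrices are log-normal (per-gene baseline log2 level U(6,12),
per-sample scaling offset N(0, 0.1), per-gene Gaussian log2 noise, default
0.25) with group shifts on differential genes expressed in units of the
residual SD and applied to the later half of the groups; over-dispersed
"wide" genes get log2 noise 1.3 (linear CV ≈ 110%, comfortably beyond the
45% filter) with zero group effect. Cq matrices follow
`baseline + sample effect + group shift + N(0, noise)` with stable genes at
0.1 cycles and unstable ones at 1.0 cycles plus 1.5-cycle group shifts,
matching the magnitudes seen in validated assay panels (replicate CVs of a
few tenths of a percent at Cq ≈ 25–35). Planted group shifts alternate in
sign from gene to gene: every stability method normalizes against a
per-sample reference (explicitly for NormFinder's sample centring,
implicitly through pairwise ratios elsewhere), and a panel in which *all*
unstable genes co-shift one way moves that reference itself — a coherent
co-regulation scenario no reference-gene method is designed to untangle,
and not how unrelated housekeeping genes misbehave.

What passing these simulations does **not** show: robustness to microarray
probe effects, batch structure, missing-not-at-random dropout, or
co-regulated gene modules; real datasets bring all four. The two bundled
study shapes (a 2-group case/control design of 7+7 and a 5-group design of
8 per group) are desk-scale stand-ins for cohort designs an order of
magnitude larger.

## Numerical and design choices

- Ties in every ranking are averaged (scipy `rankdata`).
- The trigamma inverse in the moderation fit is Newton iteration from the
  asymptotic start `0.5 + 1/x`, 50 iterations max, relative tolerance 1e-10.
- `expression_cv` returns NaN (flagged) for non-positive means or fewer
  than two values rather than raising: a screen over 150+ genes should not
  abort on one degenerate probe.
- Gene symbols are upper-cased and trimmed on every boundary (candidate
  lists, platform tables, Cq headers); probe identifiers stay case-sensitive.
- Reports are byte-stable for a fixed config and seed; logs (with
  timestamps) go to stderr only.
- Acceptance-style recovery runs use 20 replicate simulations and 100
  dilution-series fits; these sizes put Monte-Carlo error well below the
  effect sizes being recovered while keeping a full run under a few seconds.

## Known limitations

- NormFinder here is the variance-components form, not Andersen's exact
  estimator; rankings agree in simulation but stability *values* are not
  comparable across implementations.
- The GEO Series Matrix reader targets the common single-table layout and
  leaves group assignment to an explicit sample→group file; it does not
  infer groups from characteristics lines.
- No network access anywhere: datasets, annotation tables and primer
  annotations are always user-supplied files.
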