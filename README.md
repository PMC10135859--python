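# refgenekit

Tools for choosing and validating **reference genes for RT-qPCR
normalization** in a specific clinical or experimental setting, the way a
careful qPCR lab would do it end to end:

1. **In-silico uniformity screen.** Candidate reference genes are looked up in
   transcriptomic datasets (GEO Series Matrix files or plain TSV matrices)
   with sample group labels. Every probe is tested for between-group
   differential expression with an empirical-Bayes moderated one-way F test;
   p-values are Benjamini–Hochberg adjusted platform-wide. Genes are ranked
   per dataset by adjusted p-value — rank 1 goes to the gene with p_adj
   closest to 1, i.e. the *least* evidence of group-dependent expression —
   ranks are summed across datasets into a composite rank, and shortlisted
   genes whose linear-scale coefficient of variation exceeds 45% in any
   dataset are excluded (uniform on average, but too dispersed to normalize
   against).
2. **Primer-pair vetting.** A deterministic rule engine over annotated primer
   pairs: amplicon size in [70, 120] bp, exon-junction spanning, no known SNP
   in the last five 3′ positions of either primer, no A-to-I editing site in
   either annealing footprint, hairpin Tm ≤ 60 °C, no homo-/hetero-dimer with
   ΔG below −10 kcal/mol. After 15 consecutive failures the policy relaxes
   stepwise (tolerate rare/unknown-frequency SNPs, then waive the junction
   requirement), mirroring practical primer-design workflows.
3. **Assay QC.** Standard curves on serial cDNA dilutions: efficiency
   `E% = (10^(−1/slope) − 1) × 100` from the Cq-vs-log10(dilution) slope
   (−3.3219 cycles/log ⇔ 100%), linear dynamic range by iteratively dropping
   the most dilute level, intra-/inter-assay replicate CV, and an acceptance
   gate requiring a 5-log dynamic range with efficiency in [90%, 110%].
4. **Expression-stability consensus.** The four standard stability
   algorithms on Cq data — geNorm (stepwise exclusion on the M value plus
   the V(n/n+1) pairwise variation), NormFinder (variance-components
   stability value), BestKeeper (Cq dispersion and correlation with the
   geometric-mean index), and the comparative ΔCt method — aggregated by the
   geometric mean of ranks (RefFinder-style consensus).

A synthetic-data module generates every input with known ground truth
(planted uniform/differential genes, planted stability orderings, dilution
series with known efficiency, primer tables violating chosen rules), so the
whole pipeline is testable without any downloads.

## Worked example

Rank a small Cq panel (three candidate reference genes and two classical
housekeeping genes, six patients in two groups):

```python
import pandas as pd
from refgenekit import CqMatrix, rank_stability

cq = pd.DataFrame(
    {
        "POLR2B": [27.1, 27.3, 27.2, 27.0, 27.4, 27.2],
        "SDHA":   [24.8, 25.1, 24.9, 24.7, 25.0, 25.0],
        "ACTR3":  [26.2, 26.3, 26.4, 26.1, 26.5, 26.2],
        "GAPDH":  [22.0, 23.5, 21.8, 24.0, 22.9, 25.1],
        "B2M":    [20.5, 21.9, 20.2, 22.6, 21.0, 23.3],
    },
    index=[f"patient{i+1}" for i in range(6)],
)
groups = {f"patient{i+1}": ("control" if i < 3 else "case") for i in range(6)}
result = rank_stability(CqMatrix(cq=cq, groups=groups))
print(result.report().round(3).to_string())
```

```text
        geNorm_value  geNorm_rank  NormFinder_value  NormFinder_rank  BestKeeper_value  BestKeeper_rank  deltaCt_value  deltaCt_rank  geomean_rank  final_rank
gene
POLR2B         0.075          1.5             0.545              2.0             0.100              1.0          0.671           2.0         1.565         1.0
SDHA           0.106          3.0             0.525              1.0             0.117              3.0          0.666           1.0         1.732         2.0
ACTR3          0.075          1.5             0.597              3.0             0.117              2.0          0.714           3.0         2.280         3.0
B2M            1.266          4.0             0.814              4.0             1.017              5.0          0.996           4.0         4.229         4.0
GAPDH          1.003          5.0             0.857              5.0             0.983              4.0          1.003           5.0         4.729         5.0
```

The tight candidate genes get geNorm M values around 0.1 cycles of pairwise
log-ratio SD and occupy consensus ranks 1–3; the two classical genes, whose
Cq drifts by over a cycle between groups, land at the bottom under every
method (M > 1, NormFinder stability > 0.8) — exactly the situation in which
normalizing to an "obvious" housekeeping gene distorts the biology.

The same works from the shell on TSV files:

```sh
refgenekit simulate --out demo --seed 7     # self-contained demo workspace
refgenekit run --config demo/config.yaml    # screen → primers → QC → stability
refgenekit stability --cq demo/cq.tsv --groups demo/cq_groups.tsv --out demo/out
```

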