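import numpy as np
import pandas as pd
import pytest

from refgenekit.stability import CqMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230411)


@pytest.fixture
def small_cq(rng):
    """4 genes x 6 samples; mild independent cycle noise around gene baselines."""
    genes = ["G1", "G2", "G3", "G4"]
    base = np.array([24.0, 27.0, 30.0, 33.0])
    cq = base + rng.normal(0, 0.4, size=(6, 4))
    return CqMatrix(
        cq=pd.DataFrame(cq, index=[f"s{i}" for i in range(6)], columns=genes)
    )


@pytest.fixture
def grouped_cq(rng):
    """5 genes x 8 samples in two groups; G5 carries a 1.2-cycle group shift."""
    genes = ["G1", "G2", "G3", "G4", "G5"]
    base = np.array([22.0, 25.0, 28.0, 30.0, 26.0])
    cq = base + rng.normal(0, 0.3, size=(8, 5))
    cq[4:, 4] += 1.2
    samples = [f"s{i}" for i in range(8)]
    groups = {s: ("a" if i < 4 else "b") for i, s in enumerate(samples)}
    return CqMatrix(cq=pd.DataFrame(cq, index=samples, columns=genes), groups=groups)


# ---------------------------------------------------------------------------
# independent oracles (plain-loop definitions, no reuse of package internals)
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Hand step-up Benjamini-Hochberg."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_pos in range(m, 0, -1):
        i = order[rank_pos - 1]
        val = min(prev, p[i] * m / rank_pos)
        adj[i] = val
        prev = val
    return adj


def genorm_m_oracle(Q):
    """M values from the definition: plain loops over gene pairs."""
    import math

    genes = list(Q.columns)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                math.log2(Q.loc[s, j] / Q.loc[s, k]) for s in Q.index
            ]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            sds.append(math.sqrt(var))
        out[j] = sum(sds) / len(sds)
    return out


def genorm_exclusion_oracle(Q):
    """Recompute all M at every iteration; drop the highest-M gene."""
    remaining = Q.copy()
    order = []
    while remaining.shape[1] > 2:
        m = genorm_m_oracle(remaining)
        worst = max(sorted(m), key=lambda g: m[g])
        order.append(worst)
        remaining = remaining.drop(columns=[worst])
    return order, list(remaining.columns)


def genorm_v_oracle(Q, ranked):
    """V(n/n+1) from the definition via per-sample geometric means."""
    import math

    out = []
    for n in range(2, len(ranked)):
        logs = []
        for s in Q.index:
            nf_n = math.prod(Q.loc[s, g] for g in ranked[:n]) ** (1.0 / n)
            nf_n1 = math.prod(Q.loc[s, g] for g in ranked[: n + 1]) ** (1.0 / (n + 1))
            logs.append(math.log2(nf_n / nf_n1))
        mean = sum(logs) / len(logs)
        var = sum((x - mean) ** 2 for x in logs) / (len(logs) - 1)
        out.append(math.sqrt(var))
    return out


def delta_ct_oracle(cq_frame):
    """Mean pairwise SD of Cq differences, plain loops."""
    import math

    genes = list(cq_frame.columns)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diffs = [cq_frame.loc[s, j] - cq_frame.loc[s, k] for s in cq_frame.index]
            mean = sum(diffs) / len(diffs)
            var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
            sds.append(math.sqrt(var))
        out[j] = sum(sds) / len(sds)
    return out
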