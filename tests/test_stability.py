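import numpy as np
import pandas as pd
import pytest

from refgenekit.stability import (
    CqMatrix,
    bestkeeper,
    cq_to_relative_quantity,
    delta_ct_stability,
    genorm,
    genorm_pairwise_variation,
    normfinder,
    rank_stability,
    reffinder_consensus,
)
from refgenekit.synthetic import SimulationConfig, simulate_cq_matrix

from conftest import (
    delta_ct_oracle,
    genorm_exclusion_oracle,
    genorm_m_oracle,
    genorm_v_oracle,
)


def cq_frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=genes)


class TestRelativeQuantity:
    def test_doubling_assay_halves_per_cycle(self):
        cq = CqMatrix(cq=cq_frame([[20.0], [21.0], [22.0]]))
        Q = cq_to_relative_quantity(cq)
        assert Q.iloc[:, 0].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_minimum_cq_sample_gets_unity(self, small_cq):
        Q = cq_to_relative_quantity(small_cq)
        assert np.allclose(Q.max(axis=0), 1.0)

    def test_measured_efficiency_used(self):
        cq = CqMatrix(
            cq=cq_frame([[20.0], [21.0]]), efficiency={"G0": 1.9}
        )
        Q = cq_to_relative_quantity(cq)
        assert Q.iloc[1, 0] == pytest.approx(1 / 1.9, abs=1e-4)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            CqMatrix(cq=cq_frame([[20.0], [21.0]]), efficiency={"G0": 0.9})


class TestGenorm:
    def test_perfectly_proportional_genes_have_zero_m(self, rng):
        qa = rng.uniform(0.1, 1.0, 6)
        Q = pd.DataFrame({"A": qa, "B": 0.5 * qa, "C": rng.uniform(0.1, 1, 6)})
        m = genorm_m_oracle(Q)
        assert m["A"] < m["C"] and m["B"] < m["C"]
        res = genorm(Q)
        # pairwise SD of log ratio A/B is exactly zero
        assert np.log2(Q["A"] / Q["B"]).std(ddof=1) == pytest.approx(0.0, abs=1e-12)

    def test_scaling_one_gene_leaves_m_unchanged(self, small_cq):
        Q = cq_to_relative_quantity(small_cq)
        res1 = genorm(Q)
        Q2 = Q.copy()
        Q2["G2"] = Q2["G2"] * 7.3
        res2 = genorm(Q2)
        for g in Q.columns:
            assert res1.first_pass_m[g] == pytest.approx(res2.first_pass_m[g], abs=1e-12)

    def test_matches_bruteforce_oracle(self, small_cq):
        """M values, exclusion order and ranking equal the definitional oracle."""
        Q = cq_to_relative_quantity(small_cq)
        res = genorm(Q)
        oracle_m = genorm_m_oracle(Q)
        for g in Q.columns:
            assert res.first_pass_m[g] == pytest.approx(oracle_m[g], abs=1e-12)
        exc, final_pair = genorm_exclusion_oracle(Q)
        assert res.exclusion_order == exc
        assert set(final_pair) == {g for g, r in res.ranking.items() if r == 1.5}

    def test_pairwise_variation_matches_oracle(self, grouped_cq):
        Q = cq_to_relative_quantity(grouped_cq)
        res = genorm(Q)
        v_oracle = genorm_v_oracle(Q, res.ranked_genes)
        assert res.pairwise_v == pytest.approx(v_oracle, abs=1e-10)
        assert all(v >= 0 for v in res.pairwise_v)

    def test_proportional_extra_gene_gives_zero_v(self, rng):
        qa = rng.uniform(0.1, 1.0, 8)
        qb = rng.uniform(0.1, 1.0, 8)
        # third gene proportional to the geomean of the first two
        qc = np.sqrt(qa * qb) * 0.4
        Q = pd.DataFrame({"A": qa, "B": qb, "C": qc})
        v = genorm_pairwise_variation(Q, ["A", "B", "C"])
        assert v[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            genorm(pd.DataFrame({"A": [1, 0.5, 0.25], "B": [1, 0.5, 0.2]}))


class TestNormfinder:
    def test_constant_centered_gene_is_most_stable(self):
        # G0 tracks the sample mean exactly -> zero centred variance
        base = np.array([[20, 25, 30.0]]) + np.array([[0.0], [1.0], [2.0], [3.0]])
        jitter = np.zeros((4, 3))
        jitter[:, 1] = [0.3, -0.2, 0.4, -0.5]
        jitter[:, 2] = -jitter[:, 1]
        Q = pd.DataFrame(np.exp2(-(base + jitter)), columns=["G0", "G1", "G2"])
        values, ranks = normfinder(Q)
        assert ranks["G0"] == 1.0
        assert values["G0"] == pytest.approx(0.0, abs=1e-12)

    def test_single_group_degenerates_to_ungrouped(self, small_cq):
        Q = cq_to_relative_quantity(small_cq)
        v1, r1 = normfinder(Q)
        groups = {s: "only" for s in Q.index}
        v2, r2 = normfinder(Q, groups)
        assert v1 == pytest.approx(v2)

    def test_undersized_group_falls_back_to_ungrouped(self, small_cq):
        Q = cq_to_relative_quantity(small_cq)
        groups = {s: ("a" if i else "b") for i, s in enumerate(Q.index)}
        v_grouped, _ = normfinder(Q, groups)
        v_plain, _ = normfinder(Q)
        assert v_grouped == pytest.approx(v_plain)

    def test_group_shifted_gene_ranks_worst(self):
        """A 1.5-cycle group shift must dominate the stability value."""
        worst_count = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_groups=2, n_per_group=8,
                cq_noise_sd={f"G{j}": 0.15 for j in range(6)},
                cq_group_shift={"G5": 1.5},
            )
            cq, _ = simulate_cq_matrix(cfg)
            Q = cq_to_relative_quantity(cq)
            _, ranks = normfinder(Q, cq.groups)
            if ranks["G5"] == max(ranks.values()):
                worst_count += 1
        assert worst_count >= 19


class TestBestkeeper:
    def test_constant_gene_is_best(self):
        cq = CqMatrix(cq=cq_frame([[25, 30.0], [25, 31.0], [25, 29.0]]))
        table, ranks = bestkeeper(cq)
        assert table.loc["G0", "SD_cq"] == 0.0
        assert table.loc["G0", "CV_percent"] == 0.0
        assert ranks["G0"] == 1.0

    def test_shift_invariance_of_sd(self, small_cq):
        t1, _ = bestkeeper(small_cq)
        shifted = CqMatrix(cq=small_cq.cq.assign(G2=small_cq.cq["G2"] + 3.0))
        t2, _ = bestkeeper(shifted)
        assert t1.loc["G2", "SD_cq"] == pytest.approx(t2.loc["G2", "SD_cq"])

    def test_mad_oracle(self, small_cq):
        table, _ = bestkeeper(small_cq)
        for g in small_cq.genes:
            x = small_cq.cq[g].to_numpy()
            mad = np.abs(x - x.mean()).mean()
            assert table.loc[g, "SD_cq"] == pytest.approx(mad, abs=1e-12)
            assert table.loc[g, "CV_percent"] == pytest.approx(
                100 * mad / x.mean(), abs=1e-10
            )

    def test_index_correlation_is_pearson_vs_geomean(self, small_cq):
        from scipy import stats as sps

        table, _ = bestkeeper(small_cq)
        index = sps.gmean(small_cq.cq.to_numpy(), axis=1)
        for g in small_cq.genes:
            r_ref = sps.pearsonr(small_cq.cq[g], index)[0]
            assert table.loc[g, "r_vs_index"] == pytest.approx(r_ref, abs=1e-12)


class TestDeltaCt:
    def test_constant_offset_pair_has_zero_sd(self):
        a = np.array([24.0, 25.0, 26.0, 27.0])
        cq = CqMatrix(cq=cq_frame(np.column_stack([a, a + 3, a * 1.1])))
        values, _ = delta_ct_stability(cq)
        # the pairwise SD between G0 and G1 is zero, so both benefit equally
        oracle = delta_ct_oracle(cq.cq)
        assert values == pytest.approx(oracle, abs=1e-12)

    def test_equals_genorm_first_pass_when_e_is_2(self, grouped_cq):
        """log2(Qj/Qk) differs from Cq_k - Cq_j by a constant, so the SDs agree."""
        values, _ = delta_ct_stability(grouped_cq)
        Q = cq_to_relative_quantity(grouped_cq)
        first_m = genorm(Q).first_pass_m
        for g in grouped_cq.genes:
            assert values[g] == pytest.approx(first_m[g], abs=1e-12)

    def test_matches_direct_recomputation(self, grouped_cq):
        values, ranks = delta_ct_stability(grouped_cq)
        oracle = delta_ct_oracle(grouped_cq.cq)
        assert values == pytest.approx(oracle, abs=1e-12)


class TestConsensus:
    def test_unanimous_best_gene(self):
        ranks = {m: {"A": 1.0, "B": 2.0} for m in "wxyz"}
        out = reffinder_consensus(ranks)
        assert out.loc["A", "geomean_rank"] == 1.0
        assert out.loc["A", "final_rank"] == 1.0

    def test_geomean_of_1_2_4_8(self):
        ranks = {
            "m1": {"A": 1.0, "B": 2.0},
            "m2": {"A": 2.0, "B": 1.0},
            "m3": {"A": 4.0, "B": 3.0},
            "m4": {"A": 8.0, "B": 4.0},
        }
        out = reffinder_consensus(ranks)
        assert out.loc["A", "geomean_rank"] == pytest.approx(2.8284, abs=1e-4)

    def test_geomean_bounded_by_min_max(self, rng):
        genes = [f"g{i}" for i in range(8)]
        ranks = {
            f"m{k}": dict(zip(genes, rng.permutation(len(genes)) + 1.0))
            for k in range(4)
        }
        out = reffinder_consensus(ranks)
        mat = out[[c for c in out.columns if c.startswith("rank_")]]
        assert (out["geomean_rank"] >= mat.min(axis=1) - 1e-12).all()
        assert (out["geomean_rank"] <= mat.max(axis=1) + 1e-12).all()

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="same gene set"):
            reffinder_consensus({"m1": {"A": 1.0}, "m2": {"B": 1.0}})


class TestOrderingInvariance:
    def test_all_methods_invariant_to_sample_and_gene_order(self, grouped_cq, rng):
        res1 = rank_stability(grouped_cq)
        perm_s = rng.permutation(grouped_cq.samples)
        perm_g = rng.permutation(grouped_cq.genes)
        shuffled = CqMatrix(
            cq=grouped_cq.cq.loc[perm_s, perm_g], groups=grouped_cq.groups
        )
        res2 = rank_stability(shuffled)
        for method in res1.per_method:
            for g in grouped_cq.genes:
                assert res1.per_method[method][g]["stability_value"] == pytest.approx(
                    res2.per_method[method][g]["stability_value"], abs=1e-10
                )

    def test_missing_cq_drops_sample(self, grouped_cq):
        cq = grouped_cq.cq.copy()
        cq.iloc[0, 0] = np.nan
        res = rank_stability(CqMatrix(cq=cq, groups=grouped_cq.groups))
        full = delta_ct_oracle(cq.dropna())
        for g, d in res.per_method["deltaCt"].items():
            assert d["stability_value"] == pytest.approx(full[g], abs=1e-12)
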