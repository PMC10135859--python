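import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from refgenekit.screening import (
    ExpressionDataset,
    auto_log2,
    benjamini_hochberg,
    collapse_probes,
    composite_rank,
    expression_cv,
    filter_by_cv,
    moderated_group_test,
    rank_by_padj,
    screen_datasets,
)
from refgenekit.synthetic import SimulationConfig, simulate_expression_dataset

from conftest import bh_oracle


def make_dataset(matrix, groups, mapping=None, log2_applied=True):
    probes = [f"p{i}" for i in range(matrix.shape[0])]
    samples = list(groups)
    return ExpressionDataset(
        dataset_id="toy",
        values=pd.DataFrame(matrix, index=probes, columns=samples),
        groups=groups,
        probe_to_gene=mapping or {},
        log2_applied=log2_applied,
    )


class TestModeratedGroupTest:
    def test_constant_probe_has_no_signal(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        mat = np.array([[5.0, 5.0, 5.0, 5.0], [4.0, 6.0, 3.0, 7.0]])
        res = moderated_group_test(make_dataset(mat, groups))
        assert res.loc["p0", "F_stat"] == 0.0
        assert res.loc["p0", "p_adj"] == 1.0

    def test_equal_group_means_give_f_zero(self):
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        row = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        mat = np.vstack([row, row + 5])
        res = moderated_group_test(make_dataset(mat, groups))
        assert res["F_stat"].eq(0.0).all()
        assert res["p_value"].eq(1.0).all()

    def test_zero_prior_df_matches_ordinary_anova(self, rng):
        """Without moderation the statistic is the classic one-way ANOVA F."""
        groups = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        mat = rng.normal(8, 1, size=(20, 10))
        mat[0, 5:] += 4.0  # one probe with a clear group shift
        ds = make_dataset(mat, groups)
        res = moderated_group_test(ds, prior_df=0)
        labels = np.array(list(groups.values()))
        for i, probe in enumerate(res.index):
            f_ref, p_ref = stats.f_oneway(mat[i, labels == "A"], mat[i, labels == "B"])
            assert res.loc[probe, "F_stat"] == pytest.approx(f_ref, rel=1e-10)
            assert res.loc[probe, "p_value"] == pytest.approx(p_ref, rel=1e-9)

    def test_moderation_shrinks_variance_outlier_f(self, rng):
        """A high-variance null probe must not be declared significant."""
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        mat = rng.normal(8, 0.3, size=(200, 20))
        mat[0] = rng.normal(8, 3.0, size=20)  # over-dispersed null probe
        res = moderated_group_test(make_dataset(mat, groups))
        assert res.loc["p0", "p_adj"] > 0.05

    def test_single_group_is_configuration_error(self):
        groups = {"s0": "A", "s1": "A", "s2": "A"}
        with pytest.raises(ValueError, match="groups"):
            moderated_group_test(make_dataset(np.ones((2, 3)), groups))

    def test_auto_log_rule_fires_on_linear_scale(self, rng):
        linear = pd.DataFrame(np.exp2(rng.normal(8, 1, size=(30, 6))))
        out, applied = auto_log2(linear)
        assert applied and out.to_numpy().max() < 20
        logged = pd.DataFrame(rng.normal(8, 1, size=(30, 6)))
        _, applied2 = auto_log2(logged)
        assert not applied2


class TestBenjaminiHochberg:
    def test_hand_stepup_example(self):
        assert benjamini_hochberg([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_oracle_and_bounds(self, p):
        adj = benjamini_hochberg(p)
        assert np.allclose(adj, bh_oracle(p))
        assert np.all(adj <= 1) and np.all(adj >= np.asarray(p) - 1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = benjamini_hochberg(p)
        adj_perm = benjamini_hochberg([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)


class TestCollapseAndRank:
    def test_collapse_picks_smallest_padj_by_default(self):
        stats_df = pd.DataFrame(
            {"p_adj": [0.2, 0.8], "mean_expr": [5.0, 9.0]}, index=["pA", "pB"]
        )
        mapping = {"pA": ("G1",), "pB": ("G1",)}
        out = collapse_probes(stats_df, mapping)
        assert out.loc["G1", "probe_used"] == "pA"
        assert out.loc["G1", "p_adj"] == 0.2
        out2 = collapse_probes(stats_df, mapping, rule="max_padj")
        assert out2.loc["G1", "probe_used"] == "pB"
        out3 = collapse_probes(stats_df, mapping, rule="max_mean")
        assert out3.loc["G1", "probe_used"] == "pB"

    def test_unmapped_genes_reported_missing(self):
        stats_df = pd.DataFrame({"p_adj": [0.5]}, index=["pA"])
        out = collapse_probes(stats_df, {"pA": ("G1",)})
        candidates = ["G1", "G2", "G3"]
        missing = [g for g in candidates if g not in out.index]
        assert missing == ["G2", "G3"]

    def test_rank_one_goes_to_highest_padj(self):
        ranks = rank_by_padj({"A": 0.99, "B": 0.50, "C": 0.90})
        assert ranks == {"A": 1.0, "C": 2.0, "B": 3.0}

    def test_tied_padj_share_average_rank(self):
        assert rank_by_padj({"A": 0.5, "B": 0.5}) == {"A": 1.5, "B": 1.5}

    def test_ranks_match_sort_positions(self, rng):
        padj = {f"g{i}": float(p) for i, p in enumerate(rng.uniform(size=50))}
        ranks = rank_by_padj(padj)
        by_sort = {
            g: i + 1
            for i, g in enumerate(sorted(padj, key=lambda g: -padj[g]))
        }
        assert ranks == {g: float(by_sort[g]) for g in padj}

    def test_ranks_invariant_under_monotone_transform(self, rng):
        padj = {f"g{i}": float(p) for i, p in enumerate(rng.uniform(0.01, 0.99, 30))}
        transformed = {g: p**3 for g, p in padj.items()}
        assert rank_by_padj(padj) == rank_by_padj(transformed)


class TestCompositeRank:
    def test_sum_of_ranks_orders_shortlist(self):
        comp, missing = composite_rank(
            {"d1": {"A": 1, "B": 2}, "d2": {"A": 3, "B": 1}}
        )
        assert comp == {"B": 3.0, "A": 4.0}
        assert list(comp) == ["B", "A"]
        assert missing == set()

    def test_gene_missing_in_one_dataset_is_excluded(self):
        comp, missing = composite_rank(
            {"d1": {"A": 1, "B": 2, "C": 3}, "d2": {"A": 2, "B": 1}}
        )
        assert "C" not in comp and missing == {"C"}

    def test_single_dataset_identity(self):
        comp, _ = composite_rank({"d1": {"A": 2.0, "B": 1.0}})
        assert comp == {"B": 1.0, "A": 2.0}

    def test_dataset_permutation_invariance_and_tie_shift(self):
        d1, d2 = {"A": 1.0, "B": 2.0}, {"A": 2.0, "B": 1.0}
        c12, _ = composite_rank({"x": d1, "y": d2})
        c21, _ = composite_rank({"y": d2, "x": d1})
        assert c12 == c21
        tied = {"A": 1.5, "B": 1.5}
        c3, _ = composite_rank({"x": d1, "y": d2, "z": tied})
        assert all(c3[g] == c12[g] + 1.5 for g in c12)


class TestExpressionCV:
    @pytest.mark.parametrize(
        "values,expected",
        [([10.0, 10.0, 10.0], 0.0), ([8.0, 12.0], 28.2843), ([1.0, 2.0, 3.0], 50.0)],
    )
    def test_linear_scale_examples(self, values, expected):
        groups = {f"s{i}": "A" for i in range(len(values))}
        ds = make_dataset(
            np.array([values]), groups, mapping={"p0": ("G1",)}, log2_applied=False
        )
        assert expression_cv(ds, "G1") == pytest.approx(expected, abs=1e-3)

    def test_log_matrix_is_delogged_first(self):
        groups = {"s0": "A", "s1": "A"}
        ds = make_dataset(
            np.log2(np.array([[8.0, 12.0]])), groups,
            mapping={"p0": ("G1",)}, log2_applied=True,
        )
        assert expression_cv(ds, "G1") == pytest.approx(28.2843, abs=1e-3)

    def test_cv_filter_strict_threshold(self):
        table = {
            "A": {"d1": 46.0, "d2": 10.0},
            "B": {"d1": 45.0, "d2": 45.0},
            "C": {"d1": 10.0, "d2": 10.0},
        }
        retained, excluded = filter_by_cv(table, threshold=45.0)
        assert retained == ["B", "C"]
        assert excluded == {"A": ["d1"]}


class TestScreenEndToEnd:
    def test_planted_high_cv_genes_are_the_excluded_set(self):
        """Shortlisted over-dispersed genes fall to the CV filter, exactly."""
        uniform = tuple(f"U{i}" for i in range(10))
        wide = tuple(f"W{i}" for i in range(8))
        de = {f"D{i}": 4.0 for i in range(8)}
        datasets = []
        for seed, (k, n) in zip((11, 12), ((2, 10), (5, 6))):
            cfg = SimulationConfig(
                seed=seed, n_groups=k, n_per_group=n,
                planted_uniform=uniform, planted_high_cv=wide, planted_de=de,
            )
            ds, _ = simulate_expression_dataset(cfg, dataset_id=f"d{seed}")
            datasets.append(ds)
        candidates = list(uniform) + list(wide) + list(de)
        report, records = screen_datasets(datasets, candidates, shortlist_size=18)
        excluded = {g for g, r in records.items() if r.status == "excluded_cv"}
        assert excluded == {w.upper() for w in wide}
        shortlisted = {g for g, r in records.items() if r.status == "shortlisted"}
        assert shortlisted == {u.upper() for u in uniform}

    def test_planted_de_genes_rank_worse_than_uniform(self):
        """Group-shifted genes get higher (worse) composite ranks."""
        uniform = tuple(f"U{i}" for i in range(6))
        de = {f"D{i}": 4.0 for i in range(6)}
        cfg = SimulationConfig(
            seed=5, n_groups=2, n_per_group=10,
            planted_uniform=uniform, planted_de=de,
        )
        ds, _ = simulate_expression_dataset(cfg)
        report, _ = screen_datasets([ds], list(uniform) + list(de), shortlist_size=6)
        comp = report["composite_rank"].dropna()
        assert comp[[u.upper() for u in uniform]].max() < comp[
            [d.upper() for d in de]
        ].min()
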