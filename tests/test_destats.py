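"""Statistical kernel: normalization, DE, BH, rank-sum, hypergeometric ORA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nichemapper.destats import (
    bh_adjust,
    cpm_normalize,
    de_test,
    hypergeom_ora,
    rank_sum,
)
from nichemapper.synth import PlantedReceptor, SynthConfig, simulate_bulk


def brute_force_bh(p):
    """Independent step-down reference: padj_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        out[idx] = min(1.0, min(candidates))
    return out


def enumeration_ranksum_p(x, y):
    """Independent exact two-sided rank-sum p by full relabeling enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    ranks = stats.rankdata(pooled)

    def u_of(idx):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        return ranks[sel].sum() - n1 * (n1 + 1) / 2.0

    d_obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        if abs(u_of(comb) - mu) >= d_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestCpmNormalize:
    def test_two_sample_column(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
        out = cpm_normalize(counts)
        assert np.allclose(out["s1"], [1e5, 9e5])

    def test_equal_counts_share_evenly(self):
        counts = pd.DataFrame({"s1": [1, 1, 1, 1]})
        assert np.allclose(cpm_normalize(counts)["s1"], 2.5e5)

    def test_zero_row_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 7]}, index=["g0", "g1"])
        assert (cpm_normalize(counts).loc["g0"] == 0).all()

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [3, 1], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm_normalize(counts)


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.09]), [0.03, 0.03, 0.09])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_brute_force_and_statsmodels(self, ps):
        ours = bh_adjust(ps)
        assert np.allclose(ours, brute_force_bh(ps))
        assert np.allclose(ours, multipletests(ps, method="fdr_bh")[1])


class TestDeTest:
    def test_identical_groups_are_null(self):
        col = [5, 10, 20]
        counts = pd.DataFrame(
            {f"s{i}": col for i in range(6)}, index=["g1", "g2", "g3"]
        )
        groups = ["control"] * 3 + ["disease"] * 3
        de = de_test(counts, groups, disease_label="disease")
        assert np.allclose(de["log2fc"], 0)
        assert np.allclose(de["p"], 1)

    def test_fold_change_hand_arithmetic(self):
        # pseudocount 0.5: mean CPM 100 vs 25 -> log2(100.5/25.5)
        assert np.isclose(np.log2(100.5 / 25.5), 1.9786, atol=1e-4)
        counts = pd.DataFrame(
            {
                "c1": [25, 10**6 - 25],
                "c2": [25, 10**6 - 25],
                "d1": [100, 10**6 - 100],
                "d2": [100, 10**6 - 100],
            },
            index=["target", "rest"],
        )
        de = de_test(counts, ["control", "control", "disease", "disease"],
                     disease_label="disease")
        assert de.loc["target", "log2fc"] == pytest.approx(np.log2(100.5 / 25.5))

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        with pytest.raises(ValueError, match="2 samples"):
            de_test(counts, ["control", "disease", "disease"])

    def test_planted_effect_power(self):
        """A +2 log2FC gene at n=50/group is BH-significant nearly always."""
        hits = 0
        n_reps = 60
        for seed in range(1, n_reps + 1):
            cfg = SynthConfig(
                seed=seed,
                n_genes=200,
                n_samples_per_group=50,
                planted_receptors=[PlantedReceptor("G0001", "bcCML", 2.0)],
            )
            counts, groups = simulate_bulk(cfg)["bcCML"]
            de = de_test(counts, groups, disease_label="disease")
            hits += de.loc["G0001", "padj"] < 0.05
        assert hits / n_reps >= 0.95


class TestRankSum:
    def test_separated_groups_exact(self):
        res = rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_identical_multisets_p_one(self):
        res = rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    def test_detection_fractions(self):
        res = rank_sum([0, 0, 2, 3], [0, 1])
        assert res.pct_in == pytest.approx(0.5)
        assert res.pct_out == pytest.approx(0.5)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 4), (5, 5), (2, 8)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            assert rank_sum(x, y).p == pytest.approx(enumeration_ranksum_p(x, y))

    def test_asymptotic_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=25)
        res = rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)
        assert res.statistic == pytest.approx(ref.statistic)


class TestHypergeomOra:
    def test_exact_tail_example(self):
        universe = [f"g{i}" for i in range(20)]
        geneset = universe[:5]
        query = universe[2:7]  # overlap 3
        k, p, _ = hypergeom_ora(query, geneset, universe)
        assert k == 3
        assert p == pytest.approx(1126 / 15504)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        k, p, _ = hypergeom_ora(universe[:3], universe[5:8], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_saturation(self):
        universe = [f"g{i}" for i in range(6)]
        k, p, _ = hypergeom_ora(universe, universe, universe)
        assert k == 6 and p == pytest.approx(1.0)

    def test_symmetric_in_query_and_geneset(self, rng):
        universe = [f"g{i}" for i in range(30)]
        a = list(rng.choice(universe, 8, replace=False))
        b = list(rng.choice(universe, 12, replace=False))
        assert hypergeom_ora(a, b, universe)[:2] == hypergeom_ora(b, a, universe)[:2]

    def test_offenders_listed(self):
        with pytest.raises(ValueError, match="alien"):
            hypergeom_ora(["alien"], ["g1"], ["g1", "g2"])
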