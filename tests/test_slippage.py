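"""Synapomorphic ranking, informative-character filtering and Spearman tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata, spearmanr

import decaylab.io as dio
from decaylab.datamodel import ValidationError
from decaylab.scoring import DecayRankTable
from decaylab.simulate import simulate_rank_pairs
from decaylab.slippage import (
    compare_taxa_ranks,
    filter_informative,
    holm_adjust,
    run_test_battery,
    spearman,
    synapomorphic_rank,
)
from tests.conftest import spearman_oracle, write_ladder_tree


def ladder_hypothesis(tmp_path, name="hyp", n_internal=4, contested=None):
    tree, assign = write_ladder_tree(tmp_path, name, n_internal, contested)
    return dio.read_hypothesis(tree, assign, focal_terminal="Focal")


class TestSynapomorphicRank:
    def test_one_character_per_node_ranks_tipward_to_rootward(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=4)
        ranking = synapomorphic_rank(hyp)
        assert ranking.ranks == {"c1": 1.0, "c2": 2.0, "c3": 3.0, "c4": 4.0}

    def test_shared_node_gives_midrank(self, tmp_path):
        tree, assign = write_ladder_tree(tmp_path, n_internal=3)
        # put an extra character on the tip-ward node
        with open(assign, "a") as fh:
            fh.write("c4,n1,\n")
        hyp = dio.read_hypothesis(tree, assign, focal_terminal="Focal")
        ranking = synapomorphic_rank(hyp)
        assert ranking.ranks["c1"] == ranking.ranks["c4"] == 1.5
        assert ranking.ranks["c2"] == 3.0

    def test_homoplasy_treatment_moves_contested_character(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=4, contested={"c3": "n1"})
        homology = synapomorphic_rank(hyp, "homology")
        homoplasy = synapomorphic_rank(hyp, "homoplasy")
        assert homology.depths["c3"] == 3
        # under homoplasy c3 joins c1 on the tip-ward node: depth 1, midrank 1.5
        assert homoplasy.depths["c3"] == 1
        assert homoplasy.ranks["c1"] == homoplasy.ranks["c3"] == 1.5
        assert homology.ranks["c3"] == 3.0

    def test_unknown_treatment_rejected(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path)
        with pytest.raises(ValidationError):
            synapomorphic_rank(hyp, "parsimony")


class TestFilterInformative:
    def test_extreme_depths_removed_intermediate_retained(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=5)
        ranking = synapomorphic_rank(hyp)
        decay = DecayRankTable(ranks={f"c{i}": float(i) for i in range(1, 6)})
        fr, fd = filter_informative(ranking, decay)
        # c1 (focal-clade node) and c5 (root) are uninformative
        assert set(fr.ranks) == {"c2", "c3", "c4"}
        assert set(fd.ranks) == {"c2", "c3", "c4"}
        # survivors are re-ranked from 1
        assert sorted(fr.ranks.values()) == [1.0, 2.0, 3.0]
        assert sorted(fd.ranks.values()) == [1.0, 2.0, 3.0]

    def test_too_few_survivors_rejected(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=3)
        ranking = synapomorphic_rank(hyp)
        decay = DecayRankTable(ranks={"c1": 1.0, "c2": 2.0, "c3": 3.0})
        with pytest.raises(ValidationError, match="informative"):
            filter_informative(ranking, decay)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(extra=st.lists(st.integers(2, 6), min_size=3, max_size=8))
    def test_never_removes_intermediate_depth(self, tmp_path_factory, extra):
        tmp = tmp_path_factory.mktemp("filter")
        tree, assign = write_ladder_tree(tmp, n_internal=7)
        with open(assign, "a") as fh:
            for j, depth in enumerate(extra):
                fh.write(f"x{j},n{depth},\n")
        hyp = dio.read_hypothesis(tree, assign, focal_terminal="Focal")
        ranking = synapomorphic_rank(hyp)
        decay = DecayRankTable(
            ranks={c: float(i + 1) for i, c in enumerate(sorted(ranking.ranks))}
        )
        fr, _ = filter_informative(ranking, decay)
        for char, depth in ranking.depths.items():
            if 1 < depth < 7:
                assert char in fr.ranks


class TestSpearman:
    def test_perfect_agreement_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        r, p, _ = spearman(x, x, p_method="t_approx")
        assert r == pytest.approx(1.0)
        r, _, _ = spearman(x, -x, p_method="t_approx")
        assert r == pytest.approx(-1.0)

    def test_constant_ranks_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_midrank_pearson_oracle(self, data):
        n = data.draw(st.integers(3, 30))
        ints = st.integers(0, 8)  # small range forces ties
        x = data.draw(st.lists(ints, min_size=n, max_size=n))
        y = data.draw(st.lists(ints, min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r, _, _ = spearman(x, y, p_method="t_approx")
        assert r == pytest.approx(spearman_oracle(x, y), abs=1e-12)
        assert r == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_equals_brute_force_enumeration_with_tie(self):
        """n = 6 with a tie: p must equal the exhaustive 720-permutation tail."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 3.0, 6.0, 5.0]
        r, p, method = spearman(x, y, p_method="exact_permutation")
        assert method == "exact_permutation"
        ry = rankdata(y)
        r_obs = pearsonr(rankdata(x), ry)[0]
        hits = 0
        for perm in itertools.permutations(ry):
            if abs(pearsonr(rankdata(x), np.array(perm))[0]) >= abs(r_obs) - 1e-12:
                hits += 1
        assert r == pytest.approx(r_obs, abs=1e-12)
        assert p == pytest.approx(hits / math.factorial(6), abs=1e-12)

    def test_exact_and_monte_carlo_agree_at_n7(self):
        x, y = simulate_rank_pairs(7, 0.6, seed=7)
        _, p_exact, _ = spearman(x, y, p_method="exact_permutation")
        n_perm = 20_000
        _, p_mc, _ = spearman(x, y, p_method="monte_carlo", n_perm=n_perm, seed=11)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / n_perm

    def test_monte_carlo_deterministic_under_seed(self):
        x, y = simulate_rank_pairs(15, -0.4, seed=2)
        out1 = spearman(x, y, p_method="monte_carlo", n_perm=2000, seed=5)
        out2 = spearman(x, y, p_method="monte_carlo", n_perm=2000, seed=5)
        assert out1 == out2


class TestBattery:
    def _decay_ranks(self, chars):
        return DecayRankTable(ranks={c: float(i + 1) for i, c in enumerate(chars)})

    def test_four_hypotheses_with_contested_yield_eight_tests(self, tmp_path):
        hyps = [
            ladder_hypothesis(tmp_path, f"h{i}", n_internal=5, contested={"c4": "n1"})
            for i in range(4)
        ]
        decay = self._decay_ranks([f"c{i}" for i in range(1, 6)])
        results = run_test_battery(decay, hyps, p_method="t_approx")
        assert len(results) == 8
        assert {(r.hypothesis_id, r.treatment) for r in results} == {
            (f"h{i}", t) for i in range(4) for t in ("homology", "homoplasy")
        }

    def test_hypothesis_without_contested_yields_one_test(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=5)
        decay = self._decay_ranks([f"c{i}" for i in range(1, 6)])
        results = run_test_battery(decay, [hyp], p_method="t_approx")
        assert len(results) == 1
        assert results[0].treatment == "homology"

    def test_identical_rankings_give_rs_one(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=6)
        decay = self._decay_ranks([f"c{i}" for i in range(1, 7)])
        (res,) = run_test_battery(decay, [hyp], p_method="exact_permutation")
        assert res.r_s == pytest.approx(1.0)

    def test_decay_resistant_apomorphies_give_negative_rs(self, tmp_path):
        """Decay-prone symplesiomorphies -> negative correlation by convention."""
        hyp = ladder_hypothesis(tmp_path, n_internal=6)
        # most decay-prone character sits at the root-most node
        decay = self._decay_ranks([f"c{i}" for i in range(6, 0, -1)])
        (res,) = run_test_battery(decay, [hyp], p_method="exact_permutation")
        assert res.r_s == pytest.approx(-1.0)

    def test_battery_invariant_to_orderings(self, tmp_path):
        hyps = [
            ladder_hypothesis(tmp_path, f"h{i}", n_internal=5, contested={"c2": "n1"})
            for i in range(3)
        ]
        decay = self._decay_ranks(["c3", "c1", "c5", "c2", "c4"])
        a = run_test_battery(decay, hyps, p_method="t_approx")
        b = run_test_battery(decay, list(reversed(hyps)), p_method="t_approx")
        assert a == b

    def test_filtered_battery_uses_informative_subset(self, tmp_path):
        hyp = ladder_hypothesis(tmp_path, n_internal=6)
        decay = self._decay_ranks([f"c{i}" for i in range(1, 7)])
        (res,) = run_test_battery(
            decay, [hyp], filtered=True, p_method="exact_permutation"
        )
        assert res.n_characters == 4  # c1 and c6 removed
        assert res.filtered

    def test_holm_adjustment_is_monotone_and_optional(self, tmp_path):
        hyps = [
            ladder_hypothesis(tmp_path, f"h{i}", n_internal=5, contested={"c4": "n1"})
            for i in range(2)
        ]
        decay = self._decay_ranks(["c2", "c5", "c1", "c4", "c3"])
        raw = run_test_battery(decay, hyps, p_method="t_approx")
        adj = run_test_battery(decay, hyps, p_method="t_approx", holm=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15


class TestCompareTaxa:
    def test_self_comparison_is_one(self):
        t = DecayRankTable(ranks={"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        res = compare_taxa_ranks(t, t, p_method="exact_permutation")
        assert res.r_s == pytest.approx(1.0)

    def test_disjoint_character_sets_rejected(self):
        a = DecayRankTable(ranks={"a": 1.0, "b": 2.0, "c": 3.0})
        b = DecayRankTable(ranks={"x": 1.0, "y": 2.0, "z": 3.0})
        with pytest.raises(ValidationError, match="shared"):
            compare_taxa_ranks(a, b)

    def test_reranks_within_intersection(self):
        # shared characters have gappy ranks in each table; r_s must use
        # ranks recomputed over the intersection only
        a = DecayRankTable(ranks={"a": 1.0, "b": 5.0, "c": 9.0, "q": 2.0})
        b = DecayRankTable(ranks={"a": 2.0, "b": 4.0, "c": 6.0, "z": 1.0})
        res = compare_taxa_ranks(a, b, p_method="exact_permutation")
        assert res.n_characters == 3
        assert res.r_s == pytest.approx(1.0)


def test_holm_adjust_matches_hand_computation():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
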