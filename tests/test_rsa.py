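"""RDMs, candidate models, tau-a, signed-rank inference, FDR, MDS, Dice."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from bodybubbles import rsa


# ---------------------------------------------------------------------------
# oracles

def tau_a_bruteforce(x, y):
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (n * (n - 1) / 2)


def signed_rank_exact(values, alternative):
    """Exact Wilcoxon signed-rank p by enumerating all sign assignments."""
    v = np.asarray(values, dtype=float)
    assert np.all(v != 0)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    n = len(v)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    if alternative == "greater":
        return float(np.mean(ws >= w_obs))
    p = 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs))
    return float(min(p, 1.0))


def bh_stepup(p, q):
    m = len(p)
    order = np.argsort(p)
    flags = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            flags[idx] = True
    return flags


def single_linkage_cophenetic(d):
    """O(n^3) nearest-neighbor agglomeration -> cophenetic distances."""
    n = d.shape[0]
    clusters = [{i} for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = (None, None, math.inf)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
            if dist < best[2]:
                best = (a, b, dist)
        a, b, h = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] |= clusters[b]
        del clusters[b]
    return coph


# ---------------------------------------------------------------------------

class TestTrueRdm:
    def test_identical_and_opposite_patterns(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        x = np.vstack([base, base, -base])
        r = rsa.true_rdm(x, ["a", "b", "c"])
        assert r.values[0, 1] == pytest.approx(0.0)
        assert r.values[0, 2] == pytest.approx(2.0)

    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 4))
        r = rsa.true_rdm(x, ["a", "b", "c"])
        for i, j in itertools.combinations(range(3), 2):
            expected = 1.0 - np.corrcoef(x[i], x[j])[0, 1]
            assert r.values[i, j] == pytest.approx(expected)

    def test_zero_variance_pattern_names_condition(self):
        x = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="flat"):
            rsa.true_rdm(x, ["flat", "ok"])

    def test_group_rdm_mean_and_order_checks(self):
        conds = ["a", "b"]
        r1 = rsa.RDM(np.array([[0, 0.2], [0.2, 0]]), conds)
        r2 = rsa.RDM(np.array([[0, 0.4], [0.4, 0]]), conds)
        g = rsa.group_rdm([r1, r2])
        assert g.values[0, 1] == pytest.approx(0.3)
        assert np.allclose(rsa.group_rdm([r2, r1]).values, g.values)
        r3 = rsa.RDM(np.array([[0, 0.4], [0.4, 0]]), ["b", "a"])
        with pytest.raises(ValueError):
            rsa.group_rdm([r1, r3])


@pytest.fixture(scope="module")
def models():
    return rsa.candidate_rdms(seed=0)


class TestCandidateModels:

    def test_all_models_present_and_normalized(self, models):
        assert set(models) == {
            "body_separate", "body_pattern1", "emotion_separate",
            "emotion_pattern1", "body_pattern2", "emotion_pattern2", "random",
        }
        for m in models.values():
            v = m.values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 0.0)
            assert v.max() == pytest.approx(1.0)
            assert v.min() >= 0.0

    def test_body_separate_block_structure(self, models):
        v = models["body_separate"].values
        conds = models["body_separate"].conditions
        for i, (_, p1) in enumerate(conds):
            for j, (_, p2) in enumerate(conds):
                if i != j:
                    assert v[i, j] == (0.0 if p1 == p2 else 1.0)

    def test_body_pattern1_merges_whole_body_and_torso(self, models):
        v = models["body_pattern1"].values
        conds = models["body_pattern1"].conditions
        i = conds.index(("anger", "whole_body"))
        j = conds.index(("fear", "torso_with_arms"))
        k = conds.index(("anger", "legs"))
        assert v[i, j] == 0.0 and v[i, k] == 1.0

    def test_body_pattern2_part_pair_tiers(self, models):
        """Off-diagonal part-pair values form the tier multiset {1,1,2,2,2,3}/3."""
        v = models["body_pattern2"].values
        conds = models["body_pattern2"].conditions
        part_vals = {}
        for i, (_, p1) in enumerate(conds):
            for j, (_, p2) in enumerate(conds):
                if p1 != p2:
                    part_vals.setdefault(frozenset({p1, p2}), set()).add(round(v[i, j], 6))
        assert all(len(s) == 1 for s in part_vals.values())
        multiset = sorted(next(iter(s)) for s in part_vals.values())
        assert np.allclose(multiset, np.array([1, 1, 2, 2, 2, 3]) / 3.0)

    def test_emotion_pattern2_orders_emotion_within_torso_block(self, models):
        v = models["emotion_pattern2"].values
        conds = models["emotion_pattern2"].conditions
        wb_a = conds.index(("anger", "whole_body"))
        wb_f = conds.index(("fear", "whole_body"))
        wb_n = conds.index(("neutral", "whole_body"))
        ta_a = conds.index(("anger", "torso_with_arms"))
        # same emotion across the merged parts < anger-fear < emotion-neutral
        assert v[wb_a, ta_a] < v[wb_a, wb_f] < v[wb_a, wb_n]
        # the shifted coarse tiers stay above every emotion rank
        lg_a = conds.index(("anger", "legs"))
        hd_a = conds.index(("anger", "head"))
        assert v[wb_a, lg_a] > v[wb_a, wb_n]
        assert v[wb_a, hd_a] == pytest.approx(1.0)

    def test_random_model_seeded(self):
        a = rsa.candidate_rdms(seed=3)["random"]
        b = rsa.candidate_rdms(seed=3)["random"]
        c = rsa.candidate_rdms(seed=4)["random"]
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_incomplete_design_rejected(self):
        with pytest.raises(ValueError):
            rsa.candidate_rdms(conditions=[("anger", "legs")] * 12)


class TestKendallTauA:
    def test_perfect_and_reversed_orderings(self):
        x = np.arange(10.0)
        assert rsa.kendall_tau_a(x, x) == pytest.approx(1.0)
        assert rsa.kendall_tau_a(x, -x) == pytest.approx(-1.0)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=10)
            y = rng.choice([0.0, 1.0, 2.0], size=10)  # ties on purpose
            assert rsa.kendall_tau_a(x, y) == pytest.approx(tau_a_bruteforce(x, y))

    def test_ties_shrink_tau_toward_zero(self):
        x = np.arange(6.0)
        y_tied = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        assert rsa.kendall_tau_a(x, y_tied) < 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        t1 = rsa.kendall_tau_a(x, y)
        assert rsa.kendall_tau_a(np.exp(x), y) == pytest.approx(t1)
        assert rsa.kendall_tau_a(x, y**3) == pytest.approx(t1)


class TestSignedRankInference:
    def test_all_zero_taus_degenerate(self):
        assert rsa.relatedness_test(np.zeros(8)) == 1.0
        assert rsa.pairwise_model_test(np.ones(8), np.ones(8)) == 1.0

    def test_twelve_positive_subjects_minimum_p(self):
        taus = np.abs(np.random.default_rng(0).normal(size=12)) + 0.01
        assert rsa.relatedness_test(taus) == pytest.approx(2.0**-12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        for n in (6, 9, 12):
            v = rng.normal(0.3, 1.0, size=n)
            v[v == 0] = 0.1
            assert rsa.relatedness_test(v) == pytest.approx(
                signed_rank_exact(v, "greater")
            )
            b = rng.normal(size=n)
            d = v - b
            if np.all(d != 0):
                assert rsa.pairwise_model_test(v, b) == pytest.approx(
                    signed_rank_exact(d, "two-sided")
                )

    def test_all_positive_differences_n10(self):
        a = np.linspace(1.0, 2.0, 10)
        b = a - 0.3
        assert rsa.pairwise_model_test(a, b) == pytest.approx(2.0 * 2.0**-10)

    def test_pairwise_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert rsa.pairwise_model_test(a, b) == rsa.pairwise_model_test(b, a)

    def test_negation_symmetry_of_exact_null(self):
        v = np.abs(np.random.default_rng(5).normal(size=8)) + 0.01
        p_pos = rsa.relatedness_test(v)
        p_neg = rsa.relatedness_test(-v)
        # exact discrete null: the two one-sided p-values overlap by the
        # point mass at the observed statistic
        assert p_pos + p_neg > 1.0
        assert p_neg == pytest.approx(signed_rank_exact(-v, "greater"))


class TestFdr:
    def test_extremes(self):
        flags, _ = rsa.fdr_correct(np.ones(5), q=0.05)
        assert not flags.any()
        flags, _ = rsa.fdr_correct(np.full(5, 1e-4), q=0.05)
        assert flags.all()

    def test_matches_by_hand_stepup(self):
        p = np.array([0.01, 0.02, 0.04, 0.20])
        flags, _ = rsa.fdr_correct(p, q=0.05)
        assert np.array_equal(flags, bh_stepup(p, 0.05))
        assert np.array_equal(flags, [True, True, False, False])
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=12)
            flags, _ = rsa.fdr_correct(p, q=0.05)
            assert np.array_equal(flags, bh_stepup(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rsa.fdr_correct([0.5, 1.2])


class TestMds:
    def test_exact_recovery_of_planar_configuration(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        rdm = rsa.RDM(d, [f"c{i}" for i in range(8)])
        coords = rsa.mds_2d(rdm)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.sqrt(np.mean((d - d2) ** 2)) < 1e-8
        assert coords[0, 0] >= 0  # sign convention

    def test_duplicate_conditions_coincide(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        coords = rsa.mds_2d(rsa.RDM(d, list("abc")))
        assert np.allclose(coords[0], coords[1], atol=1e-6)

    def test_eigendecomposition_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        rdm = rsa.RDM(d, [f"c{i}" for i in range(6)])
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d * d) @ j
        w = np.sort(np.linalg.eigvalsh(b))[::-1]
        coords = rsa.mds_2d(rdm)
        assert np.sum(coords[:, 0] ** 2) == pytest.approx(w[0])
        assert np.sum(coords[:, 1] ** 2) == pytest.approx(w[1])


class TestDendrogram:
    def test_two_blocks_split_at_top(self):
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        link = rsa.dendrogram(rsa.RDM(d, list("abcdef")))
        assert link[-1, 2] == pytest.approx(0.9)  # final merge joins the blocks
        assert np.all(np.diff(link[:, 2]) >= -1e-12)  # monotone heights

    def test_matches_bruteforce_single_linkage(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = rng.uniform(0.1, 1.0, size=(8, 8))
            d = 0.5 * (d + d.T)
            np.fill_diagonal(d, 0.0)
            rdm = rsa.RDM(d, [f"c{i}" for i in range(8)])
            link = rsa.dendrogram(rdm)
            coph = cophenet(link)
            iu = np.triu_indices(8, k=1)
            oracle = single_linkage_cophenetic(d)[iu]
            assert np.allclose(coph, oracle)


class TestDice:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:3] = True
        assert rsa.dice_overlap(a, a).r_overlap == 1.0
        b = np.zeros((10, 10), dtype=bool)
        b[5:] = True
        assert rsa.dice_overlap(a, b).r_overlap == 0.0

    def test_counts_formula(self):
        a = np.zeros(60, dtype=bool)
        b = np.zeros(60, dtype=bool)
        a[:30] = True
        b[15:45] = True
        res = rsa.dice_overlap(a, b)
        assert (res.v1, res.v2, res.v_overlap) == (30, 30, 15)
        assert res.r_overlap == pytest.approx(0.5)

    def test_empty_maps_define_zero(self):
        z = np.zeros((4, 4), dtype=bool)
        assert rsa.dice_overlap(z, z).r_overlap == 0.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            rsa.dice_overlap(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestModelComparison:
    def test_pipeline_invariant_to_condition_reordering(self):
        from bodybubbles import synthetic as sy

        table = sy.simulate_patterns(
            sy.PatternSpec(generating_model="body_pattern2", n_subjects=6, seed=5)
        )
        rdms = rsa.rdms_from_table(table)
        comp = rsa.compare_models(rdms)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(12))
        reordered = {
            s: r.reorder([r.conditions[i] for i in perm]) for s, r in rdms.items()
        }
        comp2 = rsa.compare_models(reordered)
        assert np.allclose(comp.taus.to_numpy(), comp2.taus.to_numpy())
        assert np.allclose(comp.relatedness_p.to_numpy(), comp2.relatedness_p.to_numpy())

    def test_null_patterns_reject_at_nominal_rate(self):
        """Relatedness tests on pure-noise patterns reject ~5% of the time."""
        from bodybubbles import synthetic as sy

        rng = np.random.default_rng(10)
        model = rsa.candidate_rdms(seed=0)["body_separate"]
        vec = model.lower_triangle()
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            taus = [
                rsa.kendall_tau_a(rng.normal(size=66), vec) for _ in range(8)
            ]
            rejections += rsa.relatedness_test(taus) < 0.05
        rate = rejections / n_rep
        ci = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < max(ci, 0.03)

    def test_t_test_option(self):
        from bodybubbles import synthetic as sy

        table = sy.simulate_patterns(
            sy.PatternSpec(generating_model="body_separate", n_subjects=8, seed=6)
        )
        rdms = rsa.rdms_from_table(table)
        comp = rsa.compare_models(rdms, test="t")
        assert comp.relatedness_p["body_separate"] < 0.01
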