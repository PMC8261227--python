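import itertools

import numpy as np
import pytest

from hierkit import (
    WinLoseMatrix,
    davids_scores,
    devries_h_prime,
    direction_randomization_null,
    directional_consistency,
    hierarchy_shape,
    landau_h,
    steepness_slope,
    subsample_metric_curve,
    triangle_transitivity,
)
from hierkit.metrics import UndefinedMetricError, group_metrics

from conftest import flat_config, table_from


def naive_landau(W):
    """Independent V-vector tally + formula, straight from the definition."""
    n = W.shape[0]
    V = []
    for i in range(n):
        v = 0.0
        for j in range(n):
            if i == j:
                continue
            if W[i, j] > W[j, i]:
                v += 1.0
            elif W[i, j] == W[j, i]:
                v += 0.5
        V.append(v)
    return 12.0 / (n**3 - n) * sum((v - (n - 1) / 2) ** 2 for v in V)


class TestLandauH:
    def test_perfect_linear_order(self, linear_matrix):
        assert landau_h(linear_matrix) == pytest.approx(1.0)

    def test_cyclic_triad(self, cyclic_matrix):
        assert landau_h(cyclic_matrix) == pytest.approx(0.0)

    def test_matches_naive_oracle_on_mixed_matrix(self):
        rng = np.random.default_rng(3)
        W = rng.integers(0, 4, (5, 5))
        np.fill_diagonal(W, 0)
        m = WinLoseMatrix(list("ABCDE"), W)
        assert landau_h(m) == pytest.approx(naive_landau(W))

    def test_too_small(self):
        with pytest.raises(ValueError):
            landau_h(WinLoseMatrix(["A", "B"], np.array([[0, 1], [0, 0]])))

    def test_relabel_invariance(self):
        rng = np.random.default_rng(5)
        W = rng.integers(0, 5, (6, 6))
        np.fill_diagonal(W, 0)
        perm = rng.permutation(6)
        m1 = WinLoseMatrix(list("ABCDEF"), W)
        m2 = WinLoseMatrix([m1.ids[k] for k in perm], W[np.ix_(perm, perm)])
        assert landau_h(m1) == pytest.approx(landau_h(m2))
        assert devries_h_prime(m1).value == pytest.approx(devries_h_prime(m2).value)
        assert directional_consistency(m1) == pytest.approx(
            directional_consistency(m2)
        )


class TestHPrime:
    def test_all_decided_equals_h(self, linear_matrix):
        hp = devries_h_prime(linear_matrix)
        assert hp.value == pytest.approx(landau_h(linear_matrix))
        assert hp.se == 0.0

    def test_one_unknown_dyad_equals_enumeration(self):
        # A>B, A>C, A>D, B>C, B>D decided; C-D never interacted
        W = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]:
            W[i, j] = 2
        m = WinLoseMatrix(list("ABCD"), W)
        # oracle: enumerate both directions of the unknown dyad by hand
        vals = []
        for direction in ((2, 3), (3, 2)):
            W2 = W.copy()
            W2[direction] = 1
            vals.append(naive_landau(W2))
        expected = np.mean(vals)
        assert devries_h_prime(m).value == pytest.approx(expected)
        mc = devries_h_prime(m, n_assign=64, seed=0)
        assert mc.method == "enumerate"
        assert mc.value == pytest.approx(expected)

    def test_exact_matches_full_enumeration_many_unknowns(self):
        rng = np.random.default_rng(9)
        W = rng.integers(0, 3, (5, 5))
        np.fill_diagonal(W, 0)
        m = WinLoseMatrix(list("ABCDE"), W)
        n_unknown = int(np.sum(np.triu(W == W.T, k=1)))
        exact = devries_h_prime(m).value
        enum = devries_h_prime(m, n_assign=2**n_unknown, seed=0)
        assert enum.method == "enumerate"
        assert exact == pytest.approx(enum.value)

    def test_mc_close_to_exact(self):
        rng = np.random.default_rng(10)
        W = rng.integers(0, 2, (8, 8))
        np.fill_diagonal(W, 0)
        m = WinLoseMatrix(list("ABCDEFGH"), W)
        exact = devries_h_prime(m).value
        mc = devries_h_prime(m, n_assign=4000, seed=1)
        assert mc.method == "mc"
        assert abs(mc.value - exact) < 4 * mc.se + 1e-12


class TestTriangleTransitivity:
    def test_transitive_triad(self):
        W = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]])
        p_t, t_tri = triangle_transitivity(WinLoseMatrix(list("ABC"), W))
        assert (p_t, t_tri) == (1.0, 1.0)

    def test_cyclic_triad(self, cyclic_matrix):
        p_t, t_tri = triangle_transitivity(cyclic_matrix)
        assert (p_t, t_tri) == (0.0, -3.0)

    def test_no_directed_triad_raises(self):
        W = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 0]])
        with pytest.raises(UndefinedMetricError):
            triangle_transitivity(WinLoseMatrix(list("ABC"), W))

    def test_matches_brute_force_triad_census(self):
        rng = np.random.default_rng(17)
        W = rng.integers(0, 3, (7, 7))
        np.fill_diagonal(W, 0)
        D = (W > W.T).astype(int)
        trans = cyc = 0
        for i, j, k in itertools.combinations(range(7), 3):
            sub = [(i, j), (j, k), (i, k)]
            if all(D[a, b] or D[b, a] for a, b in sub):
                # cyclic iff every node has out-degree 1 within the triad
                out = [
                    D[i, j] + D[i, k],
                    D[j, i] + D[j, k],
                    D[k, i] + D[k, j],
                ]
                if sorted(out) == [1, 1, 1]:
                    cyc += 1
                else:
                    trans += 1
        p_t, t_tri = triangle_transitivity(WinLoseMatrix(list("ABCDEFG"), W))
        assert p_t == pytest.approx(trans / (trans + cyc))
        assert t_tri == pytest.approx(4 * (p_t - 0.75))


class TestDirectionalConsistency:
    def test_fully_one_directional(self, linear_matrix):
        assert directional_consistency(linear_matrix) == 1.0

    def test_three_versus_one(self):
        W = np.array([[0, 3], [1, 0]])
        assert directional_consistency(WinLoseMatrix(["A", "B"], W)) == 0.5

    def test_all_zero_raises(self):
        with pytest.raises(UndefinedMetricError):
            directional_consistency(WinLoseMatrix(["A", "B"], np.zeros((2, 2))))

    def test_per_dyad_mean_variant(self):
        W = np.array([[0, 3, 9], [1, 0, 0], [1, 0, 0]])
        m = WinLoseMatrix(list("ABC"), W)
        pooled = directional_consistency(m)
        per_dyad = directional_consistency(m, pooled=False)
        assert pooled == pytest.approx((2 + 8) / (4 + 10))
        assert per_dyad == pytest.approx((0.5 + 0.8) / 2)


class TestDirectionNull:
    def test_direction_invariant_metric_gives_p_one(self, linear_matrix):
        res = direction_randomization_null(
            linear_matrix, lambda m: float(m.W.sum()), n_perm=100, seed=0
        )
        assert res.p == 1.0
        assert res.null_lo95 == res.null_hi95 == res.observed

    def test_one_directional_data_min_p(self):
        rows = [("A", "B")] * 7 + [("B", "C")] * 7 + [("A", "C")] * 6
        from hierkit import build_win_lose_matrix

        m = build_win_lose_matrix(table_from(rows))
        res = direction_randomization_null(
            m, directional_consistency, n_perm=200, seed=0
        )
        assert res.observed == 1.0
        assert res.p == pytest.approx(1 / 201)

    def test_low_n_perm_warns(self, linear_matrix):
        with pytest.warns(UserWarning):
            direction_randomization_null(
                linear_matrix, landau_h, n_perm=50, seed=0
            )

    def test_group_metrics_p_never_zero(self, linear_matrix):
        res = group_metrics(linear_matrix, n_perm=200, seed=0)
        for r in res.values():
            assert 0 < r.p <= 1


def naive_davids(W):
    """Hand arithmetic through P, w, w2, l, l2 (independent of the module)."""
    n = W.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            tot = W[i, j] + W[j, i]
            if i != j and tot > 0:
                P[i, j] = W[i, j] / tot
    w = P.sum(axis=1)
    w2 = np.array([sum(P[i, j] * w[j] for j in range(n)) for i in range(n)])
    l = P.T.sum(axis=1)
    l2 = np.array([sum(P[j, i] * l[j] for j in range(n)) for i in range(n)])
    return w + w2 - l - l2


class TestDavidsScores:
    def test_even_split_all_zero(self):
        n = 4
        W = np.ones((n, n), dtype=int)
        np.fill_diagonal(W, 0)
        res = davids_scores(WinLoseMatrix(list("ABCD"), W))
        assert res.DS == pytest.approx(np.zeros(n))
        assert res.norm_DS == pytest.approx(np.full(n, (n - 1) / 2))

    def test_worked_matrix_matches_hand_computation(self):
        W = np.array(
            [[0, 5, 2, 1], [1, 0, 4, 0], [2, 2, 0, 3], [0, 1, 1, 0]]
        )
        m = WinLoseMatrix(list("ABCD"), W)
        res = davids_scores(m)
        assert res.DS == pytest.approx(naive_davids(W))
        assert res.DS.sum() == pytest.approx(0.0, abs=1e-10)
        assert np.all(res.norm_DS >= 0) and np.all(res.norm_DS <= 3)

    def test_ds_sums_to_zero_random(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = rng.integers(4, 9)
            W = rng.integers(0, 6, (n, n))
            np.fill_diagonal(W, 0)
            # ensure no isolated individual
            for i in range(n):
                if W[i].sum() + W[:, i].sum() == 0:
                    W[i, (i + 1) % n] = 1
            res = davids_scores(WinLoseMatrix([str(k) for k in range(n)], W))
            assert res.DS.sum() == pytest.approx(0.0, abs=1e-9)

    def test_isolated_individual_named(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 1] = 2
        with pytest.raises(ValueError, match="C"):
            davids_scores(WinLoseMatrix(list("ABC"), W))

    def test_dyadic_correction_shrinks_toward_half(self):
        W = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]])
        m = WinLoseMatrix(list("ABC"), W)
        raw = davids_scores(m, correction="raw")
        cor = davids_scores(m, correction="dyadic")
        nonzero = raw.DS != 0
        assert np.all(np.abs(cor.DS[nonzero]) < np.abs(raw.DS[nonzero]))
        assert np.all(cor.DS[~nonzero] == 0)


class TestSteepness:
    def test_despotic_limit_near_one(self):
        n = 6
        W = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                W[i, j] = 50
        s = steepness_slope(WinLoseMatrix([str(k) for k in range(n)], W))
        assert s == pytest.approx(1.0, abs=0.01)

    def test_even_split_zero(self):
        W = np.ones((5, 5), dtype=int) * 3
        np.fill_diagonal(W, 0)
        assert steepness_slope(WinLoseMatrix(list("ABCDE"), W)) == pytest.approx(0.0)


class TestHierarchyShape:
    def test_higher_always_wins(self):
        rows = [("A", "B"), ("A", "C"), ("B", "C"), ("A", "B")]
        table = table_from(rows)
        curve = hierarchy_shape(table, {"A": 3, "B": 2, "C": 1})
        assert (curve.table["prop_higher_won"] == 1.0).all()
        assert curve.table["n"].sum() == 4
        assert curve.n_tied == 0

    def test_unranked_participant_errors(self):
        table = table_from([("A", "B")])
        with pytest.raises(KeyError):
            hierarchy_shape(table, {"A": 1})

    def test_coin_flip_bins_cover_half(self):
        from hierkit import generate_colony, generate_events

        cfg = flat_config(n=10, n_events=1000, beta=0.0)
        roster, truth = generate_colony(cfg, seed=2)
        table = generate_events(roster, truth, cfg, seed=3)
        curve = hierarchy_shape(table, truth.scores, bin_width=0.25)
        covered = (
            (curve.table["ci_lo"] <= 0.5) & (0.5 <= curve.table["ci_hi"])
        ).mean()
        assert covered >= 0.75  # 95% CIs on 4 bins; all should usually cover


class TestSubsampleCurve:
    def test_event_count_metric_is_identity(self, default_dataset):
        table = default_dataset.events
        curve = subsample_metric_curve(
            table, lambda m: float(m.W.sum()), step=100, n_orders=1, seed=0
        )
        assert curve.values[0] == pytest.approx(curve.sizes.astype(float))

    def test_step_too_large(self, toy_table):
        with pytest.raises(ValueError):
            subsample_metric_curve(toy_table, landau_h, step=10)

    def test_h_prime_increases_with_size_under_strong_hierarchy(self):
        from hierkit import generate_colony, generate_events

        cfg = flat_config(n=12, n_events=800, beta=8.0, score_spacing=1.0)
        roster, truth = generate_colony(cfg, seed=4)
        table = generate_events(roster, truth, cfg, seed=5)
        curve = subsample_metric_curve(
            table, lambda m: devries_h_prime(m).value, step=80, n_orders=3, seed=6
        )
        assert curve.slope > 0
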