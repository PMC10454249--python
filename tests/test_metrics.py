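import itertools
import math

import numpy as np
import pytest

from covnet import (
    all_measures,
    assortativity,
    characteristic_path_length,
    distances,
    global_efficiency,
    local_efficiency,
    mean_clustering,
    strength_degree,
)

from conftest import random_weight_matrix

# ---------------------------------------------------------------------------
# brute-force oracles (exhaustive enumeration; independent of the package
# implementation, usable for N <= ~8)
# ---------------------------------------------------------------------------


def oracle_distances(w, length=lambda x: 1.0 / x):
    """Shortest path by exhaustive enumeration of simple paths."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src in range(n):
        for dst in range(n):
            if src == dst:
                continue
            best = np.inf
            inner = [v for v in range(n) if v not in (src, dst)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    path = (src,) + mid + (dst,)
                    total = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        total += length(w[a, b])
                    if ok:
                        best = min(best, total)
            d[src, dst] = best
    return d


def oracle_global_efficiency(w):
    d = oracle_distances(w)
    n = w.shape[0]
    total = sum(
        0.0 if math.isinf(d[i, j]) else 1.0 / d[i, j]
        for i in range(n) for j in range(n) if i != j
    )
    return total / (n * (n - 1))


def oracle_local_efficiency(w):
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        total += oracle_global_efficiency(sub)
    return total / n


def oracle_mean_clustering(w):
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    wh = w / wmax
    cs = []
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            cs.append(0.0)
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        cs.append(s / (k * (k - 1)))
    return float(np.mean(cs))


def oracle_cpl(w):
    d = oracle_distances(w)
    n = w.shape[0]
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    return float(np.mean(finite)) if finite else float("inf")


def oracle_assortativity(w):
    n = w.shape[0]
    deg = [(w[i] > 0).sum() for i in range(n)]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                pairs.append((deg[i], deg[j]))
                pairs.append((deg[j], deg[i]))
    if len(pairs) < 4:
        return float("nan")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------


def complete_graph(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


def star_graph(n_leaves=3):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return w


class TestDistances:
    def test_triangle_half_weights(self):
        d = distances(complete_graph(3, 0.5))
        off = d[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)

    def test_two_hop_beats_direct(self):
        w = np.array([[0, 0.9, 0.1], [0.9, 0, 0.9], [0.1, 0.9, 0]])
        d = distances(w)
        assert d[0, 2] == pytest.approx(1 / 0.9 + 1 / 0.9)

    def test_disconnected_pairs_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d = distances(w)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        assert d[0, 1] == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            w = random_weight_matrix(rng, 6, density=0.5)
            np.testing.assert_allclose(
                distances(w), oracle_distances(w), atol=1e-10
            )

    @pytest.mark.parametrize("convention,length", [
        ("one-minus", lambda x: 1.0 - x),
        ("neg-log", lambda x: -math.log(x)),
    ])
    def test_alternative_conventions(self, rng, convention, length):
        w = random_weight_matrix(rng, 5, density=0.6) * 0.9 + 0.0
        np.testing.assert_allclose(
            distances(w, distance=convention),
            oracle_distances(w, length=length),
            atol=1e-10,
        )

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            distances(complete_graph(3), distance="taxicab")


class TestGlobalEfficiency:
    def test_complete_k4(self):
        assert global_efficiency(complete_graph(4)) == pytest.approx(1.0)

    def test_three_node_hand_value(self):
        w = np.array([[0, 0.9, 0.1], [0.9, 0, 0.9], [0.1, 0.9, 0]])
        assert global_efficiency(w) == pytest.approx(0.75)

    def test_edgeless_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0


class TestLocalEfficiency:
    def test_complete_k3(self):
        assert local_efficiency(complete_graph(3)) == pytest.approx(1.0)

    def test_star_zero(self):
        assert local_efficiency(star_graph(3)) == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            w = random_weight_matrix(rng, 8, density=0.5)
            assert local_efficiency(w) == pytest.approx(
                oracle_local_efficiency(w), abs=1e-10
            )


class TestMeanClustering:
    def test_complete_k4(self):
        assert mean_clustering(complete_graph(4)) == pytest.approx(1.0)

    def test_triangle_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.2
        # normalized weights 1, 0.625, 0.25; C = (1 * 0.625 * 0.25)^(1/3)
        expected = (1.0 * 0.625 * 0.25) ** (1.0 / 3.0)
        assert mean_clustering(w) == pytest.approx(expected, abs=1e-9)

    def test_path_graph_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert mean_clustering(w) == 0.0

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert mean_clustering(np.zeros((4, 4))) == 0.0


class TestCharacteristicPathLength:
    def test_complete_k4(self):
        assert characteristic_path_length(complete_graph(4)) == pytest.approx(1.0)

    def test_three_node_hand_value(self):
        w = np.array([[0, 0.9, 0.1], [0.9, 0, 0.9], [0.1, 0.9, 0]])
        expected = (1 / 0.9 + (1 / 0.9 + 1 / 0.9) + 1 / 0.9) / 3.0
        assert characteristic_path_length(w) == pytest.approx(expected)

    def test_unit_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert characteristic_path_length(w) == pytest.approx(4.0 / 3.0)

    def test_all_disconnected_is_inf(self):
        assert math.isinf(characteristic_path_length(np.zeros((3, 3))))

    def test_partial_disconnection_excludes_pairs(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        assert characteristic_path_length(w) == pytest.approx(1.0)


class TestStrengthDegree:
    def test_complete_k4(self):
        assert strength_degree(complete_graph(4)) == (3.0, 3.0)

    def test_triangle_hand_values(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.2
        s, k = strength_degree(w)
        assert s == pytest.approx(1.0)
        assert k == pytest.approx(2.0)

    def test_edgeless(self):
        assert strength_degree(np.zeros((5, 5))) == (0.0, 0.0)


class TestAssortativity:
    def test_star_perfectly_disassortative(self):
        assert assortativity(star_graph(3)) == pytest.approx(-1.0)

    def test_unit_path_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert assortativity(w) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert math.isnan(assortativity(complete_graph(4)))

    def test_single_edge_undefined(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.7
        assert math.isnan(assortativity(w))

    def test_matches_bruteforce(self, rng):
        checked = 0
        for _ in range(50):
            w = random_weight_matrix(rng, 6, density=0.4)
            ours, theirs = assortativity(w), oracle_assortativity(w)
            if math.isnan(theirs):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(theirs, abs=1e-10)
                checked += 1
        assert checked >= 20


class TestAllMeasures:
    def test_complete_k4_bundle(self):
        m = all_measures(complete_graph(4))
        assert m.global_efficiency == pytest.approx(1.0)
        assert m.local_efficiency == pytest.approx(1.0)
        assert m.mean_clustering_coefficient == pytest.approx(1.0)
        assert m.characteristic_path_length == pytest.approx(1.0)
        assert m.average_strength == pytest.approx(3.0)
        assert m.average_degree == pytest.approx(3.0)
        assert math.isnan(m.assortative_coefficient)

    def test_scaling_laws(self, rng):
        w = random_weight_matrix(rng, 9, density=0.6)
        base = all_measures(w)
        for c in (0.25, 0.5, 0.9):
            scaled = all_measures(c * w)
            assert scaled.average_strength == pytest.approx(
                c * base.average_strength, rel=1e-9
            )
            assert scaled.characteristic_path_length == pytest.approx(
                base.characteristic_path_length / c, rel=1e-9
            )
            assert scaled.global_efficiency == pytest.approx(
                c * base.global_efficiency, rel=1e-9
            )
            assert scaled.mean_clustering_coefficient == pytest.approx(
                base.mean_clustering_coefficient, rel=1e-9
            )

    def test_to_record_renders_na(self):
        rec = all_measures(complete_graph(4)).to_record()
        assert rec["assortative_coefficient"] == "NA"
        assert rec["global_efficiency"] == "1"

    def test_permutation_invariance(self, rng):
        w = random_weight_matrix(rng, 7, density=0.6)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        a, b = all_measures(w), all_measures(wp)
        for name in (
            "global_efficiency", "local_efficiency", "mean_clustering_coefficient",
            "characteristic_path_length", "average_strength", "average_degree",
        ):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)
        if math.isnan(a.assortative_coefficient):
            assert math.isnan(b.assortative_coefficient)
        else:
            assert a.assortative_coefficient == pytest.approx(
                b.assortative_coefficient, rel=1e-9
            )

    def test_monotonicity_edge_addition(self, rng):
        for _ in range(10):
            w = random_weight_matrix(rng, 6, density=0.4)
            zeros = np.argwhere(np.triu(w == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
            assert global_efficiency(w2) >= global_efficiency(w) - 1e-12
            a, b = characteristic_path_length(w), characteristic_path_length(w2)
            # CPL over reachable pairs can only compare when connectivity is equal
            if np.isfinite(a) and np.array_equal(
                np.isfinite(distances(w)), np.isfinite(distances(w2))
            ):
                assert b <= a + 1e-12
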