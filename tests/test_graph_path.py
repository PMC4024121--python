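import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graphpac import (
    GraphPACError,
    INSERTION_METHODS,
    PathOrder,
    brute_force_optimal_tour,
    brute_force_shortest_path,
    distance_matrix,
    hamiltonian_path,
    insertion_tour,
    kendall_tau_distance,
    path_separation,
)
from graphpac.graph_path import tour_length

COLINEAR = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]], dtype=float)


def _random_points(rng, n):
    return rng.uniform(0, 50, size=(n, 3))


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        D = distance_matrix(np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], float))
        assert D[0, 2] == pytest.approx(5.0)
        assert D[0, 0] == 0.0

    def test_translation_invariance(self, rng):
        pts = _random_points(rng, 8)
        np.testing.assert_allclose(
            distance_matrix(pts), distance_matrix(pts + [7.0, -3.0, 11.0]), atol=1e-9
        )

    def test_duplicate_points_warn(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float)
        with pytest.warns(UserWarning, match="duplicate"):
            distance_matrix(pts)


class TestInsertionTour:
    @pytest.mark.parametrize("method", INSERTION_METHODS)
    def test_triangle_tour_is_perimeter(self, method):
        D = distance_matrix(np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], float))
        tour = insertion_tour(D, method)
        assert tour.length == pytest.approx(12.0)

    @pytest.mark.parametrize("method", INSERTION_METHODS)
    def test_colinear_tour_is_twice_the_span(self, method):
        tour = insertion_tour(distance_matrix(COLINEAR), method)
        assert tour.length == pytest.approx(20.0)

    @pytest.mark.parametrize("method", INSERTION_METHODS)
    def test_tour_valid_and_length_consistent(self, rng, method):
        for n in (4, 7, 12, 30):
            D = distance_matrix(_random_points(rng, n))
            tour = insertion_tour(D, method)
            assert sorted(tour.order) == list(range(n))
            assert tour.length == pytest.approx(tour_length(D, tour.order), rel=1e-9)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(GraphPACError, match="symmetric"):
            insertion_tour(D, "cheapest")

    def test_deterministic(self, rng):
        D = distance_matrix(_random_points(rng, 15))
        a = insertion_tour(D, "cheapest")
        b = insertion_tour(D, "cheapest")
        np.testing.assert_array_equal(a.order, b.order)


class TestHamiltonianPath:
    @pytest.mark.parametrize("method", INSERTION_METHODS)
    def test_colinear_path_is_sorted_order(self, method):
        path = hamiltonian_path(distance_matrix(COLINEAR), method)
        np.testing.assert_array_equal(path.order, [0, 1, 2, 3])
        assert path.length(distance_matrix(COLINEAR)) == pytest.approx(10.0)

    def test_two_vertices(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(hamiltonian_path(D, "cheapest").order, [0, 1])

    @pytest.mark.parametrize("method", ["cheapest", "farthest"])
    def test_reversing_input_preserves_geometric_path(self, rng, method):
        # nearest is excluded: the dummy vertex degenerates its selection
        # rule to the index tie-break, so relabelling can change its path
        pts = _random_points(rng, 9)
        D = distance_matrix(pts)
        Dr = distance_matrix(pts[::-1])
        n = len(pts)
        edges = lambda order: {frozenset((a, b)) for a, b in zip(order[:-1], order[1:])}
        fwd = edges(hamiltonian_path(D, method).order)
        rev = edges((n - 1) - hamiltonian_path(Dr, method).order)
        assert fwd == rev

    @pytest.mark.parametrize("method", INSERTION_METHODS)
    def test_path_never_beats_brute_force(self, rng, method):
        for n in (4, 6, 8):
            D = distance_matrix(_random_points(rng, n))
            exact = brute_force_shortest_path(D).length(D)
            assert hamiltonian_path(D, method).length(D) >= exact - 1e-9


class TestBruteForce:
    def test_colinear_sorted(self):
        path = brute_force_shortest_path(distance_matrix(COLINEAR))
        np.testing.assert_array_equal(path.order, [0, 1, 2, 3])

    def test_triangle_drops_longest_edge(self):
        D = distance_matrix(np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], float))
        path = brute_force_shortest_path(D)
        assert path.length(D) == pytest.approx(7.0)

    def test_refuses_large_instances(self):
        with pytest.raises(GraphPACError, match="N <= 10"):
            brute_force_shortest_path(np.zeros((11, 11)))

    def test_optimal_tour_never_beaten(self, rng):
        for n in (5, 7):
            D = distance_matrix(_random_points(rng, n))
            opt = brute_force_optimal_tour(D).length
            for method in INSERTION_METHODS:
                assert insertion_tour(D, method).length >= opt - 1e-9


class TestPathDiagnostics:
    def test_kendall_tau_identity_and_reversal(self):
        assert kendall_tau_distance(PathOrder(np.arange(6), "x")) == 0
        assert kendall_tau_distance(PathOrder(np.array([2, 1, 0]), "x")) == 3
        assert kendall_tau_distance(PathOrder(np.array([1, 0, 2]), "x")) == 1

    @given(st.permutations(list(range(8))))
    def test_kendall_tau_bounds(self, perm):
        kt = kendall_tau_distance(PathOrder(np.array(perm), "x"))
        assert 0 <= kt <= 8 * 7 // 2

    def test_path_separation(self):
        path = PathOrder(np.arange(10), "x")
        assert path_separation(path, 3, 4) == 1
        assert path_separation(path, 3, 3) == 0
        assert path_separation(path, 0, 9) == 9
        with pytest.raises(GraphPACError):
            path_separation(path, 0, 10)
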