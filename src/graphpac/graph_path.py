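"""Linearize a protein by a shortest-Hamiltonian-path heuristic.

Each residue is a vertex of a complete Euclidean graph whose edge
lengths are C-alpha pairwise distances.  A travelling-salesman insertion
heuristic (cheapest, nearest or farthest insertion) builds a short tour;
a zero-distance dummy vertex converts the tour into a Hamiltonian path,
the standard shortest-path reduction.  The resulting vertex order is the
one-dimensional coordinate system on which the clustering test runs:
residues far apart in sequence but close in space end up with nearby
path ranks, unlike in the raw sequence order.

For points obeying the triangle inequality the cheapest- and
nearest-insertion tours are at most twice the optimal tour length; the
brute-force enumerators below serve as exact oracles on small instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import GraphPACError

INSERTION_METHODS = ("cheapest", "nearest", "farthest")


@dataclass
class Tour:
    """A cyclic visiting order (0-based vertex indices) and its length."""

    order: np.ndarray
    length: float

    @property
    def n(self) -> int:
        return len(self.order)


@dataclass
class PathOrder:
    """Vertices in path order: ``order[p]`` is the vertex at rank p.

    ``positions()`` gives the inverse permutation as 1-based path ranks,
    the coordinate used by the order-statistic test.
    """

    order: np.ndarray
    method: str

    @property
    def n(self) -> int:
        return len(self.order)

    def positions(self) -> np.ndarray:
        pos = np.empty(self.n, dtype=int)
        pos[self.order] = np.arange(1, self.n + 1)
        return pos

    def length(self, D: np.ndarray) -> float:
        return float(D[self.order[:-1], self.order[1:]].sum())


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (Angstrom) between residue coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise GraphPACError("expected an (N, 3) array with N >= 2 coordinates")
    D = squareform(pdist(coords))
    n = len(D)
    if np.any(D[np.triu_indices(n, 1)] == 0.0):
        warnings.warn(
            "duplicate coordinates: off-diagonal zero distance present",
            stacklevel=2,
        )
    return D


def _validate_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise GraphPACError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise GraphPACError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise GraphPACError("distance matrix must be nonnegative")
    return D


def tour_length(D: np.ndarray, order: np.ndarray) -> float:
    order = np.asarray(order)
    return float(D[order, np.roll(order, -1)].sum())


def insertion_tour(D: np.ndarray, method: str) -> Tour:
    """Build a tour by the named insertion rule.

    cheapest: insert the (vertex, edge) pair with the minimal increase in
    tour length.  nearest: insert the unvisited vertex closest to the
    tour, at its minimal-increase position.  farthest: insert the
    unvisited vertex whose distance to the tour is maximal, at its
    minimal-increase position.

    Deterministic tie rules: the lowest vertex index wins, and among
    insertion positions the earliest along the tour wins.  cheapest and
    nearest start from the globally shortest edge, farthest from the
    globally longest one.
    """
    if method not in INSERTION_METHODS:
        raise GraphPACError(f"unknown insertion method {method!r}")
    D = _validate_matrix(D)
    N = len(D)
    if N == 1:
        return Tour(order=np.array([0]), length=0.0)
    if N == 2:
        return Tour(order=np.array([0, 1]), length=2.0 * D[0, 1])

    iu, ju = np.triu_indices(N, 1)
    flat = D[iu, ju]
    e = int(np.argmin(flat)) if method in ("cheapest", "nearest") else int(np.argmax(flat))
    tour: list[int] = [int(iu[e]), int(ju[e])]
    unvisited = np.array(sorted(set(range(N)) - set(tour)), dtype=int)
    # distance from each unvisited vertex to the current tour
    min_dist = np.minimum(D[unvisited, tour[0]], D[unvisited, tour[1]])

    while unvisited.size:
        tarr = np.asarray(tour)
        u, v = tarr, np.roll(tarr, -1)
        edge_len = D[u, v]
        if method == "cheapest":
            # increase[i, e] = cost of inserting unvisited[i] on edge e
            increase = D[np.ix_(unvisited, u)] + D[np.ix_(unvisited, v)] - edge_len
            ki, pos = np.unravel_index(np.argmin(increase), increase.shape)
        else:
            ki = int(np.argmin(min_dist)) if method == "nearest" else int(np.argmax(min_dist))
            inc_k = D[unvisited[ki], u] + D[unvisited[ki], v] - edge_len
            pos = int(np.argmin(inc_k))
        k = int(unvisited[ki])
        tour.insert(pos + 1, k)
        keep = np.ones(unvisited.size, dtype=bool)
        keep[ki] = False
        unvisited = unvisited[keep]
        min_dist = np.minimum(min_dist[keep], D[unvisited, k])

    order = np.asarray(tour)
    return Tour(order=order, length=tour_length(D, order))


def hamiltonian_path(D: np.ndarray, method: str) -> PathOrder:
    """Approximate shortest Hamiltonian path via the dummy-vertex reduction.

    A dummy vertex at distance 0 to every residue is appended, a tour is
    built on the augmented problem, and cutting the tour at the dummy
    yields the path (the dummy's two incident edges contribute nothing,
    so the path length equals the augmented tour length).  Orientation is
    canonical: the endpoint with the smaller vertex index comes first.
    """
    D = _validate_matrix(D)
    N = len(D)
    if N < 2:
        raise GraphPACError("need at least 2 vertices for a path")
    aug = np.zeros((N + 1, N + 1))
    aug[:N, :N] = D
    tour = insertion_tour(aug, method)
    order = list(tour.order)
    cut = order.index(N)
    path = order[cut + 1:] + order[:cut]
    if path[0] > path[-1]:
        path.reverse()
    return PathOrder(order=np.asarray(path), method=method)


def brute_force_shortest_path(D: np.ndarray) -> PathOrder:
    """Exact minimum-length Hamiltonian path by exhaustive enumeration.

    Refuses N > 10 (N!/2 orientations-deduplicated sequences).  Serves as
    the independent oracle for the heuristics on small instances.
    """
    D = _validate_matrix(D)
    N = len(D)
    if N > 10:
        raise GraphPACError("brute force limited to N <= 10")
    if N < 2:
        raise GraphPACError("need at least 2 vertices for a path")
    best_len = np.inf
    best: np.ndarray | None = None
    # enumerate by chunk to bound memory at large N
    for first in range(N):
        rest = [v for v in range(N) if v != first]
        perms = np.array(list(itertools.permutations(rest)), dtype=int)
        full = np.hstack([np.full((len(perms), 1), first, dtype=int), perms])
        keep = full[:, 0] < full[:, -1]  # one orientation per path
        full = full[keep]
        if not len(full):
            continue
        lengths = D[full[:, :-1], full[:, 1:]].sum(axis=1)
        i = int(np.argmin(lengths))
        if lengths[i] < best_len - 1e-12:
            best_len = float(lengths[i])
            best = full[i]
    assert best is not None
    return PathOrder(order=best, method="exact")


def brute_force_optimal_tour(D: np.ndarray) -> Tour:
    """Exact minimum-length tour by enumerating (N-1)!/2 cyclic orders."""
    D = _validate_matrix(D)
    N = len(D)
    if N > 10:
        raise GraphPACError("brute force limited to N <= 10")
    if N < 3:
        return insertion_tour(D, "cheapest")
    rest = np.array(list(itertools.permutations(range(1, N))), dtype=int)
    rest = rest[rest[:, 0] < rest[:, -1]]  # fix orientation
    full = np.hstack([np.zeros((len(rest), 1), dtype=int), rest])
    lengths = D[full, np.roll(full, -1, axis=1)].sum(axis=1)
    i = int(np.argmin(lengths))
    return Tour(order=full[i], length=float(lengths[i]))


def kendall_tau_distance(path: PathOrder) -> int:
    """Discordant pairs between the path order and the identity order.

    Equivalently the number of adjacent swaps bubble sort needs to restore
    sequence order; 0 for an untouched protein, N(N-1)/2 for a full
    reversal.
    """
    o = np.asarray(path.order)
    gt = o[:, None] > o[None, :]
    return int(np.triu(gt, k=1).sum())


def path_separation(path: PathOrder, i: int, j: int) -> int:
    """Rank separation |position(i) - position(j)| along the path."""
    n = path.n
    if not (0 <= i < n and 0 <= j < n):
        raise GraphPACError(f"vertex index out of range for path of {n} vertices")
    pos = path.positions()
    return int(abs(pos[i] - pos[j]))
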