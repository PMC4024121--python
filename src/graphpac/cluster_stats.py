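"""Order-statistic clustering test in path coordinates.

After linearization, the n mutations of a protein occupy path ranks
1..N.  Under the null that mutation positions are uniform over the N
analyzed residues, the scaled gap between order statistics X(i) < X(k),

    c = (X(k) - X(i) + 1) / N,

is approximately Beta(k-i, i+n-k+1) distributed, so the left tail of
that Beta is the cluster p-value: a small gap containing many mutations
is evidence of non-random clustering.  All n(n-1)/2 ordered pairs are
tested and Bonferroni-adjusted within the structure.

The ``span_convention`` switch controls the +1 in c: "inclusive"
(default) counts residues in the closed span, so recurrent mutations at
a single residue (gap 0) still receive a finite, highly significant
p-value; "exclusive" is the literal limiting form, which degenerates to
p = 0 for gap 0.  A Monte-Carlo oracle draws from the discrete uniform
null for independent verification of the Beta approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import betainc

from .errors import GraphPACError, InsufficientMutationsError
from .graph_path import PathOrder
from .mutation_data import MutationCounts
from .reconciliation import ResidueMap

SPAN_CONVENTIONS = ("inclusive", "exclusive")


def _span_offset(span_convention: str) -> int:
    if span_convention not in SPAN_CONVENTIONS:
        raise GraphPACError(f"unknown span convention {span_convention!r}")
    return 1 if span_convention == "inclusive" else 0


@dataclass
class OrderStatistics:
    """Sorted path positions X(1) <= ... <= X(n) of all n mutations."""

    positions: np.ndarray  # with multiplicity, nondecreasing
    n: int
    N: int

    def __post_init__(self) -> None:
        assert len(self.positions) == self.n
        if self.n:
            assert 1 <= self.positions[0] and self.positions[-1] <= self.N


@dataclass
class RawCluster:
    """One tested pair of order statistics (i < k) and its p-values."""

    i: int
    k: int
    xi: int
    xk: int
    span_c: float
    p_raw: float
    p_bonf: float


@dataclass
class ClusterReport(RawCluster):
    """A cluster unmapped to original residue numbering."""

    start_residue: int = 0
    end_residue: int = 0
    members: list[int] = field(default_factory=list)
    p_star: float | None = None
    structure_id: str = ""
    method: str = ""


class OracleEstimate(NamedTuple):
    estimate: float
    se: float


def order_statistics(counts: MutationCounts, path: PathOrder) -> OrderStatistics:
    """Map per-residue counts into sorted path positions.

    ``counts`` must already be restricted/re-indexed to the path's
    residues (keys 1..N in structure order); each mutated residue
    contributes ``count`` copies of its path rank.
    """
    N = path.n
    if counts.n_total < 2:
        raise InsufficientMutationsError(
            f"need at least 2 mutations to form order statistics, got {counts.n_total}"
        )
    pos_of = path.positions()  # 1-based rank per 0-based vertex
    positions: list[int] = []
    for residue_idx, count in counts.counts.items():
        if not (1 <= residue_idx <= N):
            raise GraphPACError(
                f"mutation at residue index {residue_idx} outside path of {N} residues"
            )
        positions.extend([int(pos_of[residue_idx - 1])] * count)
    return OrderStatistics(
        positions=np.sort(np.asarray(positions)), n=counts.n_total, N=N
    )


def pair_cluster_pvalue(
    i: int,
    k: int,
    xi: int,
    xk: int,
    n: int,
    N: int,
    span_convention: str = "inclusive",
) -> float:
    """Beta tail probability of seeing a span this tight by chance.

    Returns Pr(Beta(k-i, i+n-k+1) <= c) with c the scaled span of the
    pair; nondecreasing in c and, at fixed c and n, decreasing in k-i.
    """
    offset = _span_offset(span_convention)
    if not (1 <= i < k <= n):
        raise GraphPACError(f"invalid order-statistic indices i={i}, k={k}, n={n}")
    if not (1 <= xi <= xk <= N):
        raise GraphPACError(f"invalid positions xi={xi}, xk={xk}, N={N}")
    c = min((xk - xi + offset) / N, 1.0)
    return float(betainc(k - i, i + n - k + 1, c))


def bonferroni_factor(n: int) -> int:
    """Number of pairwise tests, n(n-1)/2."""
    if n < 2:
        raise GraphPACError("Bonferroni factor requires n >= 2")
    return n * (n - 1) // 2


def all_pairs_scan(
    os_: OrderStatistics, span_convention: str = "inclusive"
) -> list[RawCluster]:
    """Test every ordered pair (i, k), i < k, of order statistics.

    Returns n(n-1)/2 clusters, each with the raw Beta p-value and its
    Bonferroni adjustment min(1, p * n(n-1)/2).  The multiset of p-values
    is invariant under path reversal (gap lengths are preserved).
    """
    n, N = os_.n, os_.N
    if n < 2:
        raise InsufficientMutationsError("all-pairs scan requires n >= 2")
    offset = _span_offset(span_convention)
    X = os_.positions
    ii, kk = np.triu_indices(n, 1)
    ii, kk = ii + 1, kk + 1  # 1-based order-statistic indices
    xi, xk = X[ii - 1], X[kk - 1]
    c = np.minimum((xk - xi + offset) / N, 1.0)
    p_raw = betainc(kk - ii, ii + n - kk + 1, c)
    m = bonferroni_factor(n)
    p_bonf = np.minimum(1.0, p_raw * m)
    return [
        RawCluster(
            i=int(ii[t]),
            k=int(kk[t]),
            xi=int(xi[t]),
            xk=int(xk[t]),
            span_c=float(c[t]),
            p_raw=float(p_raw[t]),
            p_bonf=float(p_bonf[t]),
        )
        for t in range(len(ii))
    ]


def mc_cluster_pvalue_oracle(
    i: int,
    k: int,
    c_obs: float,
    n: int,
    N: int,
    reps: int = 100_000,
    seed: int = 0,
    span_convention: str = "inclusive",
    with_replacement: bool = True,
) -> OracleEstimate:
    """Monte-Carlo estimate of the cluster p-value under the uniform null.

    Draws n positions i.i.d. uniform on {1..N} ``reps`` times (or without
    replacement for sensitivity checks), sorts them, and estimates
    Pr((X(k) - X(i) + offset)/N <= c_obs) with its binomial standard
    error.  Independent of the Beta closed form.
    """
    if reps < 1000:
        raise GraphPACError("use at least 1000 replicates")
    if not (1 <= i < k <= n):
        raise GraphPACError(f"invalid order-statistic indices i={i}, k={k}, n={n}")
    offset = _span_offset(span_convention)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 50_000
    done = 0
    while done < reps:
        size = min(chunk, reps - done)
        if with_replacement:
            draws = rng.integers(1, N + 1, size=(size, n))
        else:
            if n > N:
                raise GraphPACError("cannot draw n > N without replacement")
            keys = rng.random((size, N))
            draws = np.argpartition(keys, n - 1, axis=1)[:, :n] + 1
        draws.sort(axis=1)
        stat = (draws[:, k - 1] - draws[:, i - 1] + offset) / N
        hits += int(np.count_nonzero(stat <= c_obs + 1e-12))
        done += size
    est = hits / reps
    se = float(np.sqrt(est * (1.0 - est) / reps))
    return OracleEstimate(estimate=est, se=se)


def unmap_cluster(
    rc: RawCluster,
    path: PathOrder,
    residue_map: ResidueMap | None,
    order_stats: OrderStatistics,
    structure_id: str = "",
) -> ClusterReport:
    """Translate a path-space cluster back to original residue numbers.

    Endpoints are the canonical residue numbers of path ranks xi and xk
    (reported min..max in canonical numbering); members are the canonical
    residues of every mutated path rank inside [xi, xk].
    """

    def canon(rank: int) -> int:
        vertex = int(path.order[rank - 1])  # 0-based structure-order vertex
        if residue_map is None:
            return vertex + 1
        return residue_map.pairs[vertex][1]

    a, b = canon(rc.xi), canon(rc.xk)
    start, end = min(a, b), max(a, b)
    mutated_ranks = sorted(
        {int(p) for p in order_stats.positions if rc.xi <= p <= rc.xk}
    )
    members = sorted(canon(r) for r in mutated_ranks)
    return ClusterReport(
        i=rc.i,
        k=rc.k,
        xi=rc.xi,
        xk=rc.xk,
        span_c=rc.span_c,
        p_raw=rc.p_raw,
        p_bonf=rc.p_bonf,
        start_residue=start,
        end_residue=end,
        members=members,
        structure_id=structure_id,
        method=path.method,
    )
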