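"""Structure-level multiplicity adjustment and the rFDR threshold.

Testing many structures (times three insertion methods) multiplies the
family of tests.  Each cluster's within-structure Bonferroni p-value is
first scaled by a structure-level multiplier into p*; p* is then
compared against an rFDR threshold

    rFDR = alpha * (k + 1) / (2k)

for k total tests — a closed-form approximation of the expected FDR
significance level that is accurate when the tests are independent or
positively correlated.  The threshold lives in (alpha/2, alpha] and
decreases toward alpha/2 as k grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cluster_stats import ClusterReport
from .errors import GraphPACError

METHOD_ORDER = ("cheapest", "nearest", "farthest")


@dataclass
class MultiplicityConfig:
    alpha: float = 0.05
    k_total: int = 1
    structure_multiplier: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise GraphPACError("alpha must be in (0, 1)")
        if self.k_total < 1:
            raise GraphPACError("k_total must be >= 1")
        if self.structure_multiplier < 1:
            raise GraphPACError("structure_multiplier must be >= 1")


def structure_level_adjust(p_bonf: float, multiplier: int) -> float:
    """p* = min(1, p_bonf * multiplier); monotone, never below p_bonf."""
    if multiplier < 1:
        raise GraphPACError("multiplier must be >= 1")
    return min(1.0, p_bonf * multiplier)


def rfdr_threshold(alpha: float, k: int) -> float:
    """alpha * (k + 1) / (2k): expected significance level over k tests."""
    if not (0.0 < alpha < 1.0):
        raise GraphPACError("alpha must be in (0, 1)")
    if k < 1:
        raise GraphPACError("k must be >= 1")
    return alpha * (k + 1) / (2 * k)


def significant_clusters(
    reports: list[ClusterReport],
    cfg: MultiplicityConfig,
    round_down: bool = True,
) -> tuple[list[ClusterReport], dict[str, str]]:
    """Filter clusters at the rFDR threshold and pick per-structure methods.

    Clusters with p* <= threshold are kept, where the threshold is
    rfdr_threshold(alpha, k_total), floored to three decimals when
    ``round_down`` is set (e.g. 0.025007... -> 0.025).  The second return
    value maps each structure to the insertion method whose most
    significant cluster has the smallest p (ties broken by the fixed
    method order cheapest, nearest, farthest).
    """
    threshold = rfdr_threshold(cfg.alpha, cfg.k_total)
    if round_down:
        threshold = math.floor(threshold * 1000) / 1000
    kept = [r for r in reports if r.p_star is not None and r.p_star <= threshold]

    best_method: dict[str, str] = {}
    best_p: dict[str, tuple[float, float, int]] = {}
    for r in reports:
        p_star = 1.0 if r.p_star is None else r.p_star
        rank = METHOD_ORDER.index(r.method) if r.method in METHOD_ORDER else len(METHOD_ORDER)
        key = (p_star, r.p_raw, rank)
        sid = r.structure_id
        if sid not in best_p or key < best_p[sid]:
            best_p[sid] = key
            best_method[sid] = r.method
    return kept, best_method
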