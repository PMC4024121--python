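"""Synthetic C-alpha traces and mutation tables with known structure.

The generators emulate the two data features the pipeline depends on:

* geometry with *domain structure* — residues far apart in sequence but
  close in space (``make_contact_domains`` builds helical segments with
  a long spatial excursion between the contacting regions); and
* per-sample missense mutation lists, either planted at chosen residues
  (``plant_mutations``) or drawn from the uniform-position null
  (``draw_uniform_mutations``).

Everything is deterministic under a fixed seed, and traces are written
as ordinary PDB ATOM records so the full pipeline consumes them exactly
like real data.  ``close_far_test`` is the rank-separation diagnostic:
residue pairs close in 3D space should sit closer along the heuristic
path than pairs far apart in space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import GraphPACError
from .graph_path import distance_matrix, hamiltonian_path, path_separation
from .mutation_data import MutationRecord
from .structure_io import CalphaTrace, Residue

# Ideal-helix constants reproducing the canonical ~3.8 A C-alpha virtual
# bond: 2.3 A radius, 1.5 A rise per residue, 100 degrees per residue.
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

_AA_CYCLE = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    n_residues: int
    geometry: str = "contact_domains"  # "helix" | "contact_domains"
    contact_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0


@dataclass
class CloseFarResult:
    mean_close: float
    mean_far: float
    t_statistic: float
    p_value: float
    close_threshold: float
    far_threshold: float
    n_structures: int


def _helix_coords(
    n: int,
    *,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    phase_deg: float = 0.0,
    z_direction: float = 1.0,
) -> np.ndarray:
    idx = np.arange(n)
    theta = np.deg2rad(phase_deg + HELIX_TWIST_DEG * idx)
    x = origin[0] + HELIX_RADIUS * np.cos(theta)
    y = origin[1] + HELIX_RADIUS * np.sin(theta)
    z = origin[2] + z_direction * HELIX_RISE * idx
    return np.column_stack([x, y, z])


def _coords_to_trace(
    coords: np.ndarray, structure_id: str, start_res: int = 1
) -> CalphaTrace:
    residues = [
        Residue(
            res_seq=start_res + i,
            icode=None,
            aa=_AA_CYCLE[i % len(_AA_CYCLE)],
            coord=coords[i],
        )
        for i in range(len(coords))
    ]
    return CalphaTrace(structure_id=structure_id, chain_id="A", residues=residues)


def make_helix(n_residues: int, *, structure_id: str = "helix") -> CalphaTrace:
    """Ideal alpha-helix trace, residues numbered 1..n."""
    if n_residues < 2:
        raise GraphPACError("a helix needs at least 2 residues")
    return _coords_to_trace(_helix_coords(n_residues), structure_id)


def make_contact_domains(spec: FixtureSpec) -> CalphaTrace:
    """Helical segments rigidly placed to realize sequence-distant contacts.

    For a contact pair (a, b, t): residues around a stay in the first
    segment, the chain then leaves on a long spatial excursion (the
    middle segment, ~60 A away), and the final segment returns
    antiparallel beside the first so that residue b sits within t
    Angstrom of residue a.  Linearly distant residues thereby become
    spatial neighbors while the sequence order runs through the
    excursion.  Additional pairs must be consistent with the same
    two-contact-region split; coordinates are verified against every
    requested pair and an unsatisfiable request raises an error.
    """
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "helix" or not spec.contact_pairs:
        coords = _helix_coords(n)
        coords = coords + rng.uniform(-0.05, 0.05, size=coords.shape)
        return _coords_to_trace(coords, f"fixture-{spec.seed}")

    a, b, target = spec.contact_pairs[0]
    if not (1 <= a < b <= n):
        raise GraphPACError(f"contact pair ({a}, {b}) out of range for n={n}")
    if target <= 0:
        raise GraphPACError("contact target distance must be positive")
    margin = max(2, (b - a) // 8)
    m1, m2 = a + margin, b - margin
    if not (a <= m1 < m2 < b <= n) or m1 < 1:
        raise GraphPACError(
            f"contact pair ({a}, {b}) too close in sequence to satisfy with "
            "an excursion segment"
        )

    # segment 1: residues 1..m1, +z axis at the origin, residue a facing +x
    seg1 = _helix_coords(m1, phase_deg=-HELIX_TWIST_DEG * (a - 1))
    # segment 2: the excursion, residues m1+1..m2, far off to the side
    seg2 = _helix_coords(m2 - m1, origin=(60.0, 15.0, 0.0))
    # segment 3: residues m2+1..n, antiparallel beside segment 1, residue b
    # facing -x; axis placed so d(a, b) = 0.9 * target before jitter
    axis_x = 2.0 * HELIX_RADIUS + 0.9 * target
    z_b = HELIX_RISE * (a - 1)  # same height as residue a
    first3 = m2 + 1
    seg3 = _helix_coords(
        n - m2,
        origin=(axis_x, 0.0, z_b + HELIX_RISE * (b - first3)),
        phase_deg=180.0 - HELIX_TWIST_DEG * (b - first3),
        z_direction=-1.0,
    )
    coords = np.vstack([seg1, seg2, seg3])
    coords = coords + rng.uniform(-0.05, 0.05, size=coords.shape)

    for pa, pb, pt in spec.contact_pairs:
        d = float(np.linalg.norm(coords[pa - 1] - coords[pb - 1]))
        if d > pt:
            raise GraphPACError(
                f"unsatisfiable contact: residues {pa} and {pb} ended up "
                f"{d:.2f} A apart, requested <= {pt} A"
            )
    return _coords_to_trace(coords, f"fixture-{spec.seed}")


def plant_mutations(
    positions_and_counts: dict[int, int],
    n_samples: int,
    protein_id: str = "FIXTURE",
) -> list[MutationRecord]:
    """Emit missense records realizing the requested per-residue counts.

    Mutations are distributed round-robin across ``n_samples`` samples;
    collapsing the output recovers the input map exactly.
    """
    if n_samples < 1:
        raise GraphPACError("need at least one sample")
    records: list[MutationRecord] = []
    slot = 0
    for pos in sorted(positions_and_counts):
        count = positions_and_counts[pos]
        if count < 1:
            raise GraphPACError("planted counts must be >= 1")
        for _ in range(count):
            records.append(
                MutationRecord(
                    sample_id=f"S{slot % n_samples + 1}",
                    protein_id=protein_id,
                    position=pos,
                    ref_aa="G",
                    alt_aa="V",
                    mutation_class="missense",
                    somatic_status="Confirmed somatic variant",
                )
            )
            slot += 1
    return records


def draw_uniform_mutations(
    n_mutations: int,
    n_residues: int,
    n_samples: int,
    seed: int,
    protein_id: str = "NULL",
) -> list[MutationRecord]:
    """Mutations with positions i.i.d. uniform on 1..n_residues (the null)."""
    rng = np.random.default_rng(seed)
    positions = rng.integers(1, n_residues + 1, size=n_mutations)
    records = []
    for idx, pos in enumerate(positions):
        records.append(
            MutationRecord(
                sample_id=f"S{idx % n_samples + 1}",
                protein_id=protein_id,
                position=int(pos),
                ref_aa="G",
                alt_aa="V",
                mutation_class="missense",
                somatic_status="Confirmed somatic variant",
            )
        )
    return records


def close_far_test(
    traces: list[CalphaTrace],
    method: str,
    close_thr: float,
    far_thr: float,
    sample_size: int = 40,
    seed: int = 0,
) -> CloseFarResult:
    """Do spatially close residues sit closer along the path than far ones?

    For each trace, ``sample_size`` residues are sampled (seeded, without
    replacement) and every pair among them is classified by Euclidean
    distance as close (< close_thr) or far (> far_thr).  The mean path
    rank separation of close pairs (c-bar_i) and far pairs (f-bar_i) is
    computed per structure, and a one-sided Welch t-test of f-bar > c-bar
    across structures is returned.  Structures lacking either pair class
    are skipped with a warning.
    """
    if close_thr >= far_thr:
        raise GraphPACError("close threshold must be below far threshold")
    if len(traces) < 2:
        raise GraphPACError("need at least 2 traces")
    rng = np.random.default_rng(seed)
    c_bars: list[float] = []
    f_bars: list[float] = []
    for trace in traces:
        coords = trace.coords()
        N = len(coords)
        D = distance_matrix(coords)
        path = hamiltonian_path(D, method)
        pick = rng.choice(N, size=min(sample_size, N), replace=False)
        close_seps: list[int] = []
        far_seps: list[int] = []
        for s in range(len(pick)):
            for t in range(s + 1, len(pick)):
                i, j = int(pick[s]), int(pick[t])
                d3 = D[i, j]
                if d3 < close_thr:
                    close_seps.append(path_separation(path, i, j))
                elif d3 > far_thr:
                    far_seps.append(path_separation(path, i, j))
        if not close_seps or not far_seps:
            warnings.warn(
                f"structure {trace.structure_id!r}: no qualifying "
                "close/far pairs, skipped",
                stacklevel=2,
            )
            continue
        c_bars.append(float(np.mean(close_seps)))
        f_bars.append(float(np.mean(far_seps)))
    if len(c_bars) < 2:
        raise GraphPACError("fewer than 2 structures with qualifying pairs")
    tt = stats.ttest_ind(f_bars, c_bars, equal_var=False, alternative="greater")
    return CloseFarResult(
        mean_close=float(np.mean(c_bars)),
        mean_far=float(np.mean(f_bars)),
        t_statistic=float(tt.statistic),
        p_value=float(tt.pvalue),
        close_threshold=close_thr,
        far_threshold=far_thr,
        n_structures=len(c_bars),
    )
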