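"""Reconcile structure residue numbering with canonical sequence positions.

A structure rarely covers the whole canonical protein: termini and
flexible loops are often unresolved, and PDB numbering need not start at
1.  Two reconciliation modes are provided:

* :func:`align_canonical` — global pairwise alignment of the ATOM-derived
  sequence against the canonical sequence (the default and the robust
  choice);
* :func:`direct_numbering_map` — trust the PDB residue numbers as
  canonical positions (usable when the depositors numbered the chain by
  the canonical sequence).

Residues without coordinates are then removed from the analysis by
:func:`restrict_counts`, which re-indexes the covered residues 1..N in
structure order.  That re-indexing is what lets the downstream uniform
null live on exactly the N observable residues.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .errors import AlignmentError, GraphPACError, InsufficientMutationsError
from .mutation_data import MutationCounts
from .structure_io import CalphaTrace, trace_sequence

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")

StructureKey = tuple[int, str | None]


@dataclass
class ResidueMap:
    """Injective map from structure residues to canonical 1-based positions.

    ``pairs`` is ordered along the structure; canonical positions are
    strictly increasing along that order.
    """

    pairs: list[tuple[StructureKey, int]]

    @property
    def N_effective(self) -> int:
        return len(self.pairs)

    def canonical_positions(self) -> list[int]:
        return [c for _, c in self.pairs]

    def to_tsv(self) -> str:
        lines = ["structure_residue\tcanonical_position"]
        for (res_seq, icode), canon in self.pairs:
            lines.append(f"{res_seq}{icode or ''}\t{canon}")
        return "\n".join(lines) + "\n"


def align_canonical(
    structure_seq: str,
    canonical_seq: str,
    *,
    trace: CalphaTrace | None = None,
    match: float = 2.0,
    mismatch: float = -1.0,
    open_gap: float = -2.0,
    extend_gap: float = -0.5,
    min_identity: float = 0.3,
) -> ResidueMap:
    """Map structure sequence positions onto canonical positions by alignment.

    A global alignment (match 2, mismatch -1, gap open -2, gap extend
    -0.5) is computed; every aligned non-gap column yields one pair.
    Mismatched columns are mapped only when both letters are standard
    amino acids (an 'X' never maps through a mismatch); gap columns are
    never mapped.  An identity below ``min_identity`` over the aligned
    columns raises :class:`AlignmentError` — that usually means the wrong
    chain or the wrong canonical sequence.

    When ``trace`` is given, structure keys are its (res_seq, icode)
    pairs; otherwise keys are (i, None) with i the 1-based position in
    ``structure_seq``.
    """
    if not structure_seq or not canonical_seq:
        raise AlignmentError("cannot align empty sequences")
    if trace is not None and len(trace) != len(structure_seq):
        raise GraphPACError("trace length does not match structure sequence length")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    alignment = aligner.align(structure_seq, canonical_seq)[0]

    keys: list[StructureKey]
    if trace is not None:
        keys = trace.keys()
    else:
        keys = [(i, None) for i in range(1, len(structure_seq) + 1)]

    pairs: list[tuple[StructureKey, int]] = []
    aligned_cols = 0
    matches = 0
    for (s_start, s_end), (c_start, c_end) in zip(*alignment.aligned):
        for off in range(s_end - s_start):
            s_i = s_start + off
            c_i = c_start + off
            a, b = structure_seq[s_i], canonical_seq[c_i]
            aligned_cols += 1
            if a == b:
                matches += 1
                pairs.append((keys[s_i], c_i + 1))
            elif a in STANDARD_AAS and b in STANDARD_AAS:
                pairs.append((keys[s_i], c_i + 1))

    if aligned_cols == 0 or matches / aligned_cols < min_identity:
        identity = 0.0 if aligned_cols == 0 else matches / aligned_cols
        raise AlignmentError(
            f"unreliable alignment: identity {identity:.1%} over {aligned_cols} "
            f"aligned columns is below the {min_identity:.0%} threshold"
        )
    return ResidueMap(pairs=pairs)


def direct_numbering_map(trace: CalphaTrace) -> ResidueMap:
    """Trust PDB residue numbers as canonical positions.

    Requires strictly positive, strictly increasing residue numbers and no
    insertion codes; anything else means the numbering is not canonical
    and the alignment mode should be used instead.
    """
    pairs: list[tuple[StructureKey, int]] = []
    last = 0
    for res in trace.residues:
        if res.icode is not None:
            raise GraphPACError(
                f"residue {res.res_seq}{res.icode} carries an insertion code; "
                "use align_canonical instead of direct numbering"
            )
        if res.res_seq < 1:
            raise GraphPACError(
                f"residue number {res.res_seq} is not a valid canonical position; "
                "use align_canonical instead of direct numbering"
            )
        if res.res_seq <= last:
            raise GraphPACError(
                f"residue numbers are not strictly increasing at {res.res_seq}; "
                "use align_canonical instead of direct numbering"
            )
        last = res.res_seq
        pairs.append((res.key, res.res_seq))
    return ResidueMap(pairs=pairs)


def restrict_counts(
    counts: MutationCounts, residue_map: ResidueMap
) -> tuple[MutationCounts, int]:
    """Drop counts at canonical positions without coordinates and re-index.

    The surviving positions are renumbered 1..N in structure order, with
    N = ``residue_map.N_effective``.  If at most one mutation survives the
    restriction, :class:`InsufficientMutationsError` is raised and the
    structure should be dropped (no pair of order statistics exists).
    """
    new_counts: dict[int, int] = {}
    for idx, (_, canon) in enumerate(residue_map.pairs, start=1):
        if canon in counts.counts:
            new_counts[idx] = counts.counts[canon]
    n_total = sum(new_counts.values())
    if n_total <= 1:
        raise InsufficientMutationsError(
            f"only {n_total} mutation(s) fall on residues with coordinates"
        )
    # n_samples is carried over unchanged: the statistic depends only on the
    # collapsed position multiset, not on the sample partition.
    restricted = MutationCounts(
        counts=new_counts, n_total=n_total, n_samples=counts.n_samples
    )
    return restricted, residue_map.N_effective
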