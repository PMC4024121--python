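"""Read, filter and collapse per-sample mutation tables.

The input is a generic tab-separated table with one row per reported
mutation (sample, protein, canonical residue position, ref/alt amino
acid, mutation class, somatic status), i.e. the shape of a curated
somatic-mutation database extract.  Analysis keeps only missense
mutations with a whitelisted somatic status, removes exact duplicate
reports, and tallies them into per-residue counts.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import RowError, SchemaError

REQUIRED_COLUMNS = (
    "sample_id",
    "protein_id",
    "position",
    "ref_aa",
    "alt_aa",
    "mutation_class",
    "somatic_status",
)

#: Somatic-status values accepted by default.  Matching is exact-string and
#: case-sensitive: these are literal curation labels, not free text.
DEFAULT_SOMATIC_STATUSES = frozenset(
    {
        "Confirmed somatic variant",
        "Reported in another cancer sample as somatic",
    }
)


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    protein_id: str
    position: int  # canonical residue position, 1-based
    ref_aa: str
    alt_aa: str
    mutation_class: str  # "missense", "nonsense", "synonymous", "other"
    somatic_status: str


@dataclass
class MutationCounts:
    """Per-residue missense counts collapsed over samples.

    ``n_total`` is the total mutation count n; ``n_samples`` the number of
    distinct samples m the counts were collapsed over.
    """

    counts: dict[int, int] = field(default_factory=dict)
    n_total: int = 0
    n_samples: int = 0

    def __post_init__(self) -> None:
        assert self.n_total == sum(self.counts.values())


def read_mutation_table(tsv_content: str) -> list[MutationRecord]:
    """Parse a TSV mutation table into records.

    The header must name the seven required fields; extra columns are
    ignored.  Raises :class:`SchemaError` for a missing column and
    :class:`RowError` (with the line number) for a non-integer position.
    """
    df = pd.read_csv(io.StringIO(tsv_content), sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table is missing required column(s): {missing}")

    records: list[MutationRecord] = []
    for idx, row in df.iterrows():
        raw_pos = row["position"]
        try:
            position = int(str(raw_pos).strip())
        except (TypeError, ValueError) as exc:
            # +2: one for the header, one for 0- vs 1-based indexing
            raise RowError(
                f"non-integer position {raw_pos!r} at line {idx + 2}"
            ) from exc
        records.append(
            MutationRecord(
                sample_id=str(row["sample_id"]),
                protein_id=str(row["protein_id"]),
                position=position,
                ref_aa=str(row["ref_aa"]),
                alt_aa=str(row["alt_aa"]),
                mutation_class=str(row["mutation_class"]),
                somatic_status=str(row["somatic_status"]),
            )
        )
    return records


def filter_mutations(
    records: Iterable[MutationRecord],
    allowed_status: frozenset[str] | set[str] | None = None,
) -> list[MutationRecord]:
    """Keep missense mutations with an allowed somatic status, deduplicated.

    Duplicate reports of the same (sample, protein, position, ref, alt)
    tuple are collapsed to one record to avoid double counting; the first
    occurrence is kept.  Filtering is idempotent.
    """
    if allowed_status is None:
        allowed_status = DEFAULT_SOMATIC_STATUSES
    out: list[MutationRecord] = []
    seen: set[tuple[str, str, int, str, str]] = set()
    for rec in records:
        if rec.mutation_class != "missense":
            continue
        if rec.somatic_status not in allowed_status:
            continue
        key = (rec.sample_id, rec.protein_id, rec.position, rec.ref_aa, rec.alt_aa)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def collapse_counts(records: Iterable[MutationRecord], protein_id: str) -> MutationCounts:
    """Tally mutations of one protein into per-residue counts.

    Collapsing is over samples: the result depends only on the multiset of
    positions, not on how mutations were distributed across samples.
    """
    positions: Counter[int] = Counter()
    samples: set[str] = set()
    for rec in records:
        if rec.protein_id != protein_id:
            continue
        positions[rec.position] += 1
        samples.add(rec.sample_id)
    counts = dict(sorted(positions.items()))
    return MutationCounts(
        counts=counts, n_total=sum(counts.values()), n_samples=len(samples)
    )
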