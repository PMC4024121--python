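"""End-to-end orchestration: parse -> reconcile -> linearize -> scan -> adjust.

Runs the full analysis over a batch of structures.  Per-structure
failures (bad file, unreliable alignment, too few mutations on covered
residues) are logged and skipped so one bad input never aborts the
batch; every input structure ends up exactly once in either the output
tables or the dropped log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import cluster_stats, graph_path, reconciliation, significance, structure_io
from .errors import GraphPACError
from .mutation_data import (
    DEFAULT_SOMATIC_STATUSES,
    collapse_counts,
    filter_mutations,
    read_mutation_table,
)

logger = logging.getLogger("graphpac")


@dataclass
class StructureInput:
    path: str
    chain: str | None = None
    protein_id: str | None = None  # defaults to the file stem

    @property
    def label(self) -> str:
        stem = Path(self.path).stem
        return f"{stem}:{self.chain}" if self.chain else stem

    def protein(self) -> str:
        return self.protein_id or Path(self.path).stem


@dataclass
class RunConfig:
    structures: list[StructureInput]
    mutation_tsv: str = ""
    canonical_fasta: str | None = None
    methods: tuple[str, ...] = graph_path.INSERTION_METHODS
    alpha: float = 0.05
    span_convention: str = "inclusive"
    k_total: int | None = None  # default: structures analyzed x methods
    structure_multiplier: int | None = None  # default: s(s-1)/2 per protein
    round_down: bool = True
    allowed_status: frozenset[str] = DEFAULT_SOMATIC_STATUSES
    min_identity: float = 0.3
    seed: int = 0
    out_dir: str = "graphpac_out"

    def __post_init__(self) -> None:
        if not self.methods:
            raise GraphPACError("at least one insertion method is required")
        for m in self.methods:
            if m not in graph_path.INSERTION_METHODS:
                raise GraphPACError(f"unknown insertion method {m!r}")
        if not (0.0 < self.alpha < 1.0):
            raise GraphPACError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        structures = [
            StructureInput(**s) if isinstance(s, dict) else StructureInput(path=s)
            for s in raw.pop("structures", [])
        ]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "allowed_status" in raw:
            raw["allowed_status"] = frozenset(raw["allowed_status"])
        return cls(structures=structures, **raw)

    def echo_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["structures"] = [dataclasses.asdict(s) for s in self.structures]
        d["methods"] = list(self.methods)
        d["allowed_status"] = sorted(self.allowed_status)
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunSummary:
    n_structures: int
    n_analyzed: int
    n_dropped: int
    n_clusters: int
    n_significant: int
    threshold: float
    best_method: dict[str, str] = field(default_factory=dict)


def _reconcile(trace, protein, canonical_seqs, min_identity):
    if canonical_seqs is not None and protein in canonical_seqs:
        return reconciliation.align_canonical(
            structure_io.trace_sequence(trace),
            canonical_seqs[protein],
            trace=trace,
            min_identity=min_identity,
        )
    return reconciliation.direct_numbering_map(trace)


def run_pipeline(cfg: RunConfig) -> RunSummary:
    """Run the four-step cluster analysis and write TSV outputs.

    Outputs in ``cfg.out_dir``: clusters.tsv (every tested pair with
    p_raw, p_bonf, p_star and a significance flag), path_orders.tsv,
    diagnostics.tsv (Kendall tau per structure x method), dropped.tsv,
    and run_config.yaml (the configuration echoed for provenance).
    Deterministic: identical config and seed give byte-identical tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = filter_mutations(
        read_mutation_table(Path(cfg.mutation_tsv).read_text()), cfg.allowed_status
    )
    canonical_seqs = None
    if cfg.canonical_fasta:
        canonical_seqs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(cfg.canonical_fasta, "fasta")
        }

    reports: list[cluster_stats.ClusterReport] = []
    diag_rows: list[dict] = []
    path_rows: list[dict] = []
    dropped: list[dict] = []
    analyzed_by_protein: dict[str, int] = {}
    structure_reports: dict[str, list[cluster_stats.ClusterReport]] = {}

    for sin in cfg.structures:
        label = sin.label
        protein = sin.protein()
        try:
            trace = structure_io.parse_calpha_trace(
                Path(sin.path).read_text(), sin.chain, structure_id=label
            )
            rmap = _reconcile(trace, protein, canonical_seqs, cfg.min_identity)
            counts = collapse_counts(records, protein)
            restricted, N = reconciliation.restrict_counts(counts, rmap)
            D = graph_path.distance_matrix(trace.coords())
        except GraphPACError as exc:
            logger.warning("dropping structure %s: %s", label, exc)
            dropped.append({"structure_id": label, "reason": str(exc)})
            continue

        analyzed_by_protein[protein] = analyzed_by_protein.get(protein, 0) + 1
        structure_reports[label] = []
        for method in cfg.methods:
            path = graph_path.hamiltonian_path(D, method)
            os_ = cluster_stats.order_statistics(restricted, path)
            for rc in cluster_stats.all_pairs_scan(os_, cfg.span_convention):
                rep = cluster_stats.unmap_cluster(
                    rc, path, rmap, os_, structure_id=label
                )
                rep.method = method
                structure_reports[label].append(rep)
            diag_rows.append(
                {
                    "structure_id": label,
                    "method": method,
                    "n_residues": N,
                    "n_mutations": restricted.n_total,
                    "kendall_tau": graph_path.kendall_tau_distance(path),
                }
            )
            for rank, vertex in enumerate(path.order, start=1):
                path_rows.append(
                    {
                        "structure_id": label,
                        "method": method,
                        "structure_residue": rmap.pairs[int(vertex)][0][0],
                        "canonical_position": rmap.pairs[int(vertex)][1],
                        "path_position": rank,
                    }
                )
    structure_protein = {s.label: s.protein() for s in cfg.structures}
    for label, reps in structure_reports.items():
        protein = structure_protein[label]
        s = analyzed_by_protein.get(protein, 1)
        multiplier = (
            cfg.structure_multiplier
            if cfg.structure_multiplier is not None
            else max(1, s * (s - 1) // 2)
        )
        for rep in reps:
            rep.p_star = significance.structure_level_adjust(rep.p_bonf, multiplier)
        reports.extend(reps)

    n_analyzed = len(structure_reports)
    k_total = cfg.k_total if cfg.k_total is not None else max(
        1, n_analyzed * len(cfg.methods)
    )
    mcfg = significance.MultiplicityConfig(alpha=cfg.alpha, k_total=k_total)
    kept, best_method = significance.significant_clusters(
        reports, mcfg, round_down=cfg.round_down
    )
    threshold = significance.rfdr_threshold(cfg.alpha, k_total)
    if cfg.round_down:
        import math

        threshold = math.floor(threshold * 1000) / 1000
    kept_ids = {id(r) for r in kept}

    cluster_df = pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "method": r.method,
                "start_residue": r.start_residue,
                "end_residue": r.end_residue,
                "n_mutations_in_cluster": r.k - r.i + 1,
                "p_raw": r.p_raw,
                "p_bonf": r.p_bonf,
                "p_star": r.p_star,
                "significant": id(r) in kept_ids,
            }
            for r in sorted(
                reports, key=lambda r: (r.structure_id, r.method, r.p_raw, r.i, r.k)
            )
        ]
    )
    cluster_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(path_rows).to_csv(out / "path_orders.tsv", sep="\t", index=False)
    pd.DataFrame(diag_rows).to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    pd.DataFrame(dropped, columns=["structure_id", "reason"]).to_csv(
        out / "dropped.tsv", sep="\t", index=False
    )
    (out / "run_config.yaml").write_text(cfg.echo_yaml())

    return RunSummary(
        n_structures=len(cfg.structures),
        n_analyzed=n_analyzed,
        n_dropped=len(dropped),
        n_clusters=len(reports),
        n_significant=len(kept),
        threshold=threshold,
        best_method=best_method,
    )
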