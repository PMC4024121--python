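"""Parse PDB ATOM records into C-alpha traces.

Only one representative atom per residue is kept (the alpha-carbon by
default).  Selection rules follow common crystallographic practice for
bulk processing: the first MODEL in the file, the first-listed alternate
location of each residue, and — when no chain is requested — the first
chain that contains a matching atom.  HETATM records are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyChainError, PDBParseError

#: Three-letter -> one-letter residue codes.  Besides the 20 standard amino
#: acids a few common non-standard residues seen in ATOM records are mapped
#: to their closest standard letter (e.g. selenomethionine -> M).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ONE_TO_THREE = {v: k for k, v in reversed(THREE_TO_ONE.items())}


@dataclass(frozen=True)
class Residue:
    """One residue of a trace: PDB numbering plus the representative atom."""

    res_seq: int
    icode: str | None
    aa: str
    coord: np.ndarray
    resname: str = ""

    @property
    def key(self) -> tuple[int, str | None]:
        return (self.res_seq, self.icode)


@dataclass
class CalphaTrace:
    """Ordered C-alpha records of one chain, in file order.

    Invariants: non-empty, no duplicated (res_seq, icode) key, one
    coordinate triple per residue.
    """

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """(N, 3) array of coordinates in Angstrom, in stored order."""
        return np.array([r.coord for r in self.residues], dtype=float)

    def keys(self) -> list[tuple[int, str | None]]:
        return [r.key for r in self.residues]


def parse_calpha_trace(
    pdb_text: str,
    chain_id: str | None = None,
    *,
    atom_name: str = "CA",
    structure_id: str = "",
) -> CalphaTrace:
    """Extract the C-alpha trace of one chain from raw PDB content.

    Parameters
    ----------
    pdb_text:
        Full text of a PDB file (ATOM records per PDB v3.3 fixed columns;
        trailing occupancy/B-factor/element columns may be absent).
    chain_id:
        Chain to extract.  When ``None`` the first chain containing a
        matching atom is used.
    atom_name:
        Representative backbone atom, "CA" by default.  Any other backbone
        atom (e.g. "N", "C", "O") works equally well as a residue position.

    Only the first MODEL of a multi-model file is read; for residues with
    alternate locations the first-listed altLoc is kept.
    """
    residues: list[Residue] = []
    seen: set[tuple[int, str | None]] = set()
    locked_chain: str | None = chain_id
    model_count = 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            model_count += 1
            if model_count > 1:
                break
            continue
        if record.startswith("ENDMDL"):
            break
        if not record.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"ATOM record too short at line {lineno}: {line!r}")
        if line[12:16].strip() != atom_name:
            continue
        chain = line[21]
        if locked_chain is None:
            locked_chain = chain
        if chain != locked_chain:
            continue
        try:
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"malformed ATOM coordinate/number columns at line {lineno}: {line!r}"
            ) from exc
        icode = line[26].strip() or None
        key = (res_seq, icode)
        if key in seen:
            # duplicate (res_seq, icode): a later altLoc of a residue we
            # already hold -- the first-listed conformation wins.
            continue
        seen.add(key)
        resname = line[17:20].strip()
        residues.append(
            Residue(
                res_seq=res_seq,
                icode=icode,
                aa=THREE_TO_ONE.get(resname, "X"),
                coord=np.array([x, y, z], dtype=float),
                resname=resname,
            )
        )

    if not residues:
        target = chain_id if chain_id is not None else "<any>"
        raise EmptyChainError(
            f"no {atom_name} atoms found for chain {target!r} in structure "
            f"{structure_id or '<unnamed>'}"
        )
    return CalphaTrace(structure_id=structure_id, chain_id=locked_chain, residues=residues)


def trace_sequence(trace: CalphaTrace) -> str:
    """One-letter sequence of the trace in stored order ('X' for unknowns)."""
    return "".join(r.aa for r in trace.residues)


def write_calpha_pdb(trace: CalphaTrace) -> str:
    """Render a trace as minimal fixed-width ATOM records (plus END).

    Round-trips through :func:`parse_calpha_trace`: residue numbers, amino
    acids and coordinates survive to the PDB 3-decimal precision.
    """
    lines = []
    for serial, r in enumerate(trace.residues, start=1):
        resname = r.resname or ONE_TO_THREE.get(r.aa, "UNK")
        icode = r.icode or " "
        x, y, z = r.coord
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3} {trace.chain_id}"
            f"{r.res_seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
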