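"""Readers and writers: FASTA, extended dot-bracket, TSV tables, and
coarse-grained PDB.

One TSV dialect everywhere: tab-separated, '.' decimal point, no thousands
separators.  All user-facing indices are 1-based.
"""

from __future__ import annotations

import logging
import math
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .geometry import ScaffoldResidue, ScaffoldStructure
from .structure import SecondaryStructure, parse_dotbracket, write_dotbracket

logger = logging.getLogger("kisfold")

_RNA = set("AUGC")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA records as (id, sequence) with an RNA-only alphabet.

    Sequences are uppercased; T is mapped to U with a warning.  Illegal
    characters raise ParseError with the 1-based line number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    # validate characters line by line so errors carry line numbers
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith((">", ";")):
            continue
        bad = set(line.upper()) - _RNA - {"T"}
        if bad:
            raise ParseError(
                f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
            )
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            logger.warning("record %s: DNA alphabet detected, mapping T -> U", rec.id)
            seq = seq.replace("T", "U")
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Extended dot-bracket (.dbn)
# ---------------------------------------------------------------------------


def read_dbn(path: str | Path) -> SecondaryStructure:
    """Read a .dbn file: optional '>' header, sequence line (with '&' for
    dimers), bracket line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected a sequence line and a structure line")
    return parse_dotbracket(lines[0], lines[1])


def write_dbn(path: str | Path, structure: SecondaryStructure, name: str = "structure") -> None:
    seq = "&".join(structure.sequences)
    with open(path, "w") as fh:
        fh.write(f">{name}\n{seq}\n{write_dotbracket(structure)}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_landscape_tsv(path: str | Path, grid) -> None:
    grid.to_dataframe().to_csv(path, sep="\t", index=False)


def write_counts_tsv(path: str | Path, counts: dict[int, int]) -> None:
    """Free-coil conformation counts as (n_nt, count, ln_omega)."""
    rows = [
        {"n_nt": n, "count": c, "ln_omega": math.log(c) if c else float("-inf")}
        for n, c in sorted(counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_obstacles_tsv(path: str | Path, obstacles) -> None:
    pd.DataFrame(sorted(obstacles), columns=["x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def read_obstacles_tsv(path: str | Path) -> frozenset:
    df = pd.read_csv(path, sep="\t")
    return frozenset((int(r.x), int(r.y), int(r.z)) for r in df.itertuples(index=False))


# ---------------------------------------------------------------------------
# Coarse-grained PDB
# ---------------------------------------------------------------------------

_LABEL_B = {"helix": 1.0, "loop": 2.0}
_B_LABEL = {1.0: "helix", 2.0: "loop"}


def _to_atom_array(scaffold: ScaffoldStructure):
    import biotite.structure as struc

    n = 2 * scaffold.n_residues
    arr = struc.AtomArray(n)
    coords = np.zeros((n, 3))
    k = 0
    for r in scaffold.residues:
        for name, xyz, elem in (("P", r.p, "P"), ("C4'", r.c4, "C")):
            arr.chain_id[k] = r.chain_id
            arr.res_id[k] = r.resi
            arr.res_name[k] = r.name if r.name in "AUGC" else "N"
            arr.atom_name[k] = name
            arr.element[k] = elem
            arr.hetero[k] = False
            coords[k] = xyz
            k += 1
    arr.coord = coords
    arr.set_annotation("b_factor", np.array(
        [_LABEL_B[r.label] for r in scaffold.residues for _ in range(2)]
    ))
    return arr


def write_pdb(path: str | Path, scaffold: ScaffoldStructure) -> None:
    """Write the scaffold as standard ATOM lines (atom names P and C4'),
    one chain per strand, TER between chains."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(scaffold))
    pdb.write(str(path))
    _ensure_ter(Path(path))


def _ensure_ter(path: Path) -> None:
    lines = path.read_text().splitlines()
    out = []
    prev_chain = None
    for ln in lines:
        if ln.startswith("ATOM"):
            chain = ln[21]
            if prev_chain is not None and chain != prev_chain:
                out.append("TER")
            prev_chain = chain
        out.append(ln)
    if prev_chain is not None and (not out or not out[-1].startswith("TER")):
        out.append("TER")
    path.write_text("\n".join(out) + "\n")


def read_pdb(path: str | Path) -> ScaffoldStructure:
    """Read a coarse-grained scaffold PDB written by write_pdb."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
    residues: list[ScaffoldResidue] = []
    seen: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    for k in range(arr.array_length()):
        key = (str(arr.chain_id[k]), int(arr.res_id[k]))
        if key not in seen:
            seen[key] = {"name": str(arr.res_name[k]), "b": float(arr.b_factor[k])}
            order.append(key)
        seen[key][str(arr.atom_name[k])] = np.array(arr.coord[k], dtype=float)
    for chain_id, resi in order:
        d = seen[(chain_id, resi)]
        if "P" not in d or "C4'" not in d:
            raise ParseError(f"{path}: residue {chain_id}{resi} lacks P/C4' pseudo-atoms")
        residues.append(
            ScaffoldResidue(
                chain_id=chain_id,
                resi=resi,
                name=d["name"] if d["name"] in "AUGC" else "N",
                label=_B_LABEL.get(d["b"], "helix"),
                p=d["P"],
                c4=d["C4'"],
            )
        )
    return ScaffoldStructure(residues=residues)
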