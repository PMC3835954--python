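"""Input/output for the standard formats the pipeline touches.

FASTA nucleotide sequences (the trigger dsRNA and its orthologs), CSV
bioassay tables, and Newick serialization of the identity-distance tree.
Sequences are stored in the DNA alphabet: dsRNA triggers arrive as cDNA
clones, so U is normalized to T on input (the original alphabet is
remembered so output can round-trip) and T/U compare equal everywhere
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .phylogenetics import Tree

DNA_ALPHABET = frozenset("ACGTN")
TREATMENTS = ("control", "test", "positive_control")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (trigger dsRNA or ortholog region).

    Residues are uppercase DNA symbols over {A,C,G,T,N}; ``is_rna`` records
    whether the source used U so writing can restore it.
    """

    id: str
    residues: str
    description: str = ""
    is_rna: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains illegal symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> tuple[str, bool]:
    """Uppercase and convert U->T; return (dna_residues, had_u)."""
    up = raw.upper()
    return up.replace("U", "T"), "U" in up


@dataclass(frozen=True)
class BioassayRow:
    """One treatment group in a feeding bioassay.

    ``dose`` is the diet concentration in ng/mL (liquid diets) or ng/g
    (solid diets); the two are treated identically. ``endpoint_value`` is an
    optional continuous measurement such as mean larval weight in mg.
    """

    species: str
    treatment: str
    dose: float
    n_exposed: int
    n_dead: int
    endpoint_value: float | None = None

    def __post_init__(self):
        if self.dose < 0:
            raise ValidationError(f"negative dose {self.dose}")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValidationError(
                f"n_dead={self.n_dead} outside [0, n_exposed={self.n_exposed}]"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment {self.treatment!r} not one of {TREATMENTS}"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Residues are uppercased with U normalized to T; gap characters are
    rejected here (use :func:`read_gapped_fasta` for pre-aligned input).
    Raises :class:`ParseError` with a line number for an empty file,
    duplicate ids, or illegal symbols.
    """
    return _read_fasta(path, allow_gaps=False)


def read_gapped_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read pre-aligned FASTA; '-' gap columns are preserved in residues.

    Records returned here are plain tuples of (id, description, row, is_rna)
    packed into SequenceRecord-like rows via :class:`GappedRecord`.
    """
    rows = _read_fasta(path, allow_gaps=True)
    return rows


@dataclass(frozen=True)
class GappedRecord:
    """A gapped alignment row read from pre-aligned FASTA."""

    id: str
    row: str
    description: str = ""
    is_rna: bool = False

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id,
            residues=self.row.replace("-", ""),
            description=self.description,
            is_rna=self.is_rna,
        )


def _read_fasta(path, allow_gaps: bool):
    # Hand line loop (not SeqIO) so parse errors carry line numbers.
    path = Path(path)
    records: list = []
    seen: set[str] = set()
    header_line = None
    rec_id = rec_desc = None
    chunks: list[str] = []
    raw_u = False

    def flush():
        nonlocal raw_u
        if rec_id is None:
            return
        raw = "".join(chunks)
        residues, had_u = normalize_residues(raw)
        if not residues:
            raise ParseError(f"record {rec_id!r} has no residues", header_line)
        allowed = DNA_ALPHABET | ({"-"} if allow_gaps else set())
        bad = set(residues) - allowed
        if bad:
            raise ParseError(
                f"record {rec_id!r} contains illegal symbols {sorted(bad)}",
                header_line,
            )
        if allow_gaps:
            records.append(
                GappedRecord(id=rec_id, row=residues, description=rec_desc, is_rna=had_u)
            )
        else:
            records.append(
                SequenceRecord(
                    id=rec_id, residues=residues, description=rec_desc, is_rna=had_u
                )
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError("empty FASTA header", lineno)
                rid = parts[0]
                if rid in seen:
                    raise ParseError(f"duplicate sequence id {rid!r}", lineno)
                seen.add(rid)
                rec_id, rec_desc = rid, (parts[1] if len(parts) > 1 else "")
                header_line, chunks = lineno, []
            else:
                if rec_id is None:
                    raise ParseError("sequence data before first header", lineno)
                chunks.append(line)
    flush()
    if not records:
        raise ParseError(f"no FASTA records in {path}", 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, restoring U for RNA-flagged sequences."""
    bio = []
    for r in records:
        seq = r.residues.replace("T", "U") if r.is_rna else r.residues
        bio.append(_BioRecord(Seq(seq), id=r.id, description=r.description))
    SeqIO.write(bio, str(path), "fasta")


# --- bioassay tables -------------------------------------------------------

BIOASSAY_COLUMNS = ["species", "treatment", "dose", "n_exposed", "n_dead", "endpoint_value"]


def read_bioassay_table(path: str | Path) -> list[BioassayRow]:
    """Read a CSV bioassay table into validated rows.

    Required columns: species, treatment, dose, n_exposed, n_dead; the
    endpoint_value column is optional. Invariant-violating rows raise
    :class:`ValidationError` naming the row index.
    """
    df = pd.read_csv(path)
    missing = set(BIOASSAY_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"bioassay table missing columns {sorted(missing)}", 1)
    rows = []
    for idx, rec in df.iterrows():
        ev = rec.get("endpoint_value")
        if ev is not None and isinstance(ev, float) and math.isnan(ev):
            ev = None
        try:
            rows.append(
                BioassayRow(
                    species=str(rec["species"]),
                    treatment=str(rec["treatment"]),
                    dose=float(rec["dose"]),
                    n_exposed=int(rec["n_exposed"]),
                    n_dead=int(rec["n_dead"]),
                    endpoint_value=None if ev is None else float(ev),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"bioassay row {idx}: {exc}") from exc
    return rows


def write_bioassay_table(rows: Iterable[BioassayRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "treatment": r.treatment,
                "dose": r.dose,
                "n_exposed": r.n_exposed,
                "n_dead": r.n_dead,
                "endpoint_value": r.endpoint_value,
            }
            for r in rows
        ],
        columns=BIOASSAY_COLUMNS,
    )
    df.to_csv(path, index=False)


# --- Newick ----------------------------------------------------------------


def newick_string(tree: "Tree") -> str:
    """Serialize a rooted tree with branch lengths to Newick."""
    from .phylogenetics import Tree  # local import to avoid a cycle

    if not isinstance(tree, Tree):
        raise ValidationError("newick_string expects a Tree")

    def render(node) -> str:
        if not node.children:
            if not node.label:
                raise ValidationError("unlabeled leaf cannot be serialized")
            return f"{node.label}:{node.branch_length:.12g}" if node.parent_known else node.label
        inner = ",".join(render(c) for c in node.children)
        if node.parent_known:
            return f"({inner}):{node.branch_length:.12g}"
        return f"({inner})"

    return render(tree.root) + ";"


def write_newick(tree: "Tree", path: str | Path) -> None:
    """Write the tree as a single-line Newick file terminated by ';'."""
    Path(path).write_text(newick_string(tree) + "\n")
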