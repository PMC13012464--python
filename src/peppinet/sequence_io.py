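"""Sequence and pair-table I/O with amino-acid alphabet validation.

Sequences are plain upper-case amino-acid strings.  The 20 canonical
residues are "standard"; the ambiguity/rare letters B, Z, X, U, O, J are
accepted but flagged non-standard, mirroring common practice for
PDB-derived sequence sets.  Pair tables are TSV files with a header row
``peptide_id\tprotein_id\tlabel\tsource``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
# accepted but counted non-standard (ambiguity codes and rare residues)
EXTENDED_AA = frozenset("BZXUOJ")
ACCEPTED_AA = STANDARD_AA | EXTENDED_AA


@dataclass(frozen=True)
class SequenceRecord:
    """An identified peptide or protein sequence.

    role is either ``"peptide"`` or ``"protein"``.
    """

    id: str
    sequence: str
    role: str = "protein"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.role not in ("peptide", "protein"):
            raise ValueError(f"unknown role {self.role!r}")
        validate_sequence(self.sequence, seq_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairExample:
    """One labeled (peptide, protein) example."""

    peptide_id: str
    protein_id: str
    label: int
    source: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def validate_sequence(seq: str, seq_id: str = "?", alphabet: frozenset = ACCEPTED_AA) -> None:
    """Raise ValueError on an empty sequence or any letter outside *alphabet*."""
    if not seq:
        raise ValueError(f"sequence {seq_id!r} is empty")
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise ValueError(
                f"sequence {seq_id!r}: illegal character {ch!r} at position {pos}"
            )


def nonstandard_fraction(seq: str, standard: frozenset = STANDARD_AA) -> float:
    """Fraction of residues outside the canonical 20-letter alphabet.

    The standard set is configurable because no single convention covers
    every structure-derived dataset.
    """
    if not seq:
        raise ValueError("nonstandard_fraction undefined for empty sequence")
    return sum(1 for ch in seq if ch not in standard) / len(seq)


def read_fasta(path, role: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The id is the header token before the first whitespace; sequences are
    upper-cased and validated.  Duplicate ids, empty sequences and illegal
    characters raise ValueError.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    chunks: list[str] = []

    def flush():
        if cur_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"FASTA entry {cur_id!r} has an empty sequence")
        records.append(SequenceRecord(id=cur_id, sequence=seq, role=role))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise ValueError(f"FASTA header without id in {path}")
                if cur_id in seen:
                    raise ValueError(f"duplicate FASTA id {cur_id!r}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise ValueError(f"sequence data before first header in {path}")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of read_fasta."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


PAIR_COLUMNS = ("peptide_id", "protein_id", "label", "source")


def read_pair_table(path) -> list[PairExample]:
    """Read a TSV pair table (header required; source column optional)."""
    pairs: list[PairExample] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty pair table")
        header = header_line.rstrip("\n").split("\t")
        for col in ("peptide_id", "protein_id", "label"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            raw = fields[idx["label"]]
            if raw not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: label must be 0 or 1, got {raw!r}"
                )
            source = fields[idx["source"]] if "source" in idx and len(fields) > idx["source"] else ""
            pairs.append(
                PairExample(
                    peptide_id=fields[idx["peptide_id"]],
                    protein_id=fields[idx["protein_id"]],
                    label=int(raw),
                    source=source,
                )
            )
    return pairs


def write_pair_table(pairs: Iterable[PairExample], path) -> None:
    """Write pairs as TSV; inverse of read_pair_table."""
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(f"{p.peptide_id}\t{p.protein_id}\t{p.label}\t{p.source}\n")


def resolve_pairs(pairs: Sequence[PairExample], records: Sequence[SequenceRecord]) -> None:
    """Check that every pair's ids resolve against a sequence collection."""
    ids = {r.id for r in records}
    for p in pairs:
        for which in (p.peptide_id, p.protein_id):
            if which not in ids:
                raise KeyError(f"pair references unknown sequence id {which!r}")
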