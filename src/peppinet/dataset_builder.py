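"""Build labeled peptide-protein pairs from complex structures.

Contact rule: two residues on different chains interact when their
alpha-carbon distance is strictly below 5 Angstrom.  If either residue
lacks a Calpha, the nearest inter-atomic distance across all atom pairs is
used instead; a residue with no usable coordinates at all is regarded as
non-binding.  A complex contributes a positive pair when at least one
cross-chain residue pair interacts.  Pairs in which either sequence is
more than 20% non-standard residues are dropped, and negatives are drawn
uniformly from the non-positive (peptide, protein) combinations, one per
positive.

The peptide chain is the shortest chain of length <= peptide_max_len
(default 50 residues); every other chain is treated as a candidate
receptor independently.  Chain sequences come from the observed coordinate
records (SEQRES is ignored), since contacts are defined on coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .sequence_io import PairExample, SequenceRecord, nonstandard_fraction

CONTACT_THRESHOLD = 5.0  # Angstrom, strict '<'
DEFAULT_PEPTIDE_MAX_LEN = 50
NONSTANDARD_MAX_FRACTION = 0.20

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEC": "U", "PYL": "O", "ASX": "B", "GLX": "Z",
}


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    name: str  # three-letter code
    number: int
    icode: str = ""
    atoms: tuple[Atom, ...] = ()

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), "X")

    @property
    def calpha(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None

    @property
    def key(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ComplexStructure:
    complex_id: str
    chains: tuple[Chain, ...]


@dataclass(frozen=True)
class ContactVerdict:
    residue_a: str
    residue_b: str
    distance: float | None
    verdict: str  # "interacting" | "non_binding"
    basis: str  # "calpha" | "nearest_atom" | "missing_coordinates"


def parse_structure(path, complex_id: str | None = None) -> ComplexStructure:
    """Parse a PDB file; altlocs resolve to the highest-occupancy atom."""
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    structure = parser.get_structure(complex_id or path.stem, str(path))
    model = next(structure.get_models())
    chains = []
    for chain in model:
        residues = []
        for res in chain:
            atoms = tuple(
                Atom(name=a.get_name(), coord=tuple(float(x) for x in a.get_coord()))
                for a in res.get_atoms()  # disordered atoms yield best occupancy
            )
            het, seqnum, icode = res.get_id()
            residues.append(
                Residue(name=res.get_resname().strip(), number=int(seqnum),
                        icode=icode.strip(), atoms=atoms)
            )
        if residues:
            chains.append(Chain(chain_id=chain.id, residues=tuple(residues)))
    return ComplexStructure(complex_id=complex_id or path.stem, chains=tuple(chains))


def _dist(a: Atom, b: Atom) -> float:
    return math.dist(a.coord, b.coord)


def residue_contact(
    res_a: Residue, res_b: Residue, threshold: float = CONTACT_THRESHOLD
) -> ContactVerdict:
    """Contact verdict for a cross-chain residue pair (symmetric)."""
    if not res_a.atoms or not res_b.atoms:
        return ContactVerdict(res_a.key, res_b.key, None, "non_binding",
                              "missing_coordinates")
    ca_a, ca_b = res_a.calpha, res_b.calpha
    if ca_a is not None and ca_b is not None:
        d = _dist(ca_a, ca_b)
        basis = "calpha"
    else:
        d = min(_dist(a, b) for a in res_a.atoms for b in res_b.atoms)
        basis = "nearest_atom"
    verdict = "interacting" if d < threshold else "non_binding"
    return ContactVerdict(res_a.key, res_b.key, d, verdict, basis)


@dataclass(frozen=True)
class ComplexLabel:
    """Outcome of labeling one complex."""

    records: tuple[SequenceRecord, ...]
    positives: tuple[PairExample, ...]
    rejection_reason: str | None = None
    contact_counts: tuple[tuple[str, int], ...] = ()  # (protein chain id, n contacts)


def label_complex(
    c: ComplexStructure,
    peptide_max_len: int = DEFAULT_PEPTIDE_MAX_LEN,
    threshold: float = CONTACT_THRESHOLD,
) -> ComplexLabel:
    """Identify the peptide chain and emit positives for contacting receptors.

    The peptide is the shortest chain with length <= peptide_max_len (ties
    broken by chain id); each remaining chain is examined independently and
    yields a positive pair when at least one residue pair interacts.
    """
    if len(c.chains) < 2:
        return ComplexLabel((), (), rejection_reason="fewer than 2 chains")
    qualifying = [ch for ch in c.chains if len(ch) <= peptide_max_len]
    if not qualifying:
        return ComplexLabel(
            (), (), rejection_reason=f"no chain of length <= {peptide_max_len}"
        )
    peptide = min(qualifying, key=lambda ch: (len(ch), ch.chain_id))
    pep_rec = SequenceRecord(
        id=f"{c.complex_id}_{peptide.chain_id}", sequence=peptide.sequence, role="peptide"
    )
    records = [pep_rec]
    positives = []
    counts = []
    for other in c.chains:
        if other.chain_id == peptide.chain_id:
            continue
        prot_rec = SequenceRecord(
            id=f"{c.complex_id}_{other.chain_id}", sequence=other.sequence, role="protein"
        )
        records.append(prot_rec)
        n_contacts = sum(
            residue_contact(ra, rb, threshold).verdict == "interacting"
            for ra in peptide.residues
            for rb in other.residues
        )
        counts.append((other.chain_id, n_contacts))
        if n_contacts > 0:
            positives.append(
                PairExample(
                    peptide_id=pep_rec.id,
                    protein_id=prot_rec.id,
                    label=1,
                    source=c.complex_id,
                )
            )
    return ComplexLabel(tuple(records), tuple(positives), contact_counts=tuple(counts))


def filter_nonstandard(
    records: Sequence[SequenceRecord],
    max_fraction: float = NONSTANDARD_MAX_FRACTION,
) -> list[SequenceRecord]:
    """Keep records whose non-standard fraction does not exceed the cap."""
    return [r for r in records if nonstandard_fraction(r.sequence) <= max_fraction]


def filter_pairs_nonstandard(
    pairs: Sequence[PairExample],
    records: Sequence[SequenceRecord],
    max_fraction: float = NONSTANDARD_MAX_FRACTION,
) -> list[PairExample]:
    """Drop pairs in which either member exceeds the non-standard cap."""
    kept = {r.id for r in filter_nonstandard(records, max_fraction)}
    return [p for p in pairs if p.peptide_id in kept and p.protein_id in kept]


def sample_negatives(
    positives: Sequence[PairExample],
    peptides: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    seed: int = 1234,
    n: int | None = None,
) -> list[PairExample]:
    """Uniformly sample non-positive (peptide, protein) pairs, label 0.

    Without replacement; count defaults to the number of positives, the
    balanced-dataset convention.
    """
    n = len(positives) if n is None else n
    known = {(p.peptide_id, p.protein_id) for p in positives}
    candidates = sorted(
        (pep.id, prot.id)
        for pep in peptides
        for prot in proteins
        if (pep.id, prot.id) not in known
    )
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} non-positive combinations available, need {n}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [
        PairExample(peptide_id=candidates[i][0], protein_id=candidates[i][1],
                    label=0, source="sampled_negative")
        for i in sorted(picked)
    ]


def build_dataset(
    pdb_paths: Sequence,
    peptide_max_len: int = DEFAULT_PEPTIDE_MAX_LEN,
    max_nonstandard: float = NONSTANDARD_MAX_FRACTION,
    seed: int = 1234,
) -> tuple[list[SequenceRecord], list[PairExample]]:
    """End-to-end construction: parse, label, filter, add sampled negatives."""
    records: dict[str, SequenceRecord] = {}
    positives: list[PairExample] = []
    for path in pdb_paths:
        result = label_complex(parse_structure(path), peptide_max_len)
        for rec in result.records:
            records.setdefault(rec.id, rec)
        positives.extend(result.positives)
    all_records = list(records.values())
    positives = filter_pairs_nonstandard(positives, all_records, max_nonstandard)
    kept = {r.id for r in filter_nonstandard(all_records, max_nonstandard)}
    peptides = [r for r in all_records if r.role == "peptide" and r.id in kept]
    proteins = [r for r in all_records if r.role == "protein" and r.id in kept]
    negatives = sample_negatives(positives, peptides, proteins, seed=seed)
    return all_records, positives + negatives
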