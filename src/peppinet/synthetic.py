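"""Synthetic data generators: planted-interaction embeddings, toy complex
structures with contacts at known distances, and sequence families with
controlled pairwise identity.

All generators are pure functions of their parameters and seed.

Planted interaction rule
------------------------
Peptide and protein embeddings are drawn from a standard normal.  The
interaction score of a pair is the low-rank quadratic form of the pair
mean m = (p + q)/2 through a planted orthonormal basis U (dim x rank),

    s(p, q) = || U^T m ||^2
            = ( p^T U U^T p + q^T U U^T q + 2 p^T U U^T q ) / 4 ,

plus Gaussian noise, thresholded to hit the requested positive fraction.
The score contains the cross bilinear term p^T U U^T q, so interaction
strength genuinely couples the two entities through the planted subspace.
The pair-mean form is chosen deliberately: on the 2-node pair graph with
self-loops the first graph convolution maps both node rows to the same
function of p + q, so any pair rule whose optimal predictor is not a
function of the node sum is unlearnable by this architecture regardless of
training (for a purely cross-term rule on independent entities the
Bayes-from-sum ROC AUC is exactly 5/6).  The pair-mean quadratic keeps the
planted subspace recoverable from the sum, making the generated problem a
true learnability probe rather than an impossibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import ResidueEmbeddingMatrix, SequenceEmbedding
from .sequence_io import PairExample, SequenceRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# planted-interaction embeddings


@dataclass(frozen=True)
class SyntheticSpec:
    n_peptides: int = 50
    n_proteins: int = 40
    dim: int = 64
    rank: int = 2
    noise_sd: float = 0.1  # in units of the planted score's standard deviation
    label_threshold: float | None = None  # None: calibrate to positive_fraction
    positive_fraction: float = 0.5
    seed: int = 1234

    def __post_init__(self):
        if not 1 <= self.rank <= self.dim:
            raise ValueError("need dim >= rank >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticInteractionData:
    records: tuple[SequenceRecord, ...]
    embeddings: dict[str, SequenceEmbedding]
    pairs: tuple[PairExample, ...]
    planted_basis: np.ndarray  # dim x rank
    scores: np.ndarray  # noiseless planted scores, one per pair
    threshold: float


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=length))


def gen_interaction_data(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticInteractionData:
    """Generate embeddings and labeled pairs under the planted rule.

    Pairs are the full bipartite cross of peptides and proteins.  With
    noise_sd = 0 the labels are a deterministic function of the planted
    score, so the Bayes-optimal ranking attains AUC 1 on the generated set.
    """
    rng = np.random.default_rng(spec.seed)
    u, _ = np.linalg.qr(rng.standard_normal((spec.dim, spec.rank)))

    records: list[SequenceRecord] = []
    embeddings: dict[str, SequenceEmbedding] = {}
    for prefix, n, role, lo, hi in (
        ("pep", spec.n_peptides, "peptide", 8, 15),
        ("prot", spec.n_proteins, "protein", 50, 120),
    ):
        for i in range(n):
            sid = f"{prefix}{i:04d}"
            records.append(
                SequenceRecord(sid, _random_sequence(rng, int(rng.integers(lo, hi + 1))), role)
            )
            embeddings[sid] = SequenceEmbedding(sid, rng.standard_normal(spec.dim))

    pep_ids = [r.id for r in records if r.role == "peptide"]
    prot_ids = [r.id for r in records if r.role == "protein"]
    pairs_idx = [(a, b) for a in pep_ids for b in prot_ids]
    means = np.stack(
        [(embeddings[a].vector + embeddings[b].vector) / 2.0 for a, b in pairs_idx]
    )
    scores = ((means @ u) ** 2).sum(axis=1)
    noisy = scores + spec.noise_sd * scores.std() * rng.standard_normal(len(scores))
    threshold = (
        float(np.quantile(noisy, 1.0 - spec.positive_fraction))
        if spec.label_threshold is None
        else spec.label_threshold
    )
    labels = (noisy > threshold).astype(int)
    pairs = tuple(
        PairExample(peptide_id=a, protein_id=b, label=int(y), source="synthetic")
        for (a, b), y in zip(pairs_idx, labels)
    )
    return SyntheticInteractionData(
        records=tuple(records),
        embeddings=embeddings,
        pairs=pairs,
        planted_basis=u,
        scores=scores,
        threshold=threshold,
    )


def residue_matrices(data: SyntheticInteractionData) -> list[ResidueEmbeddingMatrix]:
    """Constant L x D residue matrices whose mean pool is the planted vector."""
    by_id = {r.id: r for r in data.records}
    return [
        ResidueEmbeddingMatrix(
            seq_id=sid, values=np.tile(emb.vector, (len(by_id[sid].sequence), 1))
        )
        for sid, emb in data.embeddings.items()
    ]


# ---------------------------------------------------------------------------
# toy complex structures


@dataclass(frozen=True)
class PlannedContact:
    pep_pos: int  # 0-based residue index in the peptide chain
    prot_pos: int  # 0-based residue index in the protein chain
    distance: float  # Angstrom
    kind: str = "calpha"  # "calpha" | "nearest_atom" | "missing_coords"


@dataclass(frozen=True)
class ComplexPlan:
    complex_id: str
    pep_len: int
    prot_len: int
    contacts: tuple[PlannedContact, ...] = ()
    pep_nonstandard_fraction: float = 0.0
    with_altloc: bool = False


@dataclass(frozen=True)
class ContactTruth:
    complex_id: str
    pep_pos: int
    prot_pos: int
    kind: str
    distance: float
    expect_interacting: bool
    expect_basis: str


RESIDUE_SPACING = 50.0  # Angstrom between consecutive residues: no stray contacts
CHAIN_OFFSET = 500.0


def _validate_plan(plan: ComplexPlan) -> None:
    used_pep, used_prot = set(), set()
    for c in plan.contacts:
        if not (0 <= c.pep_pos < plan.pep_len and 0 <= c.prot_pos < plan.prot_len):
            raise ValueError(f"{plan.complex_id}: contact position out of range")
        if c.pep_pos in used_pep or c.prot_pos in used_prot:
            raise ValueError(
                f"{plan.complex_id}: residue reused across planned contacts; "
                "each planned contact needs its own residue pair"
            )
        if c.kind not in ("calpha", "nearest_atom", "missing_coords"):
            raise ValueError(f"{plan.complex_id}: unknown contact kind {c.kind!r}")
        used_pep.add(c.pep_pos)
        used_prot.add(c.prot_pos)


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, occupancy=1.0, altloc=" "):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    element = name[0]
    return (
        f"ATOM  {serial:>5d} {name_field}{altloc}{resname:>3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def gen_toy_structures(
    plans: Sequence[ComplexPlan], out_dir, seed: int = 1234
) -> tuple[list[Path], list[ContactTruth]]:
    """Write PDB files realizing the contact plans; return paths + truth table.

    Geometry: chain A (peptide) residues sit on a widely spaced line; chain
    B (protein) residues sit on a parallel line 500 A away, except that a
    planned contact moves the protein residue directly opposite its peptide
    partner at exactly the planned distance.  ``nearest_atom`` contacts
    strip the protein residue's Calpha so the fallback rule fires, and
    ``missing_coords`` residues are written with no atoms at all (they
    appear only in the truth table, matching an unresolved residue).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths, truths = [], []
    for plan in plans:
        _validate_plan(plan)
        contact_by_prot = {c.prot_pos: c for c in plan.contacts}
        n_nonstd = int(round(plan.pep_nonstandard_fraction * plan.pep_len))
        lines = []
        serial = 1
        for i in range(plan.pep_len):
            resname = "UNK" if i < n_nonstd else "GLY"
            xyz = (RESIDUE_SPACING * i, 0.0, 0.0)
            if plan.with_altloc and i == 0:
                lines.append(_pdb_atom_line(serial, "CA", resname, "A", i + 1, xyz,
                                            occupancy=0.7, altloc="A"))
                serial += 1
                alt = (xyz[0] + 0.5, 0.5, 0.0)
                lines.append(_pdb_atom_line(serial, "CA", resname, "A", i + 1, alt,
                                            occupancy=0.3, altloc="B"))
                serial += 1
            else:
                lines.append(_pdb_atom_line(serial, "CA", resname, "A", i + 1, xyz))
                serial += 1
        for j in range(plan.prot_len):
            contact = contact_by_prot.get(j)
            if contact is not None and contact.kind == "missing_coords":
                continue  # unresolved residue: no coordinate records
            if contact is None:
                xyz = (RESIDUE_SPACING * j, CHAIN_OFFSET, 0.0)
                atoms = [("CA", xyz)]
            else:
                base = (RESIDUE_SPACING * contact.pep_pos, contact.distance, 0.0)
                if contact.kind == "calpha":
                    atoms = [("CA", base)]
                else:  # nearest_atom: no Calpha on this residue
                    atoms = [("CB", base)]
            for name, xyz in atoms:
                lines.append(_pdb_atom_line(serial, name, "GLY", "B", j + 1, xyz))
                serial += 1
        path = out_dir / f"{plan.complex_id}.pdb"
        path.write_text("".join(lines) + "END\n")
        paths.append(path)
        for c in plan.contacts:
            interacting = c.kind != "missing_coords" and c.distance < 5.0
            basis = "missing_coordinates" if c.kind == "missing_coords" else c.kind
            truths.append(
                ContactTruth(plan.complex_id, c.pep_pos, c.prot_pos, c.kind,
                             c.distance, interacting, basis)
            )
    return paths, truths


def default_structure_suite() -> list[ComplexPlan]:
    """A fixed plan set covering interacting, boundary, fallback, missing and
    filter cases."""
    return [
        ComplexPlan("cplx_pos1", 6, 12, (PlannedContact(1, 3, 4.0),)),
        ComplexPlan("cplx_pos2", 5, 10,
                    (PlannedContact(0, 0, 3.2), PlannedContact(2, 5, 4.8))),
        ComplexPlan("cplx_boundary", 6, 12, (PlannedContact(2, 4, 5.0),)),
        ComplexPlan("cplx_far", 6, 12, (PlannedContact(1, 2, 8.0),)),
        ComplexPlan("cplx_nearatom", 6, 12,
                    (PlannedContact(3, 6, 3.0, kind="nearest_atom"),)),
        ComplexPlan("cplx_nearatom_far", 6, 12,
                    (PlannedContact(3, 6, 6.5, kind="nearest_atom"),)),
        ComplexPlan("cplx_missing", 6, 12,
                    (PlannedContact(2, 3, 4.0, kind="missing_coords"),)),
        ComplexPlan("cplx_filtered", 10, 12, (PlannedContact(1, 3, 4.0),),
                    pep_nonstandard_fraction=0.3),
        ComplexPlan("cplx_borderline_std", 10, 12, (PlannedContact(1, 3, 4.0),),
                    pep_nonstandard_fraction=0.2),
        ComplexPlan("cplx_altloc", 6, 12, (PlannedContact(1, 3, 4.5),),
                    with_altloc=True),
    ]


# ---------------------------------------------------------------------------
# sequence families with controlled identity


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = [c for c in STANDARD_RESIDUES if c != ch]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def gen_sequence_families(
    n_families: int = 6,
    members_per_family: int = 5,
    within_identity: float = 0.9,
    between_identity: float = 0.3,
    length: int = 100,
    seed: int = 1234,
    role: str = "protein",
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Mutation-calibrated families: members share a founder, founders share
    an ancestor.

    The per-position substitution rate mu solves (1 - mu)^2 = target under
    the ungapped (position-wise) identity model, since two members are
    independent mutants of the same founder.  Gapped identity as measured
    by the clustering aligner is bounded below by this target; between
    unrelated sequences it additionally floors at the random-alignment
    background for a 20-letter alphabet.
    """
    if not 0.0 <= between_identity < within_identity <= 1.0:
        raise ValueError("need 0 <= between < within <= 1")
    rng = np.random.default_rng(seed)
    mu_within = 1.0 - math.sqrt(within_identity)
    mu_between = 1.0 - math.sqrt(max(between_identity, 1e-9))
    ancestor = _random_sequence(rng, length)
    records: list[SequenceRecord] = []
    families: dict[str, int] = {}
    for f in range(n_families):
        founder = _mutate(rng, ancestor, mu_between)
        for m in range(members_per_family):
            seq = founder if within_identity == 1.0 else _mutate(rng, founder, mu_within)
            sid = f"fam{f}_m{m}"
            records.append(SequenceRecord(sid, seq, role))
            families[sid] = f
    return records, families
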