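"""Greedy sequence clustering and cold-start train/test splits.

Peptides and proteins are clustered independently with a CD-HIT-style
greedy scheme: sequences sorted by descending length each join the first
existing cluster whose representative they match at or above the identity
threshold, otherwise they found a new cluster.  Identity is the number of
identically aligned positions of a global alignment divided by the length
of the shorter sequence (CD-HIT's denominator).  The scheme drops CD-HIT's
k-mer prefilter and banded-alignment heuristics but keeps the same
input/output contract.

Cold-start splits assign whole clusters to train or test so that no
cluster spans both sides: ``novel_peptides`` constrains peptide clusters,
``novel_proteins`` protein clusters, ``novel_pairs`` both (pairs whose two
cluster assignments straddle the sides are dropped and counted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .sequence_io import PairExample, SequenceRecord

SCENARIOS = ("novel_peptides", "novel_proteins", "novel_pairs")
CLUSTER_THRESHOLDS = (0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]
    threshold: float

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")


@dataclass(frozen=True)
class ColdStartSplit:
    scenario: str
    threshold: float
    train_pair_ids: tuple[str, ...]
    test_pair_ids: tuple[str, ...]
    dropped_pair_ids: tuple[str, ...] = ()


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = 0.0
    a.extend_gap_score = 0.0
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Identical aligned positions over the shorter sequence's length."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _ALIGNER.score(a, b)  # max attainable matches under this scoring
    return float(matches) / min(len(a), len(b))


def greedy_cluster(records: Sequence[SequenceRecord], threshold: float) -> list[Cluster]:
    """Incremental clustering against cluster representatives.

    Deterministic: records are processed in descending-length order with
    ties broken by id, and each joins the first (earliest-founded) cluster
    whose representative it matches at >= threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for i, rep in enumerate(reps):
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                members[i].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return [
        Cluster(representative=rep.id, members=tuple(m), threshold=threshold)
        for rep, m in zip(reps, members)
    ]


def cluster_index(clusters: Sequence[Cluster]) -> dict[str, int]:
    """Map each member id -> cluster ordinal."""
    out: dict[str, int] = {}
    for i, c in enumerate(clusters):
        for m in c.members:
            out[m] = i
    return out


def _pair_id(p: PairExample) -> str:
    return f"{p.peptide_id}|{p.protein_id}"


def make_coldstart_splits(
    pairs: Sequence[PairExample],
    peptide_clusters: Sequence[Cluster],
    protein_clusters: Sequence[Cluster],
    scenario: str,
    test_fraction: float = 0.2,
    seed: int = 1234,
) -> ColdStartSplit:
    """Assign whole clusters to train or test under the chosen scenario.

    Clusters of the constrained entity type are shuffled with the seed and
    accumulated into the test side until ~test_fraction of pairs is
    reached; for ``novel_pairs`` both entity types are constrained and
    pairs straddling the sides are dropped.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    pep_cluster = cluster_index(peptide_clusters)
    prot_cluster = cluster_index(protein_clusters)
    for p in pairs:
        if p.peptide_id not in pep_cluster:
            raise KeyError(f"peptide {p.peptide_id!r} missing from clustering")
        if p.protein_id not in prot_cluster:
            raise KeyError(f"protein {p.protein_id!r} missing from clustering")

    rng = np.random.default_rng(seed)

    def pick_test_clusters(clusters, pair_cluster_of):
        counts = np.zeros(len(clusters))
        for p in pairs:
            counts[pair_cluster_of(p)] += 1
        order = rng.permutation(len(clusters))
        target = test_fraction * len(pairs)
        picked, acc = set(), 0.0
        for ci in order:
            if acc >= target:
                break
            picked.add(int(ci))
            acc += counts[ci]
        return picked

    train, test, dropped = [], [], []
    if scenario == "novel_peptides":
        test_c = pick_test_clusters(peptide_clusters, lambda p: pep_cluster[p.peptide_id])
        for p in pairs:
            (test if pep_cluster[p.peptide_id] in test_c else train).append(_pair_id(p))
    elif scenario == "novel_proteins":
        test_c = pick_test_clusters(protein_clusters, lambda p: prot_cluster[p.protein_id])
        for p in pairs:
            (test if prot_cluster[p.protein_id] in test_c else train).append(_pair_id(p))
    else:  # novel_pairs
        test_pc = pick_test_clusters(peptide_clusters, lambda p: pep_cluster[p.peptide_id])
        test_qc = pick_test_clusters(protein_clusters, lambda p: prot_cluster[p.protein_id])
        for p in pairs:
            pep_test = pep_cluster[p.peptide_id] in test_pc
            prot_test = prot_cluster[p.protein_id] in test_qc
            if pep_test and prot_test:
                test.append(_pair_id(p))
            elif not pep_test and not prot_test:
                train.append(_pair_id(p))
            else:
                dropped.append(_pair_id(p))
    if not test or not train:
        raise ValueError(
            "empty train or test side; adjust test_fraction or the clustering threshold"
        )
    return ColdStartSplit(
        scenario=scenario,
        threshold=peptide_clusters[0].threshold if peptide_clusters else 0.0,
        train_pair_ids=tuple(train),
        test_pair_ids=tuple(test),
        dropped_pair_ids=tuple(dropped),
    )
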