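"""Alanine-scanning virtual screening.

Each peptide position is substituted with alanine, the mutant is
re-embedded with the same backend and normalization statistics as the
wild type, and the relative change in predicted binding probability,

    (P_wt - P_mut) / P_wt ,

quantifies that position's contribution to the interaction.  Positions
already occupied by alanine are scanned anyway and give a relative change
of exactly 0, so the output always covers positions 1..L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .embedding import SequenceEmbedding, apply_zscore, mean_pool, embed_batch
from .pair_graph import build_pair_graph, batch_graphs
from .network import forward_cached, sigmoid
from .sequence_io import SequenceRecord
from .training import TrainedModel

ALANINE = "A"


@dataclass(frozen=True)
class ScanResult:
    position: int  # 1-based
    wild_type_residue: str
    mutant_sequence: str
    p_wild_type: float
    p_mutant: float
    relative_change: float


def _predict_prob(model: TrainedModel, pep_vec: SequenceEmbedding,
                  prot_vec: SequenceEmbedding) -> float:
    pep = apply_zscore(pep_vec, model.stats)
    prot = apply_zscore(prot_vec, model.stats)
    batch = batch_graphs([build_pair_graph(pep, prot)])
    logits, _ = forward_cached(batch, model.params, model.model_config, training=False)
    return float(sigmoid(logits)[0])


def alanine_scan(
    peptide: SequenceRecord,
    protein: SequenceRecord,
    model: TrainedModel,
    embedder: Callable[[str], np.ndarray],
) -> list[ScanResult]:
    """Scan every peptide position; deterministic in evaluation mode."""
    seqs = [peptide.sequence]
    for i in range(len(peptide.sequence)):
        seqs.append(peptide.sequence[:i] + ALANINE + peptide.sequence[i + 1:])
    records = [SequenceRecord(id=f"scan{i}", sequence=s, role="peptide")
               for i, s in enumerate(seqs)]
    pooled = [mean_pool(m) for m in embed_batch(records, embedder)]
    prot_vec = mean_pool(embed_batch([protein], embedder)[0])

    p_wt = _predict_prob(model, pooled[0], prot_vec)
    if p_wt == 0.0:
        raise ValueError("wild-type binding probability is 0; relative change undefined")

    results = []
    for i, wt_res in enumerate(peptide.sequence, start=1):
        mutant_seq = seqs[i]
        if mutant_seq == peptide.sequence:
            p_mut, change = p_wt, 0.0  # alanine -> alanine: exact identity
        else:
            p_mut = _predict_prob(model, pooled[i], prot_vec)
            change = (p_wt - p_mut) / p_wt
        results.append(
            ScanResult(
                position=i,
                wild_type_residue=wt_res,
                mutant_sequence=mutant_seq,
                p_wild_type=p_wt,
                p_mutant=p_mut,
                relative_change=change,
            )
        )
    return results


def rank_positions(results: Sequence[ScanResult]) -> list[ScanResult]:
    """Descending by relative change; ties broken by ascending position."""
    if not results:
        raise ValueError("rank_positions on empty scan")
    return sorted(results, key=lambda r: (-r.relative_change, r.position))


def write_scan_table(results: Sequence[ScanResult], path) -> None:
    """TSV export of a scan."""
    with open(path, "w") as fh:
        fh.write("position\twild_type\tmutant_sequence\tp_wild_type\tp_mutant\trelative_change\n")
        for r in results:
            fh.write(
                f"{r.position}\t{r.wild_type_residue}\t{r.mutant_sequence}\t"
                f"{r.p_wild_type:.10g}\t{r.p_mutant:.10g}\t{r.relative_change:.10g}\n"
            )
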