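"""The 2-node peptide-protein pair graph and disjoint-union batching.

Each example is a graph with node 0 = peptide, node 1 = protein, joined by
the bidirectional edge index [[0,1],[1,0]].  Self-loops are *not* stored:
the graph-convolution operator adds them internally (its propagation matrix
is built from A + I), so the stored edge list stays exactly the printed
pair-graph structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import SequenceEmbedding

PAIR_EDGE_INDEX = np.array([[0, 1], [1, 0]], dtype=np.int64)


@dataclass(frozen=True)
class PairGraph:
    node_features: np.ndarray  # 2 x D; row 0 peptide, row 1 protein
    edge_index: np.ndarray  # 2 x n_edges, directed
    pair_id: str
    label: int | None = None

    def __post_init__(self):
        x = np.asarray(self.node_features, dtype=np.float64)
        if x.shape[0] != 2 or x.ndim != 2:
            raise ValueError(f"pair graph needs a 2 x D feature matrix, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{self.pair_id}: non-finite node features")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"{self.pair_id}: label must be 0/1 or None")
        object.__setattr__(self, "node_features", x)
        object.__setattr__(self, "edge_index", np.asarray(self.edge_index, dtype=np.int64))

    @property
    def dim(self) -> int:
        return self.node_features.shape[1]


@dataclass(frozen=True)
class GraphBatch:
    """Disjoint union of pair graphs."""

    node_features: np.ndarray  # (2*B) x D
    edge_index: np.ndarray  # 2 x (2*B), offset-shifted
    membership: np.ndarray  # node -> graph index, non-decreasing
    labels: np.ndarray  # per-graph label (-1 where absent)
    pair_ids: tuple[str, ...]

    @property
    def n_graphs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def build_pair_graph(
    pep: SequenceEmbedding, prot: SequenceEmbedding, label: int | None = None
) -> PairGraph:
    """Assemble the 2-node graph: peptide row first, bidirectional edges."""
    if pep.dim != prot.dim:
        raise ValueError(
            f"dimension mismatch: peptide {pep.dim} vs protein {prot.dim}"
        )
    return PairGraph(
        node_features=np.stack([pep.vector, prot.vector]),
        edge_index=PAIR_EDGE_INDEX.copy(),
        pair_id=f"{pep.seq_id}|{prot.seq_id}",
        label=label,
    )


def batch_graphs(graphs: Sequence[PairGraph]) -> GraphBatch:
    """Stack graphs with node-index offsets of 2 per preceding graph."""
    if not graphs:
        raise ValueError("cannot batch an empty graph list")
    dims = {g.dim for g in graphs}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions in batch: {sorted(dims)}")
    feats = np.concatenate([g.node_features for g in graphs])
    edges = np.concatenate(
        [g.edge_index + 2 * i for i, g in enumerate(graphs)], axis=1
    )
    membership = np.repeat(np.arange(len(graphs), dtype=np.int64), 2)
    labels = np.array(
        [g.label if g.label is not None else -1 for g in graphs], dtype=np.int64
    )
    return GraphBatch(
        node_features=feats,
        edge_index=edges,
        membership=membership,
        labels=labels,
        pair_ids=tuple(g.pair_id for g in graphs),
    )


def unbatch_graphs(batch: GraphBatch) -> list[PairGraph]:
    """Recover the original pair graphs from a batch."""
    out = []
    for i, pid in enumerate(batch.pair_ids):
        cols = (batch.edge_index // 2 == i).all(axis=0)
        out.append(
            PairGraph(
                node_features=batch.node_features[2 * i : 2 * i + 2].copy(),
                edge_index=batch.edge_index[:, cols] - 2 * i,
                pair_id=pid,
                label=None if batch.labels[i] < 0 else int(batch.labels[i]),
            )
        )
    return out
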