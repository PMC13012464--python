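"""Fixed-length sequence features: residue embedder, mean pooling, Z-score.

A residue-level embedder maps a sequence of length L to an L x D matrix
(D = 1024 for the pre-trained protein language-model backend).  Average
pooling over residues gives one D-vector per sequence,

    v_seq = (1/L) * sum_i v_i ,

which is then standardized per feature dimension with statistics fit on the
training split only.  A deterministic hashing embedder stands in for the
language model so every downstream stage is testable without model weights;
it satisfies the same contract (sequence string -> L x D finite matrix).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import h5py
import numpy as np

from .sequence_io import SequenceRecord, validate_sequence

DEFAULT_DIM = 1024
ZSCORE_EPS = 1e-8


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    """Per-residue feature matrix (L x D) for one sequence."""

    seq_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError(f"{self.seq_id}: expected L x D matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.seq_id}: non-finite entries in residue matrix")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SequenceEmbedding:
    """Pooled fixed-length feature vector for one sequence."""

    seq_id: str
    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"{self.seq_id}: embedding must be a vector")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.seq_id}: non-finite embedding entries")
        object.__setattr__(self, "vector", v)

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-dimension Z-score statistics, fit on training data only."""

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = ZSCORE_EPS
    fit_fingerprint: str = ""

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=np.float64)
        s = np.asarray(self.std, dtype=np.float64)
        if m.shape != s.shape or m.ndim != 1:
            raise ValueError("mean/std must be 1-D vectors of equal length")
        if np.any(s < 0):
            raise ValueError("standard deviations must be non-negative")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "std", s)


def mean_pool(m: ResidueEmbeddingMatrix) -> SequenceEmbedding:
    """Column-wise arithmetic mean of the residue rows.

    A constant matrix (all rows equal) pools to that row bit-exactly, which
    sum-then-divide cannot guarantee in floating point.
    """
    if np.all(m.values == m.values[0]):
        return SequenceEmbedding(seq_id=m.seq_id, vector=m.values[0].copy())
    return SequenceEmbedding(seq_id=m.seq_id, vector=m.values.mean(axis=0))


def fit_zscore(embs: Sequence[SequenceEmbedding], epsilon: float = ZSCORE_EPS) -> NormalizationStats:
    """Fit per-dimension mean and population standard deviation.

    Population (ddof=0) convention; requires at least two vectors.
    """
    if len(embs) < 2:
        raise ValueError("fit_zscore requires at least 2 vectors")
    dims = {e.dim for e in embs}
    if len(dims) != 1:
        raise ValueError(f"mixed embedding dimensions: {sorted(dims)}")
    x = np.stack([e.vector for e in embs])
    fingerprint = hashlib.sha256(
        ("|".join(sorted(e.seq_id for e in embs))).encode()
    ).hexdigest()[:16]
    return NormalizationStats(
        mean=x.mean(axis=0),
        std=x.std(axis=0, ddof=0),
        epsilon=epsilon,
        fit_fingerprint=fingerprint,
    )


def apply_zscore(e: SequenceEmbedding, s: NormalizationStats) -> SequenceEmbedding:
    """(x - mean) / (std + epsilon), per dimension."""
    if e.dim != s.mean.shape[0]:
        raise ValueError(
            f"{e.seq_id}: dimension {e.dim} does not match stats dimension {s.mean.shape[0]}"
        )
    return SequenceEmbedding(seq_id=e.seq_id, vector=(e.vector - s.mean) / (s.std + s.epsilon))


def _context_row(context: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}:{context}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


def hash_embed(
    seq: str, dim: int = DEFAULT_DIM, seed: int = 0, window: int = 1
) -> ResidueEmbeddingMatrix:
    """Deterministic residue embedder keyed on local k-mer context.

    Row i is a pseudo-random (but fully reproducible) Gaussian vector
    derived from the (2*window+1)-mer centred at position i, padded with
    '-' at the termini, and the seed.  Identical contexts give identical
    rows; distinct sequences give distinct pooled vectors with overwhelming
    probability.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    validate_sequence(seq)
    padded = "-" * window + seq + "-" * window
    cache: dict[str, np.ndarray] = {}
    rows = np.empty((len(seq), dim))
    for i in range(len(seq)):
        context = padded[i : i + 2 * window + 1]
        if context not in cache:
            cache[context] = _context_row(context, dim, seed)
        rows[i] = cache[context]
    return ResidueEmbeddingMatrix(seq_id="", values=rows)


class HashEmbedder:
    """Embedder-contract wrapper around hash_embed."""

    def __init__(self, dim: int = DEFAULT_DIM, seed: int = 0, window: int = 1):
        self.dim = dim
        self.seed = seed
        self.window = window

    def __call__(self, sequence: str) -> np.ndarray:
        return hash_embed(sequence, dim=self.dim, seed=self.seed, window=self.window).values


def embed_batch(
    records: Sequence[SequenceRecord], backend: Callable[[str], np.ndarray]
) -> list[ResidueEmbeddingMatrix]:
    """Apply a residue-level embedding backend to each record, in order.

    The backend contract is ``sequence string -> L x D finite matrix``.
    A pre-trained language-model adapter satisfies the same contract.
    """
    out: list[ResidueEmbeddingMatrix] = []
    for rec in records:
        try:
            values = np.asarray(backend(rec.sequence), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001 - re-raise with the id attached
            raise RuntimeError(f"embedding backend failed on {rec.id!r}: {exc}") from exc
        if values.shape[0] != len(rec.sequence):
            raise ValueError(
                f"{rec.id!r}: backend returned {values.shape[0]} rows for a "
                f"length-{len(rec.sequence)} sequence"
            )
        out.append(ResidueEmbeddingMatrix(seq_id=rec.id, values=values))
    return out


def pool_records(
    records: Sequence[SequenceRecord], backend: Callable[[str], np.ndarray]
) -> dict[str, SequenceEmbedding]:
    """Embed, pool and index a record collection by id."""
    return {
        m.seq_id: mean_pool(m) for m in embed_batch(records, backend)
    }


def save_embeddings(embs: Iterable[ResidueEmbeddingMatrix], path) -> None:
    """Write an id -> L x D matrix container (HDF5, one dataset per id)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "peppinet-residue-embeddings-v1"
        for m in embs:
            if not m.seq_id:
                raise ValueError("cannot save an embedding without a seq_id")
            f.create_dataset(m.seq_id, data=m.values)


def load_embeddings(path, ids: Sequence[str] | None = None) -> dict[str, ResidueEmbeddingMatrix]:
    """Load the container; restrict to *ids* if given (missing id -> KeyError)."""
    out: dict[str, ResidueEmbeddingMatrix] = {}
    with h5py.File(path, "r") as f:
        keys = list(f.keys()) if ids is None else list(ids)
        for key in keys:
            if key not in f:
                raise KeyError(f"embedding container has no entry for id {key!r}")
            out[key] = ResidueEmbeddingMatrix(seq_id=key, values=f[key][()])
    return out
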