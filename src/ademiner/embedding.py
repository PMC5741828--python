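"""Skip-gram word embeddings with negative sampling (SGNS).

The classifier represents every word as a dense vector trained so that
words sharing contexts end up close in cosine similarity. Training
maximizes, over (center, context) pairs within a symmetric window,

    log sigma(u_o . v_c) + sum_k E_{w_k ~ P_n} [log sigma(-u_k . v_c)]

where ``v_c`` is the center (input) vector, ``u_o`` the context (output)
vector and ``P_n`` the unigram distribution raised to the 3/4 power.

Hyperparameters follow the configuration that performed best in the
original study of this classifier family: 98-dimensional vectors,
minimum-word-frequency (MWF) pruning at 2% of the number of training
sentences, 25 epochs, context window 2, and 10 gradient iterations per
sentence mini-batch.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from . import _sgns

PathLike = Union[str, Path]

NEG_TABLE_SIZE = 1_000_000


@dataclass
class Hyperparameters:
    """Embedding training knobs.

    ``mwf_percent`` prunes rare words: the occurrence threshold is
    ``max(1, ceil(mwf_percent/100 * n_sentences))``. Set ``mwf_absolute``
    to use a fixed occurrence count instead. ``iterations`` (ITR) repeats
    the gradient pass over each sentence's (center, context) pairs;
    ``epochs`` (EP) are full corpus passes. The learning rate decays
    linearly from ``learning_rate`` to ``learning_rate / 100`` across all
    updates.
    """

    dim: int = 98
    mwf_percent: float = 2.0
    epochs: int = 25
    window: int = 2
    iterations: int = 10
    negative_samples: int = 5
    learning_rate: float = 0.025
    seed: int = 0
    mwf_absolute: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.epochs <= 0 or self.window < 1 or self.iterations <= 0:
            raise ValueError("dim, epochs, iterations must be positive; window >= 1")
        if not (0 < self.mwf_percent <= 100):
            raise ValueError("mwf_percent must lie in (0, 100]")
        if self.negative_samples <= 0 or self.learning_rate <= 0:
            raise ValueError("negative_samples and learning_rate must be positive")


@dataclass
class Vocabulary:
    token_to_index: Dict[str, int]
    counts: Dict[str, int]
    total_sentences: int

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def index_to_token(self) -> List[str]:
        out = [""] * len(self.token_to_index)
        for tok, idx in self.token_to_index.items():
            out[idx] = tok
        return out


@dataclass
class EmbeddingModel:
    vocab: Vocabulary
    vectors: np.ndarray  # |V| x dim, float32
    hyper: Hyperparameters

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vector row count must equal vocabulary size")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain NaN/Inf")


def mwf_threshold(hyper_or_percent, n_sentences: int) -> int:
    """Occurrence threshold implied by the MWF setting."""
    if isinstance(hyper_or_percent, Hyperparameters):
        if hyper_or_percent.mwf_absolute is not None:
            return max(1, int(hyper_or_percent.mwf_absolute))
        percent = hyper_or_percent.mwf_percent
    else:
        percent = float(hyper_or_percent)
    return max(1, math.ceil(percent / 100.0 * n_sentences))


def build_vocabulary(
    corpus: Sequence[Sequence[str]],
    mwf_percent: float = 2.0,
    mwf_absolute: Optional[int] = None,
) -> Vocabulary:
    """Count tokens and prune those below the MWF occurrence threshold.

    Indices are assigned by descending count (ties broken alphabetically)
    so the layout is deterministic regardless of dict iteration order.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts: Dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    threshold = (
        max(1, int(mwf_absolute))
        if mwf_absolute is not None
        else mwf_threshold(mwf_percent, len(corpus))
    )
    kept = {tok: c for tok, c in counts.items() if c >= threshold}
    if not kept:
        raise ValueError(
            f"all {len(counts)} tokens fall below the MWF threshold {threshold}; "
            "lower mwf_percent or supply mwf_absolute"
        )
    order = sorted(kept, key=lambda t: (-kept[t], t))
    return Vocabulary(
        token_to_index={tok: i for i, tok in enumerate(order)},
        counts=kept,
        total_sentences=len(corpus),
    )


def _negative_table(vocab: Vocabulary, size: int = NEG_TABLE_SIZE) -> np.ndarray:
    tokens = vocab.index_to_token
    weights = np.array([vocab.counts[t] for t in tokens], dtype=np.float64) ** 0.75
    cum = np.cumsum(weights / weights.sum())
    positions = (np.arange(size) + 0.5) / size
    return np.searchsorted(cum, positions).astype(np.int32)


def _encode(corpus: Sequence[Sequence[str]], vocab: Vocabulary):
    data: List[int] = []
    offsets = [0]
    t2i = vocab.token_to_index
    for sent in corpus:
        ids = [t2i[tok] for tok in sent if tok in t2i]
        data.extend(ids)
        offsets.append(len(data))
    return np.asarray(data, dtype=np.int32), np.asarray(offsets, dtype=np.int64)


def train_skipgram(
    corpus: Sequence[Sequence[str]],
    hyper: Hyperparameters = Hyperparameters(),
    vocab: Optional[Vocabulary] = None,
) -> EmbeddingModel:
    """Train SGNS vectors; deterministic for a fixed seed and corpus order.

    Out-of-vocabulary (MWF-pruned) tokens are removed from sentences before
    pair generation, so surviving words that were separated only by rare
    words become contiguous — the standard word2vec behavior.
    """
    if vocab is None:
        vocab = build_vocabulary(corpus, hyper.mwf_percent, hyper.mwf_absolute)
    data, offsets = _encode(corpus, vocab)
    if data.shape[0] < 2:
        raise ValueError("corpus too small: fewer than two in-vocabulary tokens")
    rng = np.random.default_rng(hyper.seed)
    dim = hyper.dim
    syn0 = ((rng.random((len(vocab), dim), dtype=np.float64) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((len(vocab), dim), dtype=np.float32)
    neg_table = _negative_table(vocab)
    _sgns.train_epochs(
        data,
        offsets,
        syn0,
        syn1,
        neg_table,
        hyper.epochs,
        hyper.window,
        hyper.iterations,
        hyper.negative_samples,
        hyper.learning_rate,
        hyper.learning_rate / 100.0,
        _sgns.exp_table(),
        np.uint64(hyper.seed * 2654435761 % (2**63) + 88172645463325252),
    )
    return EmbeddingModel(vocab=vocab, vectors=syn0, hyper=hyper)


def word_vector(model: EmbeddingModel, token: str) -> Optional[np.ndarray]:
    """Vector for an in-vocabulary token, or ``None`` for OOV (not an error)."""
    idx = model.vocab.token_to_index.get(token)
    if idx is None:
        return None
    return model.vectors[idx]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized dot product in [-1, 1]; a zero vector gives similarity 0."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Persistence: vocabulary TSV + .npy matrix + JSON hyperparameter sidecar
# ---------------------------------------------------------------------------

def save_model(model: EmbeddingModel, directory: PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with (d / "vocab.tsv").open("w", encoding="utf-8") as fh:
        for tok in model.vocab.index_to_token:
            fh.write(f"{tok}\t{model.vocab.counts[tok]}\n")
    np.save(d / "vectors.npy", model.vectors)
    sidecar = {
        "format_version": 1,
        "total_sentences": model.vocab.total_sentences,
        "hyperparameters": asdict(model.hyper),
    }
    (d / "model.json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")


def load_model(directory: PathLike) -> EmbeddingModel:
    d = Path(directory)
    sidecar = json.loads((d / "model.json").read_text(encoding="utf-8"))
    token_to_index: Dict[str, int] = {}
    counts: Dict[str, int] = {}
    with (d / "vocab.tsv").open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            tok, cnt = line.rstrip("\n").split("\t")
            token_to_index[tok] = i
            counts[tok] = int(cnt)
    vocab = Vocabulary(token_to_index, counts, sidecar["total_sentences"])
    vectors = np.load(d / "vectors.npy")
    hyper = Hyperparameters(**sidecar["hyperparameters"])
    return EmbeddingModel(vocab=vocab, vectors=vectors, hyper=hyper)
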