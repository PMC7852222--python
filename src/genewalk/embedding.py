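"""Skip-gram negative-sampling node embeddings (the word2vec stage).

Walks play the role of sentences; nodes, of words. With window size 1 only
directly adjacent walk positions form training pairs, i.e. only node pairs
joined by a GWN edge ever appear as (input, output) examples. The loss per
pair (w_I, w_O) is the standard SGNS objective

    log sigma(v'_{w_O} . v_{w_I}) + sum_{i=1..k} E_{w_i ~ P_noise}
        [log sigma(-v'_{w_i} . v_{w_I})]

with P_noise(w) proportional to U(w)^{3/4} (U the corpus unigram
distribution), k negative samples, no downsampling and no minimum count.
The input vectors v are the node representations used downstream.

Training is plain sequential SGD over the pair stream with a linearly
decaying learning rate, compiled with numba for speed; it is bit-reproducible
for a fixed seed (single worker, sequential updates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .walks import WalkCorpus


@dataclass
class TrainingConfig:
    """Hyperparameters of the skip-gram model.

    Defaults follow the method's published settings: 8-dimensional vectors,
    context window 1, k = 5 negative samples, no frequent-word downsampling
    (sample = 0), min_count = 0. Epochs and the learning rate are free
    parameters; the defaults are a single gentle pass (epochs = 1,
    alpha 0.005 -> 1e-4). The corpus already repeats every neighborhood
    n_iteration = 100 times, so one pass performs ~1800 updates per edge
    direction; training much past that point converges toward an edge-local
    equilibrium that erodes the mesoscale (community) similarity signal the
    method relies on, while a gentle single pass acts like an early-stopped,
    diffusion-smoothed factorization.
    """

    dim_rep: int = 8
    window: int = 1
    k_neg: int = 5
    sample: float = 0.0
    min_count: int = 0
    epochs: int = 1
    alpha: float = 0.005
    min_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.dim_rep < 2:
            raise ValueError("dim_rep must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.k_neg < 1:
            raise ValueError("k_neg must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class EmbeddingTable:
    """Mapping node -> embedding vector, with cosine-similarity lookups."""

    def __init__(self, nodes: list, vectors: np.ndarray):
        self.nodes = list(nodes)
        self.vectors = vectors
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def __contains__(self, node) -> bool:
        return node in self._index

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node) -> np.ndarray:
        return self.vectors[self._index[node]]

    def similarity(self, a, b) -> float:
        """Cosine similarity between the vectors of two nodes."""
        return cosine_similarity(self.vector(a), self.vector(b))

    def similarities(self, pairs) -> np.ndarray:
        """Vectorized cosine similarity for an iterable of node pairs."""
        idx = np.array([[self._index[a], self._index[b]] for a, b in pairs])
        if idx.size == 0:
            return np.empty(0)
        norms = np.linalg.norm(self.vectors, axis=1)
        u, v = idx[:, 0], idx[:, 1]
        return np.einsum("ij,ij->i", self.vectors[u], self.vectors[v]) / (
            norms[u] * norms[v]
        )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), defined only for non-zero vectors of equal length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


@njit(cache=False)
def _sgns_epoch(syn0, syn1, centers, contexts, negatives, k_neg,
                step0, total_steps, alpha, min_alpha):
    dim = syn0.shape[1]
    n_pairs = centers.shape[0]
    work = np.empty(dim, dtype=np.float32)
    for i in range(n_pairs):
        frac = (step0 + i) / total_steps
        lr = np.float32(alpha + (min_alpha - alpha) * frac)
        c = centers[i]
        for d in range(dim):
            work[d] = 0.0
        for s in range(k_neg + 1):
            if s == 0:
                t = contexts[i]
                label = np.float32(1.0)
            else:
                t = negatives[i * k_neg + s - 1]
                if t == contexts[i]:
                    continue
                label = np.float32(0.0)
            dot = np.float32(0.0)
            for d in range(dim):
                dot += syn0[c, d] * syn1[t, d]
            f = np.float32(1.0) / (np.float32(1.0) + np.exp(-dot))
            g = (label - f) * lr
            for d in range(dim):
                work[d] += g * syn1[t, d]
                syn1[t, d] += g * syn0[c, d]
        for d in range(dim):
            syn0[c, d] += work[d]


def _training_pairs(corpus: WalkCorpus, window: int):
    """All (center, context) index pairs within the window, both directions."""
    cs, os = [], []
    for off in range(1, window + 1):
        left = corpus.walks[:, :-off].ravel()
        right = corpus.walks[:, off:].ravel()
        cs.append(left)
        os.append(right)
        cs.append(right)
        os.append(left)
    return np.concatenate(cs), np.concatenate(os)


def train_embeddings(corpus: WalkCorpus, config: TrainingConfig) -> EmbeddingTable:
    """Train SGNS vectors on a walk corpus.

    Returns one vector per node that appears in at least one walk (with walks
    started from every non-isolated node this is exactly the set of nodes
    with d >= 1). Reproducible bit-for-bit for a fixed config.seed.
    """
    if corpus.n_walks == 0:
        raise ValueError("empty walk corpus")
    rng = np.random.default_rng(config.seed)

    counts = np.bincount(corpus.walks.ravel(), minlength=len(corpus.nodes))
    vocab_mask = counts > 0
    # compact vocabulary (nodes never walked get no vector)
    compact = np.cumsum(vocab_mask) - 1
    vocab_nodes = [n for n, m in zip(corpus.nodes, vocab_mask) if m]
    V = len(vocab_nodes)

    centers, contexts = _training_pairs(corpus, config.window)
    centers = compact[centers].astype(np.int32)
    contexts = compact[contexts].astype(np.int32)

    noise = counts[vocab_mask].astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    syn0 = ((rng.random((V, config.dim_rep)) - 0.5) / config.dim_rep).astype(
        np.float32
    )
    syn1 = np.zeros((V, config.dim_rep), dtype=np.float32)

    n_pairs = centers.shape[0]
    total_steps = n_pairs * config.epochs
    for epoch in range(config.epochs):
        negatives = np.searchsorted(
            noise_cdf, rng.random(n_pairs * config.k_neg)
        ).astype(np.int32)
        _sgns_epoch(
            syn0, syn1, centers, contexts, negatives, config.k_neg,
            epoch * n_pairs, total_steps, config.alpha, config.min_alpha,
        )

    if not np.all(np.isfinite(syn0)):
        raise FloatingPointError("non-finite embedding values after training")
    return EmbeddingTable(vocab_nodes, syn0)
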