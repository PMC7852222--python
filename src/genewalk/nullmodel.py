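"""Randomized-network null distribution and empirical p-values.

Significance of an observed gene-GO cosine similarity is judged against
similarities arising in degree-matched random networks: the GWN's edges are
rewired by configuration-model stub matching (every node keeps its degree),
the rewired network is embedded with exactly the same walk and training
procedure as the real one, and the cosine similarities of every node with
each of its neighbors are pooled over nreps_null independent randomizations.
The p-value of an observed similarity is its normalized rank in this pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .embedding import TrainingConfig, train_embeddings
from .walks import sample_walks


@dataclass
class PipelineConfig:
    """Run-level settings: repeat counts, FDR threshold, base seed.

    nreps_graph embedding repeats of the real GWN quantify stochastic
    training variability; nreps_null randomized networks populate the null.
    Defaults are the method's full setting (10/10); ``fast()`` gives the
    reduced 3/3 setting used for quicker runs.
    """

    nreps_graph: int = 10
    nreps_null: int = 10
    fdr_alpha: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if self.nreps_graph < 1 or self.nreps_null < 1:
            raise ValueError("repeat counts must be >= 1")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")

    @classmethod
    def fast(cls, seed: int = 42, fdr_alpha: float = 0.1) -> "PipelineConfig":
        return cls(nreps_graph=3, nreps_null=3, fdr_alpha=fdr_alpha, seed=seed)


@dataclass
class NullDistribution:
    """Pooled cosine similarities from randomized networks, sorted ascending."""

    values: np.ndarray
    n_source_networks: int

    def __len__(self) -> int:
        return self.values.size


def configuration_stub_pairs(gwn: nx.Graph, rng: np.random.Generator):
    """Degree-preserving stub matching: returns the raw rewired edge pairs.

    Every edge contributes one stub to each endpoint; a random perfect
    matching of the stubs yields a multigraph in which every node has exactly
    its original degree. Self-loops and parallel edges are *not* removed
    here; :func:`randomize_network` cleans them up.
    """
    nodes = sorted(gwn.nodes, key=str)
    degrees = np.array([gwn.degree(n) for n in nodes], dtype=np.int64)
    stubs = np.repeat(np.arange(len(nodes)), degrees)
    rng.shuffle(stubs)
    half = stubs.size // 2
    return nodes, stubs[:half], stubs[half:]


def randomize_network(gwn: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Configuration-model rewiring of the full GWN edge set.

    The node set is unchanged and the pre-cleanup degree sequence equals the
    input's exactly; self-loops are then removed and parallel edges collapsed
    because the walk sampler requires a simple graph (a slight, monitored
    degree distortion).
    """
    out = nx.Graph()
    out.add_nodes_from(gwn.nodes(data=True))
    if gwn.number_of_edges() == 0:
        return out
    nodes, left, right = configuration_stub_pairs(gwn, rng)
    for i, j in zip(left, right):
        if i != j:
            out.add_edge(nodes[i], nodes[j])
    return out


def neighbor_similarities(gwn: nx.Graph, embeddings) -> np.ndarray:
    """Cosine similarity of every (node, neighbor) pair with vectors.

    Each edge contributes twice (once from each endpoint's neighbor list),
    mirroring how the per-node neighbor scan populates the null.
    """
    pairs = [
        (n, m)
        for n in gwn.nodes
        if n in embeddings
        for m in gwn.neighbors(n)
        if m in embeddings
    ]
    return embeddings.similarities(pairs)


def build_null(
    gwn: nx.Graph,
    config: PipelineConfig,
    training: TrainingConfig,
    L: int = 10,
    n_iteration: int = 100,
) -> NullDistribution:
    """Pool neighbor cosine similarities over nreps_null randomized networks.

    Each replicate gets the derived seed ``config.seed + replicate_index``
    for rewiring, walk sampling and training.
    """
    if gwn.number_of_edges() == 0:
        raise ValueError("cannot build a null distribution on an edgeless graph")
    pooled = []
    for j in range(config.nreps_null):
        rep_seed = config.seed + j
        rng = np.random.default_rng(rep_seed)
        random_net = randomize_network(gwn, rng)
        corpus = sample_walks(random_net, L=L, n_iteration=n_iteration,
                              seed=rep_seed)
        tcfg = TrainingConfig(
            dim_rep=training.dim_rep, window=training.window,
            k_neg=training.k_neg, sample=training.sample,
            min_count=training.min_count, epochs=training.epochs,
            alpha=training.alpha, min_alpha=training.min_alpha,
            seed=rep_seed,
        )
        emb = train_embeddings(corpus, tcfg)
        pooled.append(neighbor_similarities(random_net, emb))
    values = np.sort(np.concatenate(pooled))
    return NullDistribution(values=values, n_source_networks=config.nreps_null)


def p_value(similarity: float, null: NullDistribution) -> float:
    """Normalized rank of a similarity in the null: (1 + #{null >= s}) / (1 + N).

    The add-one convention keeps p strictly positive and counts ties against
    significance, as in standard permutation testing.
    """
    n = len(null)
    if n == 0:
        raise ValueError("empty null distribution")
    n_ge = n - int(np.searchsorted(null.values, similarity, side="left"))
    return (1 + n_ge) / (1 + n)


def p_values(similarities: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Vectorized :func:`p_value`."""
    n = len(null)
    if n == 0:
        raise ValueError("empty null distribution")
    n_ge = n - np.searchsorted(null.values, similarities, side="left")
    return (1 + n_ge) / (1 + n)
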