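"""Short random walks over the GWN (the DeepWalk sampling stage).

From every node n with degree d(n) >= 1 we start d(n) walks of L nodes, and
repeat the whole sweep n_iteration times, so the corpus holds exactly
n_iteration * sum_n d(n) walks. Each step jumps to a uniformly chosen
neighbor (probability 1/d of the current node). Starting d(n) walks per node
makes frequently connected nodes proportionally frequent walk origins, which
is what lets the downstream skip-gram model weight hub neighborhoods
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class WalkCorpus:
    """Sampled walk corpus in index space.

    ``walks[i, j]`` is the index (into ``nodes``) of the j-th node of walk i.
    """

    walks: np.ndarray          # (n_walks, L) int32
    nodes: list                # index -> node label, sorted for determinism
    L: int
    n_iteration: int

    @property
    def n_walks(self) -> int:
        return self.walks.shape[0]

    def iter_walks(self):
        """Yield walks as lists of node labels (for dumps/debugging)."""
        for row in self.walks:
            yield [self.nodes[i] for i in row]

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            for walk in self.iter_walks():
                fh.write(" ".join(str(n) for n in walk) + "\n")


def _csr_adjacency(gwn: nx.Graph):
    """Sorted-node CSR adjacency; sorting decouples walks from insertion order."""
    nodes = sorted(gwn.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    degrees = np.array([gwn.degree(n) for n in nodes], dtype=np.int64)
    ptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    np.cumsum(degrees, out=ptr[1:])
    neighbors = np.empty(int(ptr[-1]), dtype=np.int32)
    for i, n in enumerate(nodes):
        nbrs = sorted((index[m] for m in gwn.neighbors(n)))
        neighbors[ptr[i]:ptr[i + 1]] = nbrs
    return nodes, degrees, ptr, neighbors


def sample_walks(
    gwn: nx.Graph,
    L: int = 10,
    n_iteration: int = 100,
    seed: int | None = None,
) -> WalkCorpus:
    """Sample the full DeepWalk corpus for a GWN.

    Deterministic given (gwn, L, n_iteration, seed). Isolated nodes (d=0)
    start no walks and therefore get no embedding vector downstream.
    """
    if L < 2:
        raise ValueError(f"walk length L must be >= 2, got {L}")
    if n_iteration < 1:
        raise ValueError("n_iteration must be >= 1")
    nodes, degrees, ptr, neighbors = _csr_adjacency(gwn)
    if neighbors.size == 0:
        import warnings

        warnings.warn("graph has no edges; empty walk corpus")
        return WalkCorpus(np.empty((0, L), dtype=np.int32), nodes, L, n_iteration)

    rng = np.random.default_rng(seed)
    starts_once = np.repeat(
        np.arange(len(nodes), dtype=np.int32), degrees
    )  # each node d(n) times
    starts = np.tile(starts_once, n_iteration)
    n_walks = starts.size

    walks = np.empty((n_walks, L), dtype=np.int32)
    walks[:, 0] = starts
    cur = starts.astype(np.int64)
    for step in range(1, L):
        # uniform neighbor choice: offset into the CSR row of each current node
        offsets = (rng.random(n_walks) * degrees[cur]).astype(np.int64)
        cur = neighbors[ptr[cur] + offsets].astype(np.int64)
        walks[:, step] = cur
    return WalkCorpus(walks, nodes, L, n_iteration)
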