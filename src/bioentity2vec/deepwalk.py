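"""Node behavior representation by DeepWalk.

Behavior features describe a bioentity by its connectivity pattern: short
uniform random walks over the (test-edge-stripped) training graph are
treated as sentences and fed to a SkipGram word-embedding model, yielding a
64-dimensional vector per vertex.  Defaults follow the common DeepWalk
settings: window w=10, walk length t=80, walks per vertex gamma=10,
dimension d=64.

Nodes that never appear in the corpus (isolated after stripping, or brand
new) receive the zero vector, which is the cold-start representation fused
downstream with the node's attribute vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from ._word2vec import _sgns_kernel, _walk_kernel, build_noise_table
from .graph import HeteroGraph

DIM = 64
WINDOW = 10
WALK_LENGTH = 80
WALKS_PER_VERTEX = 10
SGNS_EPOCHS = 5
NEGATIVE = 5


@dataclass
class WalkCorpus:
    """A bag of truncated random walks (node-id sequences)."""

    walks: list[list[str]]
    walk_length: int
    walks_per_vertex: int

    def __len__(self) -> int:
        return len(self.walks)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w in self.walks:
                fh.write(" ".join(w) + "\n")

    @classmethod
    def load(cls, path: str | Path, walk_length: int, walks_per_vertex: int) -> "WalkCorpus":
        walks = [
            line.split()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return cls(walks, walk_length, walks_per_vertex)


def _csr(graph: HeteroGraph, order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = {nid: i for i, nid in enumerate(order)}
    indptr = np.zeros(len(order) + 1, dtype=np.int64)
    nbrs_sorted = []
    for i, nid in enumerate(order):
        nb = sorted(graph.neighbors(nid))
        nbrs_sorted.append([idx[x] for x in nb])
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.fromiter(
        (j for nb in nbrs_sorted for j in nb), dtype=np.int32, count=int(indptr[-1])
    )
    return indptr, indices


def generate_walks(
    graph: HeteroGraph,
    gamma: int = WALKS_PER_VERTEX,
    t: int = WALK_LENGTH,
    seed: int = 0,
) -> WalkCorpus:
    """Run gamma passes of uniform truncated random walks.

    Per pass the vertex order is shuffled and one walk of length ``t`` is
    started from every vertex; the next vertex is drawn uniformly from the
    current vertex's neighbors.  An isolated start yields the single-vertex
    walk.  The corpus therefore holds exactly gamma * |V| walks and every
    consecutive pair in every walk is an edge of ``graph``.
    """
    if t < 1 or gamma < 1:
        raise ValueError("t and gamma must be >= 1")
    order = graph.node_ids
    if not order:
        raise ValueError("empty graph")
    indptr, indices = _csr(graph, order)
    rng = np.random.default_rng(seed)
    starts = np.concatenate([rng.permutation(len(order)) for _ in range(gamma)]).astype(np.int32)
    raw = _walk_kernel(indptr, indices, starts, t, int(seed) % (2**31 - 1))
    walks = []
    for row in raw:
        stop = np.argmax(row < 0) if (row < 0).any() else len(row)
        walks.append([order[j] for j in row[: stop if stop else len(row)]])
    return WalkCorpus(walks, t, gamma)


def train_skipgram(
    corpus: WalkCorpus,
    d: int = DIM,
    w: int = WINDOW,
    seed: int = 0,
    epochs: int = SGNS_EPOCHS,
    negative: int = NEGATIVE,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> dict[str, np.ndarray]:
    """Learn d-dimensional vertex vectors from the walk corpus.

    SkipGram with negative sampling: each vertex occurrence predicts the
    vertices within a window of +-w positions; training is single-threaded
    and reproducible under ``seed``.  Every vertex occurring in the corpus
    gets a vector (min-count 0).
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({v for walk in corpus.walks for v in walk})
    index = {v: i for i, v in enumerate(vocab)}
    n = len(vocab)

    max_len = max(len(w_) for w_ in corpus.walks)
    walks = np.zeros((len(corpus.walks), max_len), dtype=np.int32)
    lengths = np.zeros(len(corpus.walks), dtype=np.int32)
    counts = np.zeros(n, dtype=np.int64)
    for i, walk in enumerate(corpus.walks):
        lengths[i] = len(walk)
        for j, v in enumerate(walk):
            walks[i, j] = index[v]
            counts[index[v]] += 1

    rng = np.random.default_rng(seed)
    syn0 = ((rng.random((n, d)) - 0.5) / d).astype(np.float32)
    syn1 = np.zeros((n, d), dtype=np.float32)
    table = build_noise_table(counts)
    _sgns_kernel(
        walks, lengths, syn0, syn1, table, w, negative,
        alpha, min_alpha, epochs, int(seed) % (2**31 - 1),
    )
    return {v: syn0[index[v]].astype(np.float64) for v in vocab}


def behavior_vectors(
    graph_train: HeteroGraph,
    gamma: int = WALKS_PER_VERTEX,
    t: int = WALK_LENGTH,
    d: int = DIM,
    w: int = WINDOW,
    seed: int = 0,
    epochs: int = SGNS_EPOCHS,
) -> dict[str, np.ndarray]:
    """Full behavior pipeline on an already-stripped training graph.

    Walk generation followed by SkipGram; every node of the graph gets a
    vector, with the zero vector for nodes absent from the corpus
    vocabulary's connected part (degree-0 nodes appear only as singleton
    walks, which carry no context — they still get their learned-from-init
    vector zeroed for a clean cold-start contract).
    """
    corpus = generate_walks(graph_train, gamma=gamma, t=t, seed=seed)
    table = train_skipgram(corpus, d=d, w=w, seed=seed, epochs=epochs)
    out: dict[str, np.ndarray] = {}
    for nid in graph_train.node_ids:
        if graph_train.degree(nid) == 0:
            out[nid] = np.zeros(d)
        else:
            out[nid] = table[nid]
    return out


def save_embeddings(table: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Persist in word2vec text format: header "n d", then one node per line."""
    ids = sorted(table)
    d = len(next(iter(table.values()))) if table else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(ids)} {d}\n")
        for nid in ids:
            vec = " ".join(f"{x:.8g}" for x in table[nid])
            fh.write(f"{nid} {vec}\n")


def load_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    n, d = (int(x) for x in lines[0].split())
    out: dict[str, np.ndarray] = {}
    for line in lines[1 : n + 1]:
        parts = line.split()
        out[parts[0]] = np.asarray([float(x) for x in parts[1 : d + 1]])
    return out
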