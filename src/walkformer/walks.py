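"""Random-walk sentence generation and tokenization.

Each network is converted into a corpus of node sequences ("sentences") by
first-order random walks that step to a neighbor with probability
proportional to the connecting edge weight. Walk length counts nodes, so a
length-10 walk carries 10 tokens before the [CLS] token is prepended.

Two corpus-size conventions are supported. ``per_network`` emits
``reps`` walks from every node with positive degree in every network.
``per_union_node`` (the default) emits exactly ``reps`` walks per vocabulary
node — each drawn from a uniformly chosen network containing that node — so
the corpus size is exactly ``reps * n`` regardless of how much the networks
overlap. A node isolated in every network yields singleton walks, which are
right-padded with [PAD] at tokenization so no vocabulary node goes
unrepresented.

Randomness uses the counter-based Philox generator: all transition uniforms
are derived from the master seed as one matrix indexed by (walk, step), so
the corpus is reproducible independently of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .networks import Network, NetworkCollection, NodeVocabulary

__all__ = [
    "Walk",
    "WalkCorpus",
    "TokenizedSequence",
    "sample_walk",
    "generate_corpus",
    "tokenize_sequence",
    "tokenize_corpus",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class Walk:
    """An ordered node-id sequence sampled from one source network."""

    node_ids: tuple[int, ...]
    source_network: int

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass
class WalkCorpus:
    walks: list[Walk]
    reps_per_node: int
    walk_length: int
    seed: int

    def __len__(self) -> int:
        return len(self.walks)


@dataclass(frozen=True)
class TokenizedSequence:
    """[CLS]-prefixed, [PAD]-completed integer token sequence."""

    token_ids: tuple[int, ...]
    positions: tuple[int, ...]
    mask_flags: tuple[bool, ...]
    original_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.token_ids)


class _RowSampler:
    """Vectorized weighted-neighbor sampling from a CSR adjacency.

    For current nodes ``u`` and uniforms ``r`` the next nodes are found by a
    single searchsorted against the global cumulative sum of the CSR data,
    offset to each row — no Python-level per-walk loop.
    """

    def __init__(self, A: sp.csr_matrix):
        self.indptr = A.indptr
        self.indices = A.indices
        self.cum = np.cumsum(A.data)
        # base[u] = cumulative mass before row u (0 where the row starts at 0)
        starts = A.indptr[:-1]
        self.base = np.where(starts > 0, self.cum[np.maximum(starts - 1, 0)], 0.0)
        self.rowsum = np.asarray(A.sum(axis=1)).ravel()

    def step(self, current: np.ndarray, uniforms: np.ndarray) -> np.ndarray:
        target = self.base[current] + uniforms * self.rowsum[current]
        pos = np.searchsorted(self.cum, target, side="right")
        pos = np.clip(pos, self.indptr[current], self.indptr[current + 1] - 1)
        return self.indices[pos]


def sample_walk(
    network: Network, start: int, length: int, rng: np.random.Generator
) -> Walk:
    """One weight-biased walk of exactly ``length`` nodes starting at ``start``."""
    if length < 1:
        raise ValueError("walk length must be >= 1")
    if not network.present[start]:
        raise ValueError(f"node id {start} has degree 0 in network {network.name!r}")
    sampler = _RowSampler(network.A)
    ids = np.empty(length, dtype=np.int64)
    ids[0] = start
    for step in range(1, length):
        ids[step] = sampler.step(ids[step - 1 : step], rng.random(1))[0]
    net_index = getattr(network, "_collection_index", 0)
    return Walk(node_ids=tuple(int(i) for i in ids), source_network=net_index)


def _batch_walks(
    sampler: _RowSampler, starts: np.ndarray, length: int, uniforms: np.ndarray
) -> np.ndarray:
    """Walks for many starts at once; ``uniforms`` is (n_walks, length-1)."""
    out = np.empty((len(starts), length), dtype=np.int64)
    out[:, 0] = starts
    for step in range(1, length):
        out[:, step] = sampler.step(out[:, step - 1], uniforms[:, step - 1])
    return out


def generate_corpus(
    collection: NetworkCollection,
    reps: int = 10,
    length: int = 10,
    corpus_mode: str = "per_union_node",
    seed: int = 0,
) -> WalkCorpus:
    """Sample the walk corpus for a network collection.

    ``per_union_node``: ``reps`` walks per vocabulary node, each from a
    uniformly chosen network where the node has positive degree (singleton
    walks if it has none anywhere); corpus size is exactly ``reps * n``.
    ``per_network``: ``reps`` walks per (network, present node) pair.
    The finished corpus is shuffled with the same seed.
    """
    if reps < 1 or length < 1:
        raise ValueError("reps and length must be >= 1")
    if corpus_mode not in ("per_union_node", "per_network"):
        raise ValueError(f"unknown corpus_mode {corpus_mode!r}")
    if not any(net.present.any() for net in collection):
        raise ValueError("no network contains a node with positive degree")

    ss = np.random.SeedSequence(seed)
    key_walks, key_choice, key_shuffle = [int(c.generate_state(1)[0]) for c in ss.spawn(3)]
    samplers = [_RowSampler(net.A) for net in collection]

    # (start node, source network) per walk, in deterministic construction order
    starts: list[int] = []
    sources: list[int] = []
    n = collection.vocab.n
    if corpus_mode == "per_union_node":
        presence = np.stack([net.present for net in collection])  # T x n
        choice_rng = np.random.Generator(np.random.Philox(key=key_choice))
        for node in range(n):
            nets = np.flatnonzero(presence[:, node])
            for _ in range(reps):
                if nets.size == 0:
                    starts.append(node)
                    sources.append(-1)  # isolated everywhere: singleton walk
                else:
                    starts.append(node)
                    sources.append(int(nets[choice_rng.integers(nets.size)]))
    else:
        for t, net in enumerate(collection):
            for node in np.flatnonzero(net.present):
                for _ in range(reps):
                    starts.append(int(node))
                    sources.append(t)

    n_walks = len(starts)
    starts_arr = np.asarray(starts, dtype=np.int64)
    sources_arr = np.asarray(sources, dtype=np.int64)
    walk_rng = np.random.Generator(np.random.Philox(key=key_walks))
    uniforms = walk_rng.random((n_walks, max(length - 1, 1)))

    node_seqs: list[tuple[int, ...]] = [()] * n_walks
    for t in range(-1, collection.T):
        sel = np.flatnonzero(sources_arr == t)
        if sel.size == 0:
            continue
        if t == -1:
            for w in sel:
                node_seqs[w] = (int(starts_arr[w]),)
            continue
        seqs = _batch_walks(samplers[t], starts_arr[sel], length, uniforms[sel])
        for w, row in zip(sel, seqs):
            node_seqs[w] = tuple(int(v) for v in row)

    walks = [
        Walk(node_ids=node_seqs[w], source_network=int(sources_arr[w]) if sources_arr[w] >= 0 else -1)
        for w in range(n_walks)
    ]
    shuffle_rng = np.random.Generator(np.random.Philox(key=key_shuffle))
    order = shuffle_rng.permutation(n_walks)
    walks = [walks[i] for i in order]
    return WalkCorpus(walks=walks, reps_per_node=reps, walk_length=length, seed=seed)


def tokenize_sequence(walk: Walk, vocab: NodeVocabulary, pad_to: int | None = None) -> TokenizedSequence:
    """Prepend [CLS], right-pad with [PAD] up to ``pad_to`` walk tokens."""
    if len(walk) == 0:
        raise ValueError("cannot tokenize an empty walk")
    for i in walk.node_ids:
        if not (0 <= i < vocab.n):
            raise ValueError(f"node id {i} outside vocabulary range [0, {vocab.n})")
    ids = [vocab.cls_id, *walk.node_ids]
    if pad_to is not None:
        if len(walk) > pad_to:
            raise ValueError(f"walk of length {len(walk)} exceeds pad_to={pad_to}")
        ids.extend([vocab.pad_id] * (pad_to - len(walk)))
    L = len(ids)
    return TokenizedSequence(
        token_ids=tuple(ids),
        positions=tuple(range(L)),
        mask_flags=(False,) * L,
        original_ids=tuple(ids),
    )


def tokenize_corpus(corpus: WalkCorpus, vocab: NodeVocabulary) -> np.ndarray:
    """All walks as one (n_walks, walk_length+1) int array, [PAD]-completed."""
    L = corpus.walk_length + 1
    out = np.full((len(corpus), L), vocab.pad_id, dtype=np.int64)
    out[:, 0] = vocab.cls_id
    for r, walk in enumerate(corpus.walks):
        out[r, 1 : 1 + len(walk)] = walk.node_ids
    return out


def write_corpus(corpus: WalkCorpus, vocab: NodeVocabulary, path: str | Path) -> None:
    """One walk per line as space-separated node names with a source tag."""
    with Path(path).open("w") as fh:
        fh.write(f"# reps={corpus.reps_per_node} length={corpus.walk_length} seed={corpus.seed}\n")
        for walk in corpus.walks:
            names = " ".join(vocab.names[i] for i in walk.node_ids)
            fh.write(f"{names}\t#source={walk.source_network}\n")


def read_corpus(path: str | Path, vocab: NodeVocabulary) -> WalkCorpus:
    walks: list[Walk] = []
    reps, length, seed = 0, 0, 0
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = dict(kv.split("=") for kv in line[1:].split())
                reps = int(parts.get("reps", 0))
                length = int(parts.get("length", 0))
                seed = int(parts.get("seed", 0))
                continue
            if not line.strip():
                continue
            body, _, tag = line.partition("\t")
            source = int(tag.split("=")[1]) if "=" in tag else 0
            ids = tuple(vocab.index[name] for name in body.split())
            walks.append(Walk(node_ids=ids, source_network=source))
    if length == 0 and walks:
        length = max(len(w) for w in walks)
    return WalkCorpus(walks=walks, reps_per_node=reps, walk_length=length, seed=seed)
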