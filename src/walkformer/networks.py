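"""Reading and numerically representing collections of weighted gene networks.

A collection of undirected weighted networks over a shared gene namespace is
the raw input of the whole pipeline. Each network is stored sparsely as its
adjacency matrix A, the degree vector, and the symmetric-normalized matrix
W = D^(-1/2) A D^(-1/2) used by the propagation step. All networks in a
collection share one :class:`NodeVocabulary`, so node ids are stable across
networks and across the special tokens the encoder appends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CLS_TOKEN = "[CLS]"
MASK_TOKEN = "[MASK]"
PAD_TOKEN = "[PAD]"
SPECIAL_TOKENS = (CLS_TOKEN, MASK_TOKEN, PAD_TOKEN)

Edge = tuple[str, str, float]


class EdgeListParseError(ValueError):
    """Raised for malformed lines or invalid weights in an edge-list file."""


@dataclass(frozen=True)
class NodeVocabulary:
    """Stable 0-based integer ids for gene names, plus trailing special tokens.

    Node ids occupy ``[0, n)`` in lexicographic name order; the [CLS], [MASK]
    and [PAD] ids follow at ``n``, ``n+1`` and ``n+2``.
    """

    names: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "NodeVocabulary":
        ordered = tuple(sorted(set(names)))
        if not ordered:
            raise ValueError("vocabulary requires at least one node name")
        for tok in SPECIAL_TOKENS:
            if tok in ordered:
                raise ValueError(f"node name collides with special token {tok!r}")
        return cls(names=ordered, index={name: i for i, name in enumerate(ordered)})

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def cls_id(self) -> int:
        return self.n

    @property
    def mask_id(self) -> int:
        return self.n + 1

    @property
    def pad_id(self) -> int:
        return self.n + 2

    @property
    def size_with_special(self) -> int:
        return self.n + len(SPECIAL_TOKENS)

    def __len__(self) -> int:
        return self.n


def read_weighted_edge_list(path: str | Path, default_weight: float = 1.0) -> list[Edge]:
    """Parse a 2- or 3-column whitespace-delimited edge list.

    ``#`` lines are comments; 2-column lines receive ``default_weight``;
    duplicate (a,b)/(b,a) pairs collapse to the maximum weight; self-edges are
    dropped with a warning. Raises :class:`EdgeListParseError` on malformed
    lines or negative weights, naming the offending line number.
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 2:
                a, b = fields
                w = default_weight
            elif len(fields) == 3:
                a, b = fields[:2]
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
            else:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            if not np.isfinite(w) or w < 0:
                raise EdgeListParseError(f"{path}:{lineno}: weight must be finite and >= 0, got {w}")
            if a == b:
                logger.warning("%s:%d: dropping self-edge on %r", path, lineno, a)
                continue
            key = (a, b) if a < b else (b, a)
            if key not in best:
                order.append(key)
                best[key] = w
            else:
                best[key] = max(best[key], w)
    return [(a, b, best[(a, b)]) for a, b in order]


def build_vocabulary(edge_lists: Sequence[Sequence[Edge]]) -> NodeVocabulary:
    """Vocabulary over the union of node names across all edge lists."""
    if not edge_lists:
        raise ValueError("at least one edge list is required")
    names: set[str] = set()
    for edges in edge_lists:
        for a, b, _ in edges:
            names.add(a)
            names.add(b)
    if not names:
        raise ValueError("edge lists contain no nodes")
    return NodeVocabulary.from_names(names)


class Network:
    """One weighted undirected network over a shared vocabulary.

    Parameters
    ----------
    vocab
        The collection-wide vocabulary; ids in this network refer to it.
    edges
        Undirected edges as ``(name_a, name_b, weight)`` with ``weight >= 0``.
    name
        Optional label used in logs and corpus provenance tags.
    """

    def __init__(self, vocab: NodeVocabulary, edges: Sequence[Edge], name: str = "network"):
        self.vocab = vocab
        self.name = name
        n = vocab.n
        rows, cols, vals = [], [], []
        canon: list[tuple[int, int, float]] = []
        for a, b, w in edges:
            if a == b:
                continue
            if w < 0:
                raise ValueError(f"negative edge weight {w} on ({a}, {b})")
            i, j = vocab.index[a], vocab.index[b]
            if i > j:
                i, j = j, i
            canon.append((i, j, float(w)))
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((w, w))
        self.edges: list[tuple[int, int, float]] = sorted(canon)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        # duplicate entries would be summed by coo->csr; inputs are pre-collapsed
        self.A: sp.csr_matrix = A.tocsr()
        self.degrees: np.ndarray = np.asarray(self.A.sum(axis=1)).ravel()
        self.present: np.ndarray = self.degrees > 0
        self.W: sp.csr_matrix = symmetric_normalized_adjacency(self.A, self.degrees)

    @property
    def n(self) -> int:
        return self.vocab.n

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def symmetric_normalized_adjacency(
    A: sp.spmatrix, degrees: np.ndarray | None = None
) -> sp.csr_matrix:
    """W = D^(-1/2) A D^(-1/2), with zero rows/columns for degree-0 nodes."""
    A = A.tocsr()
    if degrees is None:
        degrees = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.where(degrees > 0, degrees, 1.0)), 0.0)
    Dinv = sp.diags(inv_sqrt)
    return (Dinv @ A @ Dinv).tocsr()


@dataclass
class NetworkCollection:
    """An ordered list of networks sharing one vocabulary."""

    networks: list[Network]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("a collection needs at least one network")
        vocab = self.networks[0].vocab
        if any(net.vocab is not vocab for net in self.networks):
            raise ValueError("all networks must share the identical vocabulary object")

    @property
    def vocab(self) -> NodeVocabulary:
        return self.networks[0].vocab

    @property
    def T(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    @classmethod
    def from_edge_lists(
        cls,
        edge_lists: Sequence[Sequence[Edge]],
        names: Sequence[str] | None = None,
        vocab_mode: str = "union",
    ) -> "NetworkCollection":
        """Build a collection from parsed edge lists over one shared vocabulary.

        ``vocab_mode='union'`` (default) takes every name seen anywhere;
        ``'intersection'`` keeps only names present in all lists, dropping
        edges with excluded endpoints.
        """
        if vocab_mode not in ("union", "intersection"):
            raise ValueError(f"unknown vocab_mode {vocab_mode!r}")
        if vocab_mode == "intersection":
            per_list = [
                {name for a, b, _ in edges for name in (a, b)} for edges in edge_lists
            ]
            keep = set.intersection(*per_list) if per_list else set()
            if not keep:
                raise ValueError("intersection of node sets is empty")
            edge_lists = [
                [(a, b, w) for a, b, w in edges if a in keep and b in keep]
                for edges in edge_lists
            ]
            vocab = NodeVocabulary.from_names(keep)
        else:
            vocab = build_vocabulary(edge_lists)
        if names is None:
            names = [f"network_{t}" for t in range(len(edge_lists))]
        nets = [Network(vocab, edges, name=nm) for edges, nm in zip(edge_lists, names)]
        return cls(networks=nets)

    @classmethod
    def from_files(
        cls, paths: Sequence[str | Path], default_weight: float = 1.0, vocab_mode: str = "union"
    ) -> "NetworkCollection":
        edge_lists = [read_weighted_edge_list(p, default_weight) for p in paths]
        names = [Path(p).stem for p in paths]
        return cls.from_edge_lists(edge_lists, names=names, vocab_mode=vocab_mode)


def write_sparse_coo(matrix: sp.spmatrix, path: str | Path) -> None:
    """Debug writer: 0-based ``row col value`` text lines."""
    coo = matrix.tocoo()
    with Path(path).open("w") as fh:
        fh.write("# row col value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.12g}\n")
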