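"""Deterministic generators for planted-structure test collections.

Real multi-network gene compendia are clustered (genes in the same complex
or pathway interact densely) and only partially overlapping (each assay
covers a different subset of the genome). The stochastic block model with
per-network node dropout emulates exactly those two properties — planted
modules and partial coverage — without attempting realistic degree tails or
expression magnitudes.

Labeled paths emulate perturbation pathways: a chain of interacting genes
from a perturbed source to an affected target, labeled +1 / -1 / 0 by a
deterministic rule on the (source community, target community) pair. The
default rule is order-antisymmetric (community pair (a, b) is up while
(b, a) is down), so the sign of a path is invisible to any order-blind
representation of its genes — which is what makes the sequence-level [CLS]
representation earn its keep over averaged node features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import FunctionalStandard, LabeledPath
from .networks import Network, NetworkCollection, NodeVocabulary
from .walks import _RowSampler

__all__ = ["SBMSpec", "EndpointRule", "generate_sbm_collection", "generate_labeled_paths", "ring_collection"]


@dataclass(frozen=True)
class SBMSpec:
    """Parameters of the planted-module multi-network generator."""

    n_nodes: int = 200
    n_modules: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    weight_low: float = 1.0
    weight_high: float = 1.0  # equal bounds -> constant weights
    dropout: float = 0.2  # per-network node-removal fraction
    T: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.n_modules < 1 or self.n_nodes < self.n_modules:
            raise ValueError("need n_nodes >= n_modules >= 1")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_sbm_collection(spec: SBMSpec) -> tuple[NetworkCollection, FunctionalStandard]:
    """T block-model networks over one vocabulary, plus the planted modules.

    Module ``m`` owns a contiguous block of node names. Each network first
    drops ``dropout`` of the nodes uniformly at random (they stay in the
    vocabulary with degree 0 there), then draws each remaining pair as an
    edge with probability ``p_in`` within a module and ``p_out`` across.
    """
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec.n_nodes)
    vocab = NodeVocabulary.from_names(names)
    # names are zero-padded so lexicographic vocab order == generation order
    membership = np.repeat(np.arange(spec.n_modules), -(-spec.n_nodes // spec.n_modules))[: spec.n_nodes]

    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    same = membership[iu] == membership[ju]
    probs = np.where(same, spec.p_in, spec.p_out)

    networks = []
    for t in range(spec.T):
        keep = np.ones(spec.n_nodes, dtype=bool)
        if spec.dropout > 0:
            n_drop = int(round(spec.dropout * spec.n_nodes))
            keep[rng.choice(spec.n_nodes, size=n_drop, replace=False)] = False
        draw = rng.random(iu.size) < probs
        alive = draw & keep[iu] & keep[ju]
        if spec.weight_high > spec.weight_low:
            weights = rng.uniform(spec.weight_low, spec.weight_high, size=int(alive.sum()))
        else:
            weights = np.full(int(alive.sum()), spec.weight_low)
        edges = [
            (names[i], names[j], float(w))
            for i, j, w in zip(iu[alive], ju[alive], weights)
        ]
        if not edges:
            raise ValueError(f"network {t} came out empty; raise p_in/p_out or n_nodes")
        net = Network(vocab, edges, name=f"sbm_{t}")
        net._collection_index = t
        networks.append(net)

    standard = FunctionalStandard(
        labels={names[i]: {f"module_{membership[i]}"} for i in range(spec.n_nodes)},
        source="planted",
    )
    return NetworkCollection(networks=networks), standard


def ring_collection(n_nodes: int, T: int = 1) -> NetworkCollection:
    """A minimal connected collection (each network a ring); handy when only
    the vocabulary size matters, e.g. corpus-size arithmetic at scale."""
    names = _gene_names(n_nodes)
    vocab = NodeVocabulary.from_names(names)
    edges = [(names[i], names[(i + 1) % n_nodes], 1.0) for i in range(n_nodes)]
    nets = []
    for t in range(T):
        net = Network(vocab, edges, name=f"ring_{t}")
        net._collection_index = t
        nets.append(net)
    return NetworkCollection(networks=nets)


@dataclass(frozen=True)
class EndpointRule:
    """Deterministic path label from (source community, target community).

    ``up_pairs`` map to +1 and ``down_pairs`` to -1; everything else is 0.
    The default uses order-antisymmetric pairs so that reversing a path flips
    its sign.
    """

    up_pairs: frozenset = frozenset({(0, 1), (2, 3)})
    down_pairs: frozenset = frozenset({(1, 0), (3, 2)})

    def label(self, source_community: int, target_community: int) -> int:
        pair = (source_community, target_community)
        if pair in self.up_pairs:
            return 1
        if pair in self.down_pairs:
            return -1
        return 0


def generate_labeled_paths(
    collection: NetworkCollection,
    standard: FunctionalStandard,
    n_paths: int,
    rule: EndpointRule | None = None,
    seed: int = 0,
    path_length: int = 3,
    nonzero_fraction: float | None = 0.18,
    max_tries: int = 200,
) -> list[LabeledPath]:
    """Random-walk paths labeled by the endpoint-community rule.

    When ``nonzero_fraction`` is set, each path first draws its category
    (nonzero with that probability), then rejection-samples walks until the
    rule's label matches the category, so the realized nonzero share is
    binomial around the target — mirroring the sparse-signal regime of
    real perturbation-pathway compendia. ``None`` disables the balancing and
    takes walks as they come.
    """
    if rule is None:
        rule = EndpointRule()
    vocab = collection.vocab
    community = {}
    for name, labels in standard.labels.items():
        tag = sorted(labels)[0]
        community[vocab.index[name]] = int(tag.rsplit("_", 1)[1]) if "_" in tag else 0
    if len({community[i] for i in community}) < 2:
        raise ValueError("need at least two communities to label paths")

    rng = np.random.default_rng(seed)
    samplers = [_RowSampler(net.A) for net in collection]
    present = [np.flatnonzero(net.present) for net in collection]

    def draw_walk() -> tuple[list[int], int]:
        t = int(rng.integers(collection.T))
        nodes = present[t]
        walk = [int(nodes[rng.integers(nodes.size)])]
        for _ in range(path_length - 1):
            walk.append(int(samplers[t].step(np.asarray(walk[-1:]), rng.random(1))[0]))
        return walk, rule.label(community[walk[0]], community[walk[-1]])

    paths: list[LabeledPath] = []
    for _ in range(n_paths):
        walk, label = draw_walk()
        if nonzero_fraction is not None:
            want_nonzero = bool(rng.random() < nonzero_fraction)
            tries = 0
            while (label != 0) != want_nonzero and tries < max_tries:
                walk, label = draw_walk()
                tries += 1
        paths.append(LabeledPath(nodes=tuple(vocab.names[i] for i in walk), label=label))
    return paths
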