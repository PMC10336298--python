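"""Masked-node transformer encoder with per-epoch network propagation.

The model learns one embedding row per vocabulary node (plus [CLS], [MASK]
and [PAD] rows). Training is masked language modeling over the walk corpus:
a fraction of node tokens in each sentence is replaced by [MASK] and the
encoder is trained with cross-entropy to recover their identities. Once per
epoch, before any batches, the node rows of the embedding table are smoothed
over one of the input networks (round-robin in input order) by a single
random-walk-with-restart step

    X' = (1 - alpha) W X + alpha X,      W = D^(-1/2) A D^(-1/2),

which acts as a regularizer tying the embedding to network structure. The
trained artifacts are the embedding table (node features) and the encoder
weights, whose [CLS] hidden state embeds whole node sequences.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .autograd import Tensor, concat, gather_rows
from .networks import Network, NetworkCollection, NodeVocabulary
from .nn import EncoderBlock, positional_encoding_matrix
from .walks import TokenizedSequence, WalkCorpus, tokenize_corpus

logger = logging.getLogger(__name__)

__all__ = [
    "TransformerConfig",
    "EmbeddingTable",
    "MaskedBatch",
    "MLMEncoder",
    "apply_mask",
    "mask_token_array",
    "mlm_loss",
    "propagate_embeddings",
    "train",
    "extract_node_embeddings",
    "extract_sequence_embedding",
    "embed_token_sequences",
    "write_embeddings",
    "read_embeddings",
]


@dataclass
class TransformerConfig:
    """Architecture and training hyperparameters.

    ``e`` is the node-embedding dimension; the encoder width is ``2e`` when
    positional encodings are concatenated (``pe_mode='concat'``, the default)
    and ``e`` when they are added. ``alpha`` is the restart probability of the
    per-epoch propagation step (``alpha=1`` leaves the table untouched);
    ``propagate=False`` skips the step entirely.
    """

    e: int = 128
    n_blocks: int = 4
    n_heads: int = 4
    ffn_hidden: int | None = None  # defaults to 4x encoder width
    mask_rate: float = 0.20
    alpha: float = 0.5
    pe_mode: str = "concat"
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    dropout: float = 0.1
    propagate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mask_rate < 1.0):
            raise ValueError("mask_rate must be in (0, 1)")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.pe_mode not in ("concat", "add"):
            raise ValueError(f"unknown pe_mode {self.pe_mode!r}")
        if self.width % self.n_heads != 0:
            raise ValueError(f"width {self.width} not divisible by {self.n_heads} heads")

    @property
    def width(self) -> int:
        return 2 * self.e if self.pe_mode == "concat" else self.e

    @property
    def ffn_width(self) -> int:
        return self.ffn_hidden if self.ffn_hidden is not None else 4 * self.width

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TransformerConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class EmbeddingTable:
    """The (n + 3) x e token-embedding matrix; node rows follow vocab order."""

    X: Tensor
    vocab: NodeVocabulary

    @classmethod
    def initialize(cls, vocab: NodeVocabulary, e: int, rng: np.random.Generator) -> "EmbeddingTable":
        limit = 1.0 / np.sqrt(e)
        data = rng.uniform(-limit, limit, size=(vocab.size_with_special, e))
        return cls(X=Tensor(data, requires_grad=True), vocab=vocab)

    @property
    def node_rows(self) -> np.ndarray:
        return self.X.data[: self.vocab.n]


@dataclass
class MaskedBatch:
    """Token arrays after masking: ids with [MASK] substituted, plus targets."""

    token_ids: np.ndarray  # (B, L) int, post-masking
    targets: np.ndarray  # (B, L) int, original id at masked cells, -1 elsewhere
    mask_flags: np.ndarray  # (B, L) bool
    sequences: list[TokenizedSequence] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return int(self.mask_flags.sum())


def mask_token_array(
    tokens: np.ndarray,
    vocab: NodeVocabulary,
    mask_rate: float,
    rng: np.random.Generator,
) -> MaskedBatch:
    """Mask ``max(1, round(rate * n_maskable))`` node tokens per sequence.

    [CLS] and [PAD] positions are never candidates. A sequence with no
    maskable position is skipped with a warning (it contributes nothing to
    the loss).
    """
    if not (0.0 < mask_rate < 1.0):
        raise ValueError("mask_rate must be in (0, 1)")
    tokens = np.asarray(tokens)
    masked = tokens.copy()
    targets = np.full_like(tokens, -1)
    flags = np.zeros(tokens.shape, dtype=bool)
    maskable = (tokens != vocab.cls_id) & (tokens != vocab.pad_id) & (tokens != vocab.mask_id)
    for b in range(tokens.shape[0]):
        cand = np.flatnonzero(maskable[b])
        if cand.size == 0:
            logger.warning("sequence %d has no maskable position; skipped", b)
            continue
        k = max(1, int(np.floor(mask_rate * cand.size + 0.5)))
        chosen = rng.choice(cand, size=min(k, cand.size), replace=False)
        masked[b, chosen] = vocab.mask_id
        targets[b, chosen] = tokens[b, chosen]
        flags[b, chosen] = True
    return MaskedBatch(token_ids=masked, targets=targets, mask_flags=flags)


def apply_mask(
    batch: Sequence[TokenizedSequence],
    mask_rate: float,
    rng: np.random.Generator,
    vocab: NodeVocabulary,
) -> MaskedBatch:
    """Sequence-object surface over :func:`mask_token_array`."""
    tokens = np.asarray([seq.token_ids for seq in batch])
    out = mask_token_array(tokens, vocab, mask_rate, rng)
    out.sequences = [
        TokenizedSequence(
            token_ids=tuple(int(t) for t in out.token_ids[b]),
            positions=batch[b].positions,
            mask_flags=tuple(bool(f) for f in out.mask_flags[b]),
            original_ids=batch[b].token_ids,
        )
        for b in range(len(batch))
    ]
    return out


def mlm_loss(
    logits: Tensor,
    targets: np.ndarray,
    mask_flags: np.ndarray,
    reduction: str = "mean_over_masked",
) -> Tensor:
    """Cross-entropy over masked cells only.

    ``sum`` reproduces the raw masked cross-entropy sum
    ``-sum_{b,l in mask} log p(target)``; ``mean_over_masked`` divides by the
    mask count (the training default, stabler under varying mask counts).
    """
    if reduction not in ("sum", "mean_over_masked"):
        raise ValueError(f"unknown reduction {reduction!r}")
    flags = np.asarray(mask_flags, dtype=bool)
    count = int(flags.sum())
    if count == 0:
        raise ValueError("batch contains no masked positions")
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    tgt = np.where(flags, targets, 0)
    logp_true = np.take_along_axis(z - lse, tgt[..., None], axis=-1)[..., 0]
    total = -float(logp_true[flags].sum())
    scale = 1.0 if reduction == "sum" else 1.0 / count
    probs = np.exp(z - lse)

    def bw(g):
        if logits.requires_grad:
            grad = probs.copy()
            np.put_along_axis(
                grad, tgt[..., None], np.take_along_axis(grad, tgt[..., None], axis=-1) - 1.0, axis=-1
            )
            grad *= flags[..., None]
            logits._accumulate(grad * (float(g) * scale))

    return Tensor(total * scale, parents=(logits,), backward=bw)


class MLMEncoder:
    """The full model: embedding table, positional encodings, encoder stack
    and decoder projection onto the ``n`` node classes."""

    def __init__(self, vocab: NodeVocabulary, config: TransformerConfig):
        self.vocab = vocab
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        self.table = EmbeddingTable.initialize(vocab, config.e, init_rng)
        d = config.width
        self.blocks = [
            EncoderBlock(init_rng, d, config.n_heads, config.ffn_width)
            for _ in range(config.n_blocks)
        ]
        limit = 1.0 / np.sqrt(config.e)
        self.Wdec = Tensor(init_rng.uniform(-limit, limit, size=(d, vocab.n)), requires_grad=True)
        self.bdec = Tensor(np.zeros(vocab.n), requires_grad=True)
        self._pe_cache: dict[int, np.ndarray] = {}

    def parameters(self) -> list[Tensor]:
        params = [self.table.X, self.Wdec, self.bdec]
        for block in self.blocks:
            params.extend(block.parameters())
        return params

    def _pe(self, length: int) -> np.ndarray:
        if length not in self._pe_cache:
            self._pe_cache[length] = positional_encoding_matrix(length, self.config.e)
        return self._pe_cache[length]

    def forward(
        self, tokens: np.ndarray, drop_rng: np.random.Generator | None = None
    ) -> tuple[Tensor, Tensor]:
        """Encode a (B, L) token array; returns (hidden (B,L,d), logits (B,L,n))."""
        tokens = np.atleast_2d(np.asarray(tokens))
        B, L = tokens.shape
        emb = gather_rows(self.table.X, tokens)  # (B, L, e)
        pe = Tensor(np.broadcast_to(self._pe(L), (B, L, self.config.e)).copy())
        if self.config.pe_mode == "concat":
            h = concat([emb, pe], axis=-1)
        else:
            h = emb + pe
        key_mask = tokens == self.vocab.pad_id
        if not key_mask.any():
            key_mask = None
        rate = self.config.dropout if drop_rng is not None else 0.0
        for block in self.blocks:
            h = block(h, key_mask=key_mask, drop_rate=rate, drop_rng=drop_rng)
        logits = h @ self.Wdec + self.bdec
        return h, logits

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {"table": self.table.X.data, "Wdec": self.Wdec.data, "bdec": self.bdec.data}
        for i, block in enumerate(self.blocks):
            for name, p in zip(
                ("Wq", "Wk", "Wv", "W1", "b1", "W2", "b2", "ln1_g", "ln1_b", "ln2_g", "ln2_b"),
                block.parameters(),
            ):
                arrays[f"block{i}_{name}"] = p.data
        np.savez(directory / "weights.npz", **arrays)
        self.config.to_yaml(directory / "config.yaml")
        (directory / "vocab.txt").write_text("\n".join(self.vocab.names) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "MLMEncoder":
        directory = Path(directory)
        config = TransformerConfig.from_yaml(directory / "config.yaml")
        names = (directory / "vocab.txt").read_text().splitlines()
        vocab = NodeVocabulary.from_names(names)
        model = cls(vocab, config)
        arrays = np.load(directory / "weights.npz")
        model.table.X.data[...] = arrays["table"]
        model.Wdec.data[...] = arrays["Wdec"]
        model.bdec.data[...] = arrays["bdec"]
        for i, block in enumerate(model.blocks):
            for name, p in zip(
                ("Wq", "Wk", "Wv", "W1", "b1", "W2", "b2", "ln1_g", "ln1_b", "ln2_g", "ln2_b"),
                block.parameters(),
            ):
                p.data[...] = arrays[f"block{i}_{name}"]
        return model


def propagate_embeddings(table: EmbeddingTable, network: Network, alpha: float) -> EmbeddingTable:
    """One random-walk-with-restart step, in place, on the node rows.

    Rows of nodes with positive degree in ``network`` become
    ``(1-alpha) (W X)_row + alpha X_row``; degree-0 and special-token rows are
    untouched (so unused rows are not shrunk toward zero).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    n = table.vocab.n
    X_nodes = table.X.data[:n]
    propagated = (1.0 - alpha) * (network.W @ X_nodes) + alpha * X_nodes
    present = network.present
    table.X.data[:n][present] = propagated[present]
    return table


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    collection: NetworkCollection,
    corpus: WalkCorpus,
    config: TransformerConfig,
    callback: Callable[[int, float], None] | None = None,
) -> tuple[MLMEncoder, list[float]]:
    """Train the encoder on a walk corpus.

    Per epoch: (1) propagate the embedding table on network ``epoch mod T``
    (skipped when ``config.propagate`` is False); (2) reshuffle the corpus;
    (3) per batch, mask, encode, decode to node logits, take an Adam step on
    all weights and the table. Returns the model and the per-epoch mean loss
    per masked token. Raises on divergence (non-finite loss).
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    vocab = collection.vocab
    model = MLMEncoder(vocab, config)
    tokens_all = tokenize_corpus(corpus, vocab)
    ss = np.random.SeedSequence(config.seed)
    _, mask_seq, shuffle_seq, drop_seq = ss.spawn(4)  # first child mirrors model init
    mask_rng = np.random.default_rng(mask_seq)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    drop_rng = np.random.default_rng(drop_seq) if config.dropout > 0 else None
    optim = Adam(model.parameters(), config.learning_rate)

    trace: list[float] = []
    for epoch in range(config.epochs):
        if config.propagate:
            net = collection.networks[epoch % collection.T]
            propagate_embeddings(model.table, net, config.alpha)
            logger.debug("epoch %d: propagated on %s (alpha=%.3f)", epoch, net.name, config.alpha)
        order = shuffle_rng.permutation(len(corpus))
        total_loss, total_masked = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = mask_token_array(tokens_all[idx], vocab, config.mask_rate, mask_rng)
            if batch.n_masked == 0:
                continue
            model.zero_grad()
            _, logits = model.forward(batch.token_ids, drop_rng=drop_rng)
            loss = mlm_loss(logits, batch.targets, batch.mask_flags, "mean_over_masked")
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward()
            optim.step()
            total_loss += float(loss.data) * batch.n_masked
            total_masked += batch.n_masked
        epoch_loss = total_loss / max(total_masked, 1)
        trace.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss)
    return model, trace


def extract_node_embeddings(table: EmbeddingTable, vocab: NodeVocabulary) -> pd.DataFrame:
    """Node rows only (special tokens excluded), indexed by node name."""
    return pd.DataFrame(table.X.data[: vocab.n].copy(), index=list(vocab.names))


def extract_sequence_embedding(model: MLMEncoder, sequence: TokenizedSequence) -> np.ndarray:
    """Final [CLS] hidden state of one tokenized sequence (no masking/dropout)."""
    tokens = np.asarray([sequence.token_ids])
    hidden, _ = model.forward(tokens, drop_rng=None)
    return hidden.data[0, 0].copy()


def embed_token_sequences(model: MLMEncoder, tokens: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """[CLS] hidden states for a (N, L) token array, batched for memory."""
    tokens = np.asarray(tokens)
    out = np.empty((tokens.shape[0], model.config.width))
    for lo in range(0, tokens.shape[0], batch_size):
        hidden, _ = model.forward(tokens[lo : lo + batch_size], drop_rng=None)
        out[lo : lo + batch_size] = hidden.data[:, 0]
    return out


def write_embeddings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, float_format="%.8g")


def read_embeddings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, index_col=0)
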