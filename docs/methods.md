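# Methods

## The model

walkformer learns a joint embedding of the genes in a collection of T
weighted, undirected networks G_1..G_T over a shared vocabulary of n genes.
The pipeline has three stages.

**Walk sentences.** Each network is converted to text-like sentences by
first-order random walks: from node u the walk steps to neighbor v with
probability w(u,v) / Σ_v' w(u,v'). Walks are 10 nodes long by default, with
10 walks per node. Two corpus-size conventions are exposed. The default,
`per_union_node`, emits exactly `reps` walks per vocabulary node — each from
a uniformly chosen network in which the node has positive degree — so the
corpus size is exactly `reps × n` (10 × 5232 = 52 320 sentences for a
5232-gene vocabulary) regardless of how much the networks overlap. The
alternative, `per_network`, emits `reps` walks from every node in every
network, giving `reps × Σ_t n_t` sentences. Both are implemented because
the two conventions are both natural readings of "walks per node" in a
multi-network setting and they disagree exactly when networks overlap; the
union convention is the default because it keeps corpus size a function of
the vocabulary alone and leaves no node unrepresented (a node isolated in
every network still contributes singleton sentences, [PAD]-completed at
tokenization).

**Masked-node encoder.** Each sentence is tokenized as [CLS] followed by
the walk's node tokens. The encoder embeds tokens via a learned
(n + 3) × e table (three special rows: [CLS], [MASK], [PAD]), attaches
sinusoidal positional encodings

    PE(pos, i) = sin(pos / 10000^(i/e))      i even
    PE(pos, i) = cos(pos / 10000^((i−1)/e))  i odd

and runs N identical blocks of multi-head scaled dot-product self-attention
(softmax(QK^T/√d_k)V per head, heads concatenated, bias-free Q/K/V
projections, no output projection after concatenation) followed by a
position-wise ReLU feed-forward network, each sublayer wrapped in a
post-norm residual. Note the positional-encoding exponent advances by 1/e
per coordinate index (an even/odd coordinate pair shares one wavelength
through the (i−1) in the odd case), not by 2i/d; the implementation follows
that definition literally and the tests pin it against a scalar oracle.
Positional encodings are concatenated to the embedding by default
(`pe_mode='concat'`, model width d = 2e); additive encodings (d = e) are
available since that is the more common transformer convention.

Training is masked language modeling: per sentence, k = max(1, round(0.2 ·
n_maskable)) node tokens are replaced by [MASK] ([CLS] and [PAD] are never
candidates; masked tokens are always replaced by [MASK] — no secondary
mask/random-token/keep split is applied) and the encoder output is
projected to n node classes. The loss is cross-entropy over masked cells
only; the literal unnormalized sum is available (`reduction='sum'`), while
training uses the mean over masked cells so the effective learning rate does
not depend on batch mask counts. All parameters, including the embedding
table, are updated by Adam.

**Propagation regularization.** Once per epoch, before any batches, the node
rows of the embedding table are smoothed over network G_{epoch mod T}
(round-robin in input order) by one random-walk-with-restart step

    X' = (1 − α) W X + α X,    W = D^(−1/2) A D^(−1/2),

overwriting the table in place. Rows of nodes with zero degree in that
network, and the special-token rows, are left untouched — propagating them
would only shrink unused rows toward zero under the (1 − α)·0 term. α is
the restart probability; it is not prescribed by the approach itself, so the
default is the canonical RWR middle ground α = 0.5, exposed in the config.
α = 1 makes the step an exact identity. The step deliberately trades
training loss for embedding quality: the table is perturbed away from the
MLM optimum each epoch, so the final loss is higher than without
propagation, but the embedding is smoother along the networks and recovers
module structure better — the acceptance suite asserts exactly this
direction of effect on the planted-module fixture.

The trained artifacts are (i) the node rows of the embedding table after the
final epoch (which includes that epoch's propagation step), used as gene
features, and (ii) the encoder weights, whose final [CLS] hidden state
(dimension d) embeds an arbitrary gene sequence for pathway-level tasks.

## Numerical implementation

The encoder, backpropagation and Adam are implemented directly on numpy
float64 arrays via a small reverse-mode autodiff core (`autograd.py`): the
models this package targets are small (hundreds to tens of thousands of
nodes, width ≤ 256), where dense float64 batched matmuls on one CPU are
entirely adequate and exact reproducibility is easy to guarantee. Gradient
correctness of every primitive and of the end-to-end loss w.r.t. the
embedding table is pinned by central finite-difference checks (tolerance
1e-4 on the full model, 1e-6 per primitive).

Initialization: embedding table and decoder uniform in ±1/√e; transformer
projections Xavier-uniform; biases and layer-norm shifts zero. Padding keys
are excluded from attention with a −1e9 additive score mask. Layer norm uses
eps = 1e-5. Dropout (default 0.1) applies to the sublayer outputs during
training only. All randomness derives from one integer seed through
`numpy.random.SeedSequence` children (init / masking / shuffling / dropout),
and walk transitions use the counter-based Philox generator with one uniform
per (walk, step), so corpora are reproducible independently of evaluation
order. Fixed seed ⇒ bit-identical loss traces run to run on one machine.

Defaults follow small-transformer practice where the approach itself fixes
nothing: 4 blocks, 4 heads, FFN hidden 4 × width, e = 128, batch 64, Adam
at 1e-3, 100 epochs. The scaled-down study conditions used by the tests and
the acceptance script (e = 32, 2 blocks, 30 epochs on a 200-node fixture)
were chosen as the smallest configuration at which module recovery saturates
on the planted fixture; they keep a full multi-seed study in CPU minutes.

## Evaluation protocols

**Module detection.** Hierarchical clustering of the embedding over a sweep
of distance metrics {cosine, euclidean} × linkages {average, complete} ×
flat cuts k ∈ {2, …, min(50, n/4)}; each flat clustering is scored against
the functional standard by adjusted mutual information, and the sweep
maximum is reported. Genes without an embedding are dropped (logged); genes
with several module labels contribute their lexicographically first label —
the flat comparison needs one label per gene and no convention is canonical,
so the deterministic one is used and flagged.

**Gene-function prediction.** Multi-label classification of functional terms
from embedding features. Terms below 10% frequency are filtered (rarer terms
cannot be stratified into 5 folds); folds come from seeded greedy iterative
stratification (rarest remaining label first, examples dealt to the fold
with the largest remaining demand). A 500-tree random forest is trained per
fold; the score is the unweighted mean over labels of per-label F1, averaged
over folds.

**Pathway classification.** A gene path is embedded as a single [CLS]-led
sequence through the trained encoder; the final [CLS] hidden state is the
feature vector for a 500-tree random-forest classifier of the path's
−1/0/+1 effect label under stratified 5-fold cross-validation. Out-of-fold
class probabilities are pooled and one ROC curve per class is computed
one-vs-rest; the macro AUC is their unweighted mean. The "layman" baseline
replaces the [CLS] vector by the unweighted mean of the path's node
embedding rows — an order-blind representation of the same genes, trained
and scored identically. `path_synthesis` enumerates candidate paths from
perturbation sources by bounded depth-first search (default ≤ 4 edges,
≤ 1000 paths per source) and labels endpoints by the supplied up/down
effect map.

## Synthetic study conditions

`generate_sbm_collection` draws T = 3 networks of n = 200 genes in 5
equal-size planted modules (p_in = 0.3, p_out = 0.02, unit weights), each
network independently dropping 20% of the nodes to emulate the partial
coverage of real assays. These defaults are the fixed study conditions of
the test suite: small enough to train in minutes, structured enough that a
sound implementation separates the modules cleanly while each single
network, missing a fifth of the genes, cannot.

`generate_labeled_paths` samples 3-node random-walk paths
(source → mediator → target) and labels them by a deterministic rule on the
ordered (source community, target community) pair; the default rule is
order-antisymmetric (pair (a, b) up ⇔ pair (b, a) down), and a target
nonzero fraction (default 18%, the sparse-signal regime typical of
perturbation-response compendia) is met by drawing each path's category
first and rejection-sampling walks to match. Paths are 3 nodes by design:
over longer walks the community *composition* of the path becomes skewed
toward the source, so an order-blind mean of node features could read the
path's direction off composition alone and the task would no longer isolate
sequence-level information. With 3-node paths the endpoints enter the mean
symmetrically and the ±1 sign is a pure order property — precisely the
signal the [CLS] representation exists to capture.

What the fixtures do not emulate: realistic degree distributions (no
degree correction), edge-weight heterogeneity, correlated noise between
networks, or knockout-expression magnitudes. Passing the suite therefore
shows the machinery is correct and that integration/propagation/sequence
effects point the right way under clean planted structure; it does not
certify performance on real compendia.

## Known limitations

- Dense per-batch attention is O(B · L² · d); fine for walk-length
  sentences, unsuitable for very long sequences.
- The embedding table is dense ((n + 3) × e float64); a 100k-node
  vocabulary at e = 128 is ~100 MB, beyond which sparse updates would be
  needed.
- `per_union_node` sampling draws the source network per walk uniformly
  among networks containing the node, not weighted by the node's degree in
  each network.
- Iterative stratification is the greedy variant; exact label-ratio
  balancing is not guaranteed for highly co-occurring labels.
- The propagation step is not differentiated through: it is a between-epoch
  in-place smoothing, not part of the training graph (Adam moments are kept
  across it).
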