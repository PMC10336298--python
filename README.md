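# walkformer

Unsupervised integration of multiple weighted gene networks into a single
node embedding — plus a sequence-level embedding of whole gene paths — by
turning networks into random-walk "sentences" and training a small
masked-language transformer whose embedding table is smoothed over the
networks once per epoch.

## Who this is for

Systems biologists with several heterogeneous interaction networks over a
shared gene namespace (protein–protein interaction, co-expression, genetic
interaction, …) who want one joint feature vector per gene for module
detection and function prediction, and a representation of gene *paths*
(e.g. perturbation source → affected gene chains) for pathway-level
classification.

## The model

Given T undirected weighted networks {G_1..G_T} over n genes and a target
dimension e:

1. **Walks → sentences.** Each network is sampled by first-order random
   walks (transition probability ∝ edge weight), 10 walks of 10 nodes per
   vocabulary node by default, yielding a corpus of exactly `10 × n`
   sentences. A [CLS] token is prepended to every sentence.
2. **Masked-node modeling.** A transformer encoder (N = 4 blocks,
   multi-head self-attention + position-wise FFN, sinusoidal positional
   encodings concatenated to the learned token embeddings) is trained to
   recover 20% masked node tokens with cross-entropy

   L = −Σ_{b,l∈mask} Σ_c y_{b,l,c} log p_{b,l,c}.

3. **Propagation regularization.** Once per epoch the node rows of the
   embedding table X are smoothed over one input network (round-robin) by a
   random-walk-with-restart step X′ = (1−α) W X + α X with
   W = D^(−1/2) A D^(−1/2), tying the embedding to network structure. This
   raises the training loss but measurably improves downstream module
   recovery.

The trained node embedding is the table X after the final epoch; the final
[CLS] hidden state embeds any gene sequence for pathway-level tasks.
Everything runs on plain numpy (a built-in reverse-mode autodiff core,
finite-difference-checked); no GPU or deep-learning framework is required.

## Worked example

```python
import walkformer as wf

# three partially overlapping planted-module networks, 200 genes, 5 modules
collection, modules = wf.generate_sbm_collection(wf.SBMSpec(seed=0))
corpus = wf.generate_corpus(collection, reps=10, length=10, seed=0)
print(len(corpus))                     # 2000  (= 10 walks x 200 genes)

cfg = wf.TransformerConfig(e=32, n_blocks=2, epochs=30, seed=0)
model, trace = wf.train(collection, corpus, cfg)
print(round(trace[0], 3), round(trace[-1], 3))   # 5.414 4.19

emb = wf.extract_node_embeddings(model.table, collection.vocab)
result = wf.module_detection(emb, modules)
print(round(result.best_ami, 3), result.best_params)
# 1.0 ('cosine', 'complete', 5)
```

The loss falls from 5.414 (≈ ln 200, chance level over the 200-gene
vocabulary) to 4.19, and hierarchical clustering of the learned embedding
recovers the five planted modules perfectly (adjusted mutual information
1.0, at the cut with k = 5 clusters) — while the same training on any single
network, which is missing 20% of the genes, plateaus around AMI 0.65–0.73.

Pathway-level use: label 3-gene paths by an order-sensitive rule on their
endpoint communities, embed each path via the [CLS] state, and classify:

```python
paths = wf.generate_labeled_paths(collection, modules, n_paths=3000, seed=0)
res = wf.pathway_classification(paths, model=model, seed=0)
base = wf.pathway_classification(paths, embeddings=emb, seed=0)
print(round(res["macro_auc"], 3), round(base["macro_auc"], 3))
# 0.983 0.953
```

The sequence-aware [CLS] features beat the order-blind mean-of-node-features
baseline because the path's −1/+1 sign is a property of gene *order*, which
averaging destroys.

A command-line interface mirrors the library:

```bash
walkformer make-fixtures --out fixtures/
walkformer train --networks fixtures/network_0.tsv --networks fixtures/network_1.tsv \
    --networks fixtures/network_2.tsv --out run/
walkformer evaluate modules --embeddings run/embeddings.tsv \
    --standard fixtures/modules.tsv --out run/modules
walkformer evaluate paths --model run/model --paths fixtures/paths.tsv --out run/paths.json
```

Input networks are plain-text edge lists (`gene_a gene_b [weight]`, `#`
comments); functional standards are `gene<TAB>label` lines (GMT also
accepted); paths are `gene gene gene<TAB>label` lines with labels −1/0/1.

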