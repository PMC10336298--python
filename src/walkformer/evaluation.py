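"""Downstream evaluation protocols for learned embeddings.

Three tasks measure how informative a node embedding (and the sequence-level
[CLS] representation) is:

* **Module detection** — hierarchically cluster the embedding over a sweep of
  distance metrics, linkage methods and cut sizes, and score each flat
  clustering against a functional standard by adjusted mutual information
  (AMI); the best AMI over the sweep is the headline number.
* **Gene-function prediction** — multi-label classification of functional
  terms from embedding features with a random forest under stratified 5-fold
  cross-validation, scored by macro F1 (terms rarer than a frequency floor
  are filtered so folds can be stratified).
* **Pathway classification** — embed a gene path as a single sequence, take
  the final [CLS] hidden state as its feature vector, and classify its
  -1/0/+1 effect label with a random forest in cross-validation, scored by
  macro one-vs-rest ROC AUC. The "layman" baseline represents a path by the
  unweighted mean of its nodes' embedding rows instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_mutual_info_score, auc, f1_score, roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalStandard",
    "ModuleDetectionResult",
    "LabeledPath",
    "module_detection",
    "function_prediction_cv",
    "pathway_classification",
    "path_synthesis",
    "read_functional_standard",
    "read_labeled_paths",
    "write_labeled_paths",
    "iterative_stratification",
]


@dataclass
class FunctionalStandard:
    """Gene -> set of labels (module ids or function terms)."""

    labels: dict[str, set[str]]
    source: str = "user"

    def __post_init__(self) -> None:
        for gene, labs in self.labels.items():
            if not labs or any(not l for l in labs):
                raise ValueError(f"gene {gene!r} must have >= 1 non-empty label")

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels)

    def first_label(self, gene: str) -> str:
        # deterministic "first": lexicographic min; used for flat clustering
        return min(self.labels[gene])


@dataclass
class ModuleDetectionResult:
    best_ami: float
    best_params: tuple[str, str, int]  # (metric, linkage, n_clusters)
    sweep: pd.DataFrame

    def __post_init__(self) -> None:
        assert np.isclose(self.best_ami, self.sweep["ami"].max())


@dataclass(frozen=True)
class LabeledPath:
    """A gene chain from a perturbation source to an affected gene."""

    nodes: tuple[str, ...]
    label: int

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least 2 nodes")
        if self.label not in (-1, 0, 1):
            raise ValueError(f"label must be -1, 0 or 1, got {self.label}")


def module_detection(
    embeddings: pd.DataFrame,
    standard: FunctionalStandard,
    metrics: Sequence[str] = ("cosine", "euclidean"),
    linkages: Sequence[str] = ("average", "complete"),
    k_grid: Sequence[int] | None = None,
) -> ModuleDetectionResult:
    """Best AMI between hierarchical-clustering cuts and the standard.

    Genes missing from the embedding are dropped with a warning; genes with
    several module labels contribute their lexicographically first label to
    the flat comparison.
    """
    common = [g for g in standard.genes if g in embeddings.index]
    missing = len(standard.genes) - len(common)
    if missing:
        logger.warning("module_detection: dropped %d genes without embeddings", missing)
    if len(common) < 2:
        raise ValueError("fewer than 2 standard genes have embeddings")
    X = embeddings.loc[common].to_numpy()
    truth = [standard.first_label(g) for g in common]
    if k_grid is None:
        k_grid = range(2, min(50, len(common) // 4) + 1)

    rows = []
    for metric in metrics:
        dists = pdist(X, metric=metric)
        # cosine distance can dip epsilon-negative on colinear rows
        dists = np.maximum(dists, 0.0)
        for linkage in linkages:
            Z = sch.linkage(dists, method=linkage)
            for k in k_grid:
                flat = sch.fcluster(Z, t=k, criterion="maxclust")
                ami = adjusted_mutual_info_score(truth, flat)
                rows.append({"metric": metric, "linkage": linkage, "k": k, "ami": ami})
    sweep = pd.DataFrame(rows)
    best = sweep.loc[sweep["ami"].idxmax()]
    return ModuleDetectionResult(
        best_ami=float(best["ami"]),
        best_params=(str(best["metric"]), str(best["linkage"]), int(best["k"])),
        sweep=sweep,
    )


def iterative_stratification(Y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Multi-label stratified fold assignment.

    Greedy iterative stratification: repeatedly take the rarest remaining
    label, and deal its remaining examples to the fold with the greatest
    demand for that label (ties broken by overall remaining capacity, then at
    random). Returns a fold index per row.
    """
    n, L = Y.shape
    assignment = np.full(n, -1)
    desired = np.full(folds, n / folds)  # remaining overall capacity
    desired_per_label = np.tile(Y.sum(axis=0) / folds, (folds, 1)).astype(float)
    remaining = set(range(n))
    while remaining:
        counts = Y[list(remaining)].sum(axis=0)
        active = np.flatnonzero(counts > 0)
        if active.size == 0:  # rows with no positive label left: deal by capacity
            for i in sorted(remaining):
                f = int(np.argmax(desired + rng.random(folds) * 1e-9))
                assignment[i] = f
                desired[f] -= 1
            break
        label = active[np.argmin(counts[active])]
        for i in sorted(i for i in remaining if Y[i, label]):
            want = desired_per_label[:, label]
            cand = np.flatnonzero(want == want.max())
            if cand.size > 1:
                cap = desired[cand]
                cand = cand[np.flatnonzero(cap == cap.max())]
            f = int(cand[rng.integers(cand.size)]) if cand.size > 1 else int(cand[0])
            assignment[i] = f
            desired[f] -= 1
            desired_per_label[f] -= Y[i]
            remaining.discard(i)
    return assignment


def function_prediction_cv(
    embeddings: pd.DataFrame,
    standard: FunctionalStandard,
    folds: int = 5,
    min_label_freq: float = 0.10,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Macro F1 of multi-label function prediction under stratified CV.

    Labels rarer than ``min_label_freq`` among the evaluated genes are
    filtered out before stratification; genes left with no label are dropped.
    Returns (per-fold macro F1, mean).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    genes = [g for g in standard.genes if g in embeddings.index]
    dropped = len(standard.genes) - len(genes)
    if dropped:
        logger.warning("function_prediction_cv: dropped %d genes without embeddings", dropped)
    counts: dict[str, int] = {}
    for g in genes:
        for lab in standard.labels[g]:
            counts[lab] = counts.get(lab, 0) + 1
    keep = sorted(lab for lab, c in counts.items() if c / len(genes) >= min_label_freq)
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 labels reach frequency {min_label_freq}; lower the threshold"
        )
    label_ix = {lab: j for j, lab in enumerate(keep)}
    rows = [g for g in genes if standard.labels[g] & set(keep)]
    Y = np.zeros((len(rows), len(keep)), dtype=int)
    for i, g in enumerate(rows):
        for lab in standard.labels[g] & set(keep):
            Y[i, label_ix[lab]] = 1
    X = embeddings.loc[rows].to_numpy()

    rng = np.random.default_rng(seed)
    fold_of = iterative_stratification(Y, folds, rng)
    scores = []
    for f in range(folds):
        test = fold_of == f
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[~test], Y[~test])
        pred = np.asarray(clf.predict(X[test]))
        scores.append(float(f1_score(Y[test], pred, average="macro", zero_division=0)))
    return scores, float(np.mean(scores))


def _path_features_cls(paths, model) -> np.ndarray:
    from .encoder import embed_token_sequences
    from .walks import Walk, tokenize_sequence

    vocab = model.vocab
    max_len = max(len(p.nodes) for p in paths)
    tokens = np.empty((len(paths), max_len + 1), dtype=np.int64)
    for r, p in enumerate(paths):
        walk = Walk(node_ids=tuple(vocab.index[g] for g in p.nodes), source_network=0)
        tokens[r] = tokenize_sequence(walk, vocab, pad_to=max_len).token_ids
    return embed_token_sequences(model, tokens)


def _path_features_layman(paths, embeddings: pd.DataFrame) -> np.ndarray:
    return np.stack([embeddings.loc[list(p.nodes)].to_numpy().mean(axis=0) for p in paths])


def pathway_classification(
    paths: Sequence[LabeledPath],
    model=None,
    embeddings: pd.DataFrame | None = None,
    features: np.ndarray | None = None,
    folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> dict:
    """Macro one-vs-rest ROC AUC of -1/0/+1 path classification.

    Features come from, in order of precedence: ``features`` (precomputed),
    ``model`` (final [CLS] hidden state of each path run through the trained
    encoder), or ``embeddings`` (the layman baseline: mean of the path's node
    rows). Out-of-fold class probabilities are pooled across the CV and one
    ROC curve per class is computed against the rest; the macro AUC is their
    unweighted mean. A class absent from the data gets no AUC and a warning.
    """
    if features is None:
        if model is not None:
            features = _path_features_cls(paths, model)
        elif embeddings is not None:
            features = _path_features_layman(paths, embeddings)
        else:
            raise ValueError("provide features, a model, or node embeddings")
    y = np.array([p.label for p in paths])
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.zeros((len(y), classes.size))
    for train_ix, test_ix in skf.split(features, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(features[train_ix], y[train_ix])
        p = clf.predict_proba(features[test_ix])
        cols = {c: j for j, c in enumerate(clf.classes_)}
        for j, c in enumerate(classes):
            if c in cols:
                proba[test_ix, j] = p[:, cols[c]]

    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[int, float] = {}
    for j, c in enumerate(classes):
        positives = y == c
        if positives.all() or not positives.any():
            logger.warning("class %d is degenerate in the data; AUC undefined", c)
            continue
        fpr, tpr, _ = roc_curve(positives.astype(int), proba[:, j])
        curves[int(c)] = (fpr, tpr)
        aucs[int(c)] = float(auc(fpr, tpr))
    expected = {-1, 0, 1}
    absent = expected - {int(c) for c in classes}
    if absent:
        logger.warning("classes %s absent from the path data; macro over the rest", sorted(absent))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return {"macro_auc": macro, "per_class_auc": aucs, "roc_curves": curves}


def path_synthesis(
    network,
    sources: Iterable[str],
    effects: Mapping[str, str],
    max_length: int = 4,
    per_source_cap: int = 1000,
) -> list[LabeledPath]:
    """All simple paths (<= ``max_length`` edges) out of each source, labeled
    +1 / -1 when they end at a gene mapped to up / down, else 0."""
    vocab = network.vocab
    A = network.A
    labels = {"up": 1, "down": -1}
    for g, eff in effects.items():
        if eff not in labels:
            raise ValueError(f"effect for {g!r} must be 'up' or 'down', got {eff!r}")
    out: list[LabeledPath] = []
    counts = {-1: 0, 0: 0, 1: 0}
    for src in sorted(sources):
        s = vocab.index[src]
        found = 0
        stack: list[list[int]] = [[s]]
        while stack and found < per_source_cap:
            path = stack.pop()
            u = path[-1]
            for v in A.indices[A.indptr[u] : A.indptr[u + 1]][::-1]:
                if v in path:
                    continue
                new = path + [int(v)]
                name = vocab.names[v]
                label = labels.get(effects.get(name, ""), 0)
                out.append(LabeledPath(nodes=tuple(vocab.names[i] for i in new), label=label))
                counts[label] += 1
                found += 1
                if found >= per_source_cap:
                    break
                if len(new) - 1 < max_length:
                    stack.append(new)
    logger.info("path_synthesis: %d paths (+1: %d, 0: %d, -1: %d)",
                len(out), counts[1], counts[0], counts[-1])
    return out


# -- file formats ---------------------------------------------------------

def read_functional_standard(path: str | Path) -> FunctionalStandard:
    """Two-column ``gene<TAB>label`` lines, or GMT lines (set, description,
    members...) — auto-detected per line by column count."""
    labels: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                gene, lab = fields
                labels.setdefault(gene, set()).add(lab)
            elif len(fields) >= 3:
                set_name, _desc, *members = fields
                for gene in members:
                    labels.setdefault(gene, set()).add(set_name)
            else:
                raise ValueError(f"{path}: unparseable standard line {line!r}")
    return FunctionalStandard(labels=labels, source=str(path))


def read_labeled_paths(path: str | Path) -> list[LabeledPath]:
    """One path per line: space-separated gene names, TAB, label in {-1,0,1}."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            body, _, lab = line.rpartition("\t")
            out.append(LabeledPath(nodes=tuple(body.split()), label=int(lab)))
    return out


def write_labeled_paths(paths: Sequence[LabeledPath], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in paths:
            fh.write(" ".join(p.nodes) + f"\t{p.label}\n")
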