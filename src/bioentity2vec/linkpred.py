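"""Feature fusion, random-forest edge classification, and the evaluation
protocols: full k-fold cross-validation, feature ablation, training-
proportion sweep, and single-relation embedding-strategy comparison.

Each node is represented by a 128-dimensional fused vector (64 attribute
dims concatenated with 64 behavior dims); an edge sample concatenates its
two endpoint vectors in canonical node-id order into 256 features.
Positive samples are known edges; negatives are type-matched unlinked
pairs, one per positive.  A random forest with library-default
hyperparameters (and an explicit seed) scores candidate pairs.

Leakage discipline: behavior vectors are recomputed per fold on the graph
with that fold's test edges stripped; attribute vectors contain no edge
information and are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence as TySequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import attributes as attr_mod
from . import deepwalk as dw
from .attributes import Fingerprint, MeshDescriptor, Sequence
from .graph import (
    Edge,
    FoldSplit,
    HeteroGraph,
    attach_negatives,
    kfold_split,
    sample_negatives,
    strip_test_edges,
)
from .metrics import EvalReport, aggregate, evaluate

ATTR_DIM = 64
FUSED_DIM = 128
EDGE_DIM = 256
FEATURE_SETS = ("attribute", "behavior", "both")
SEQUENCE_TYPES = ("protein", "mRNA", "miRNA", "lncRNA", "circRNA")


@dataclass
class DeepWalkParams:
    gamma: int = dw.WALKS_PER_VERTEX
    t: int = dw.WALK_LENGTH
    d: int = dw.DIM
    w: int = dw.WINDOW
    epochs: int = dw.SGNS_EPOCHS


@dataclass
class ExperimentConfig:
    """Knobs shared by all protocols; defaults match the method's stated
    settings (5 folds, DeepWalk w=10/t=80/d=64, RF defaults)."""

    mode: str = "full_cv"
    feature_set: str = "both"
    folds: int = 5
    proportions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    seed: int = 0
    deepwalk: DeepWalkParams = field(default_factory=DeepWalkParams)
    rf_trees: int | None = None  # None -> sklearn default
    sae_epochs: int = 10
    shuffle_labels: bool = False  # permutation-null control

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for p in self.proportions:
            if not 0.0 < p < 1.0:
                raise ValueError(f"training proportion {p} outside (0, 1)")


# ---------------------------------------------------------------------------
# Attribute pipeline (raw payloads -> 64-dim vectors per node)
# ---------------------------------------------------------------------------


def attribute_vectors(
    graph: HeteroGraph,
    sequences: Mapping[str, Sequence] | Iterable[Sequence] = (),
    mesh: Mapping[str, TySequence[MeshDescriptor]] | None = None,
    fingerprints: Iterable[Fingerprint] = (),
    seed: int = 0,
    sae_epochs: int = 10,
) -> dict[str, np.ndarray]:
    """64-dim attribute vector per node.

    Sequence nodes get 3-mer frequency vectors (proteins through the
    4-group reduced alphabet), which are 64-dim already.  Disease and
    microbe nodes get their row of the per-category semantic-similarity
    matrix; drugs get their fingerprint bits.  Rows wider than 64 are
    compressed by a stacked autoencoder trained per attribute source; rows
    of width <= 64 are zero-padded (no compression target exists).  Nodes
    with no payload get the zero vector (attribute cold start).
    """
    from .sae import train_sae  # local import keeps module load light

    if not isinstance(sequences, Mapping):
        sequences = {s.node_id: s for s in sequences}
    mesh = mesh or {}
    fps = {f.node_id: f for f in fingerprints}

    out: dict[str, np.ndarray] = {nid: np.zeros(ATTR_DIM) for nid in graph.node_ids}

    for nid, seq in sequences.items():
        if nid not in out:
            continue
        s = attr_mod.reduce_protein_alphabet(seq) if seq.alphabet_kind == "protein" else seq
        out[nid] = attr_mod.kmer_vector(s, k=3)

    def compress(ids: list[str], raw: np.ndarray, source_seed: int) -> None:
        if raw.shape[1] > ATTR_DIM:
            model = train_sae(raw, code_dim=ATTR_DIM, epochs=sae_epochs, seed=source_seed)
            codes = model.encode(raw)
        else:
            codes = np.zeros((raw.shape[0], ATTR_DIM))
            codes[:, : raw.shape[1]] = raw
        for i, nid in enumerate(ids):
            if nid in out:
                out[nid] = codes[i]

    for off, category in enumerate(sorted(mesh)):
        descs = list(mesh[category])
        if not descs:
            continue
        ids, matrix = attr_mod.similarity_matrix(descs)
        compress(ids, matrix, seed + 100 + off)

    if fps:
        ids = sorted(fps)
        raw = np.stack([fps[i].as_array() for i in ids])
        compress(ids, raw, seed + 200)

    return out


# ---------------------------------------------------------------------------
# Fusion and edge samples
# ---------------------------------------------------------------------------


def fuse(
    attr: np.ndarray | None, behav: np.ndarray | None, feature_set: str = "both"
) -> np.ndarray:
    """Concatenate attribute || behavior into a 128-dim node vector.

    A missing source is the zero vector (cold start); ablation modes zero
    out the excluded half so the feature width is constant across modes.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    a = np.zeros(ATTR_DIM) if attr is None else np.asarray(attr, dtype=float)
    b = np.zeros(dw.DIM) if behav is None else np.asarray(behav, dtype=float)
    if a.shape != (ATTR_DIM,) or b.shape != (dw.DIM,):
        raise ValueError("attribute and behavior halves must both be 64-dim")
    if feature_set == "attribute":
        b = np.zeros_like(b)
    elif feature_set == "behavior":
        a = np.zeros_like(a)
    return np.concatenate([a, b])


def fused_table(
    node_ids: Iterable[str],
    attrs: Mapping[str, np.ndarray],
    behav: Mapping[str, np.ndarray],
    feature_set: str = "both",
) -> dict[str, np.ndarray]:
    return {
        nid: fuse(attrs.get(nid), behav.get(nid), feature_set) for nid in node_ids
    }


def make_edge_samples(
    pairs: TySequence[tuple[str, str]],
    labels: TySequence[int],
    fused: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """256-wide pair features: fused(u) || fused(v) with (u, v) in sorted
    node-id order, so samples for (a, b) and (b, a) are identical."""
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels must have equal length")
    X = np.empty((len(pairs), EDGE_DIM))
    for i, (u, v) in enumerate(pairs):
        if u > v:
            u, v = v, u
        if u not in fused or v not in fused:
            raise KeyError(f"pair ({u}, {v}) references a node without a fused vector")
        X[i, :FUSED_DIM] = fused[u]
        X[i, FUSED_DIM:] = fused[v]
    return X, np.asarray(labels, dtype=int)


def train_rf(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_trees: int | None = None
) -> RandomForestClassifier:
    """Random forest with library-default hyperparameters and explicit seed."""
    if len(set(np.unique(y))) < 2:
        raise ValueError("training labels contain a single class")
    kwargs = {} if n_trees is None else {"n_estimators": n_trees}
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **kwargs)
    clf.fit(X, y)
    return clf


def _score(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    return clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Protocol plumbing
# ---------------------------------------------------------------------------


def _zero_behavior(graph: HeteroGraph) -> dict[str, np.ndarray]:
    return {nid: np.zeros(dw.DIM) for nid in graph.node_ids}


def _behavior(graph_train: HeteroGraph, p: DeepWalkParams, seed: int) -> dict[str, np.ndarray]:
    return dw.behavior_vectors(
        graph_train, gamma=p.gamma, t=p.t, d=p.d, w=p.w, seed=seed, epochs=p.epochs
    )


def _eval_fold(
    fold: FoldSplit,
    fused: Mapping[str, np.ndarray],
    seed: int,
    rf_trees: int | None,
    shuffle_labels: bool = False,
) -> EvalReport:
    tr_pairs = [e.pair for e in fold.train_edges] + [e.pair for e in fold.negatives_train]
    tr_labels = [1] * len(fold.train_edges) + [0] * len(fold.negatives_train)
    te_pairs = [e.pair for e in fold.test_edges] + [e.pair for e in fold.negatives_test]
    te_labels = [1] * len(fold.test_edges) + [0] * len(fold.negatives_test)
    X_tr, y_tr = make_edge_samples(tr_pairs, tr_labels, fused)
    X_te, y_te = make_edge_samples(te_pairs, te_labels, fused)
    if shuffle_labels:  # permutation null: break any feature-label link
        rng = np.random.default_rng(seed * 7919 + 31 * fold.fold_index)
        y_tr = rng.permutation(y_tr)
        y_te = rng.permutation(y_te)
    clf = train_rf(X_tr, y_tr, seed=seed, n_trees=rf_trees)
    return evaluate(y_te, _score(clf, X_te))


@dataclass
class CVResult:
    """Per-fold reports plus mean +- SD aggregate for one protocol run."""

    reports: list[EvalReport]
    config: ExperimentConfig

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        return aggregate(self.reports)

    def mean(self, metric: str = "auc") -> float:
        return self.summary[metric][0]


def run_full_cv(
    graph: HeteroGraph,
    attrs: Mapping[str, np.ndarray],
    config: ExperimentConfig | None = None,
) -> CVResult:
    """k-fold CV over all positive edges with leakage-safe behavior features.

    Per fold: strip test edges -> DeepWalk on the residual graph -> fuse
    with the (edge-free) attribute vectors -> sample type-matched negatives
    -> train RF on train positives+negatives -> score the held-out
    positives+negatives.
    """
    config = config or ExperimentConfig()
    runs = run_ablation(graph, attrs, config, feature_sets=(config.feature_set,))
    return runs[config.feature_set]


def run_ablation(
    graph: HeteroGraph,
    attrs: Mapping[str, np.ndarray],
    config: ExperimentConfig | None = None,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
) -> dict[str, CVResult]:
    """Feature-importance comparison: evaluate the requested feature sets on
    identical folds, negatives and per-fold embeddings."""
    config = config or ExperimentConfig()
    folds = kfold_split(graph, k=config.folds, seed=config.seed)
    reports: dict[str, list[EvalReport]] = {fs: [] for fs in feature_sets}
    need_behavior = any(fs != "attribute" for fs in feature_sets)
    for fold in folds:
        attach_negatives(graph, fold, seed=config.seed * 1009 + 7 * fold.fold_index)
        train_g = strip_test_edges(graph, fold.test_edges)
        behav = (
            _behavior(train_g, config.deepwalk, seed=config.seed + fold.fold_index)
            if need_behavior
            else _zero_behavior(graph)
        )
        for fs in feature_sets:
            fused = fused_table(graph.node_ids, attrs, behav, fs)
            reports[fs].append(
                _eval_fold(
                    fold, fused, seed=config.seed, rf_trees=config.rf_trees,
                    shuffle_labels=config.shuffle_labels,
                )
            )
    return {
        fs: CVResult(reports[fs], replace(config, feature_set=fs)) for fs in feature_sets
    }


def run_proportion_sweep(
    graph: HeteroGraph,
    config: ExperimentConfig | None = None,
) -> dict[float, EvalReport]:
    """Behavior-only performance as a function of the training proportion.

    For each proportion p, a random p-fraction of the positive edges trains
    the embedding and the classifier; the remaining (1-p) fraction is the
    test set.  Nodes are characterized only by their behavioral feature.
    """
    config = config or ExperimentConfig(mode="proportion_sweep", feature_set="behavior")
    rng = np.random.default_rng(config.seed)
    edges = sorted(graph.edges, key=lambda e: (e.relation, e.u, e.v))
    out: dict[float, EvalReport] = {}
    for p in config.proportions:
        n_train = int(round(p * len(edges)))
        if n_train == 0 or n_train == len(edges):
            raise ValueError(f"proportion {p} leaves an empty train or test set")
        perm = rng.permutation(len(edges))
        train = [edges[i] for i in sorted(perm[:n_train].tolist())]
        test = [edges[i] for i in sorted(perm[n_train:].tolist())]
        fold = FoldSplit(0, train, test)
        attach_negatives(graph, fold, seed=config.seed * 911 + int(p * 100))
        train_g = strip_test_edges(graph, test)
        behav = _behavior(train_g, config.deepwalk, seed=config.seed)
        fused = fused_table(graph.node_ids, {}, behav, "behavior")
        out[p] = _eval_fold(fold, fused, seed=config.seed, rf_trees=config.rf_trees)
    return out


SINGLE_RELATION_MODES = (
    "attr_only",
    "attr+target_behavior",
    "global_embedding",
    "other_relations_only",
)


def _relation_subgraph(graph: HeteroGraph, keep: set[str]) -> HeteroGraph:
    edges = [e for e in graph.edges if e.relation in keep]
    return HeteroGraph(graph.nodes.values(), graph.relations.values(), edges)


def run_single_relation(
    graph: HeteroGraph,
    target_relation: str,
    mode: str,
    attrs: Mapping[str, np.ndarray] | None = None,
    config: ExperimentConfig | None = None,
) -> CVResult:
    """k-fold CV restricted to one relation under four embedding strategies.

    Modes control the graph the behavior embedding sees and which feature
    halves are active:

    * ``attr_only``         - no embedding; attribute features only.
    * ``attr+target_behavior`` - embedding on the target relation's train
      edges only; attribute + behavior features.
    * ``global_embedding``  - embedding on all relations with the fold's
      target test edges stripped; attribute + behavior features.
    * ``other_relations_only`` - embedding on every relation except the
      target (entirely); behavior features only.

    Folds and negative pairs depend only on (graph, target, seed), so the
    four modes score identical test sets with identical negatives.
    """
    if mode not in SINGLE_RELATION_MODES:
        raise ValueError(f"mode must be one of {SINGLE_RELATION_MODES}")
    if target_relation not in graph.relations:
        raise ValueError(f"unknown relation {target_relation!r}")
    config = config or ExperimentConfig(mode="single_relation")
    attrs = attrs or {}

    target_g = _relation_subgraph(graph, {target_relation})
    folds = kfold_split(target_g, k=config.folds, seed=config.seed)

    reports = []
    for fold in folds:
        # negatives: pure function of (graph, fold, seed) - mode-independent
        neg_seed = config.seed * 2003 + 13 * fold.fold_index
        fold.negatives_train = sample_negatives(graph, fold.train_edges, seed=neg_seed)
        fold.negatives_test = sample_negatives(
            graph, fold.test_edges, seed=neg_seed + 1,
            forbidden=[e.pair for e in fold.negatives_train],
        )
        dw_seed = config.seed + fold.fold_index
        if mode == "attr_only":
            behav = _zero_behavior(graph)
            feature_set = "attribute"
        elif mode == "attr+target_behavior":
            behav = _behavior(
                strip_test_edges(target_g, fold.test_edges), config.deepwalk, dw_seed
            )
            feature_set = "both"
        elif mode == "global_embedding":
            behav = _behavior(
                strip_test_edges(graph, fold.test_edges), config.deepwalk, dw_seed
            )
            feature_set = "both"
        else:  # other_relations_only
            others = set(graph.relations) - {target_relation}
            behav = _behavior(_relation_subgraph(graph, others), config.deepwalk, dw_seed)
            feature_set = "behavior"
        fused = fused_table(graph.node_ids, attrs, behav, feature_set)
        reports.append(_eval_fold(fold, fused, seed=config.seed, rf_trees=config.rf_trees))
    return CVResult(reports, replace(config, mode=f"single_relation:{mode}"))
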