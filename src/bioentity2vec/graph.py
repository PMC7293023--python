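"""Typed heterogeneous molecular association network (MAN).

A MAN is a single undirected graph whose nodes are bioentities of eight
admissible types (protein, mRNA, miRNA, lncRNA, circRNA, drug, disease,
microbe) and whose edges carry one of up to 18 relation labels, each with a
declared unordered pair of endpoint types.  This module holds the data model,
edge-list I/O, cross-validation fold splitting with test-edge stripping, and
type-matched negative sampling for the link-prediction task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NODE_TYPES = frozenset(
    {"protein", "mRNA", "miRNA", "lncRNA", "circRNA", "drug", "disease", "microbe"}
)
MAX_RELATION_TYPES = 18


class GraphError(ValueError):
    """Raised on invalid graph construction or I/O."""


@dataclass(frozen=True)
class Node:
    id: str
    type: str

    def __post_init__(self) -> None:
        if self.type not in NODE_TYPES:
            raise GraphError(f"unknown node type {self.type!r} for node {self.id!r}")


@dataclass(frozen=True)
class RelationType:
    """A relation label with its unordered endpoint-type pair."""

    label: str
    endpoint_types: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.endpoint_types
        if a not in NODE_TYPES or b not in NODE_TYPES:
            raise GraphError(f"relation {self.label!r} has unknown endpoint types {self.endpoint_types}")
        # canonical unordered storage
        if (b, a) < (a, b):
            object.__setattr__(self, "endpoint_types", (b, a))

    def matches(self, type_u: str, type_v: str) -> bool:
        return tuple(sorted((type_u, type_v))) == self.endpoint_types


def _canon_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Edge:
    """Undirected typed edge; (u, v) is stored in canonical sorted order."""

    u: str
    v: str
    relation: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise GraphError(f"self-loop on node {self.u!r} is not allowed")
        if self.v < self.u:
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.u, self.v)


class HeteroGraph:
    """Validated heterogeneous graph: typed nodes, typed undirected edges.

    Adjacency is stored once per unordered pair; symmetric queries
    (``has_edge(u, v) == has_edge(v, u)``) hold by construction.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        relations: Iterable[RelationType],
        edges: Iterable[Edge] = (),
    ) -> None:
        self.nodes: dict[str, Node] = {}
        for n in nodes:
            if n.id in self.nodes:
                if self.nodes[n.id].type != n.type:
                    raise GraphError(f"node {n.id!r} declared with conflicting types")
                continue
            self.nodes[n.id] = n
        self.relations: dict[str, RelationType] = {}
        for r in relations:
            if r.label in self.relations and self.relations[r.label] != r:
                raise GraphError(f"relation {r.label!r} declared twice with different endpoints")
            self.relations[r.label] = r
        if len(self.relations) > MAX_RELATION_TYPES:
            raise GraphError(f"more than {MAX_RELATION_TYPES} relation types declared")
        self.edges: set[Edge] = set()
        self._adj: dict[str, set[str]] = {nid: set() for nid in self.nodes}
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------

    def add_edge(self, e: Edge) -> None:
        if e.relation not in self.relations:
            raise GraphError(f"undeclared relation {e.relation!r} on edge ({e.u}, {e.v})")
        for nid in (e.u, e.v):
            if nid not in self.nodes:
                raise GraphError(f"edge ({e.u}, {e.v}) references unknown node {nid!r}")
        rel = self.relations[e.relation]
        tu, tv = self.nodes[e.u].type, self.nodes[e.v].type
        if not rel.matches(tu, tv):
            raise GraphError(
                f"edge ({e.u}, {e.v}) endpoint types ({tu}, {tv}) do not match "
                f"relation {e.relation!r} declared as {rel.endpoint_types}"
            )
        if e in self.edges:
            return  # duplicates collapse
        self.edges.add(e)
        self._adj[e.u].add(e.v)
        self._adj[e.v].add(e.u)

    # -- queries ------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def node_type(self, nid: str) -> str:
        return self.nodes[nid].type

    def nodes_of_type(self, t: str) -> list[str]:
        return sorted(nid for nid, n in self.nodes.items() if n.type == t)

    def neighbors(self, nid: str) -> set[str]:
        return self._adj[nid]

    def degree(self, nid: str) -> int:
        return len(self._adj[nid])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def positive_pairs(self) -> set[tuple[str, str]]:
        """All linked unordered pairs, relation-agnostic."""
        return {e.pair for e in self.edges}

    def edges_of_relation(self, label: str) -> list[Edge]:
        return sorted(
            (e for e in self.edges if e.relation == label),
            key=lambda e: (e.u, e.v),
        )

    def adjacency_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense symmetric boolean adjacency over ``order`` (default: sorted ids)."""
        order = list(order) if order is not None else self.node_ids
        idx = {nid: i for i, nid in enumerate(order)}
        a = np.zeros((len(order), len(order)), dtype=bool)
        for e in self.edges:
            i, j = idx[e.u], idx[e.v]
            a[i, j] = a[j, i] = True
        return a

    def copy(self) -> "HeteroGraph":
        return HeteroGraph(self.nodes.values(), self.relations.values(), self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.relations == other.relations
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"HeteroGraph({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"{len(self.relations)} relation types)"
        )


# ---------------------------------------------------------------------------
# I/O: TSV edge list + node-type manifest
# ---------------------------------------------------------------------------

EDGE_HEADER = "source\ttarget\trelation"
TYPE_HEADER = "node_id\ttype"


def read_node_types(path: str | Path) -> dict[str, str]:
    """Read a node-type manifest TSV ``node_id<TAB>type``."""
    types: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for ln, line in enumerate(lines, 1):
        if not line.strip() or (ln == 1 and line.strip() == TYPE_HEADER.replace("\t", "\t")):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "node_id":
            continue
        if len(parts) < 2:
            raise GraphError(f"{path}:{ln}: expected node_id<TAB>type")
        nid, t = parts[0], parts[1]
        if t not in NODE_TYPES:
            raise GraphError(f"{path}:{ln}: unknown node type {t!r} for node {nid!r}")
        if nid in types and types[nid] != t:
            raise GraphError(f"{path}:{ln}: node {nid!r} re-declared with type {t!r}")
        types[nid] = t
    return types


def read_edge_list(
    path: str | Path,
    node_types: Mapping[str, str],
    relations: Iterable[RelationType] | None = None,
) -> HeteroGraph:
    """Read a TSV edge list into a validated :class:`HeteroGraph`.

    Columns: ``source<TAB>target<TAB>relation`` (header optional, extra
    columns ignored).  Duplicate rows collapse; endpoint-type mismatches,
    unknown relations and dangling node references raise :class:`GraphError`
    naming the offending row.  If ``relations`` is None, relation endpoint
    types are inferred from the first row of each label.
    """
    rows: list[tuple[int, str, str, str]] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "source":
            continue
        if len(parts) < 3:
            raise GraphError(f"{path}:{ln}: expected >=3 tab-separated columns")
        rows.append((ln, parts[0], parts[1], parts[2]))

    nodes = []
    for ln, u, v, _ in rows:
        for nid in (u, v):
            if nid not in node_types:
                raise GraphError(f"{path}:{ln}: node {nid!r} missing from type manifest")
            nodes.append(Node(nid, node_types[nid]))
    # keep isolated manifest nodes too, so stripped/cold-start nodes survive I/O
    nodes.extend(Node(nid, t) for nid, t in node_types.items())

    if relations is None:
        seen: dict[str, RelationType] = {}
        for ln, u, v, rel in rows:
            pair = tuple(sorted((node_types[u], node_types[v])))
            if rel not in seen:
                seen[rel] = RelationType(rel, pair)  # type: ignore[arg-type]
        relations = seen.values()

    g = HeteroGraph(nodes, relations)
    for ln, u, v, rel in rows:
        try:
            g.add_edge(Edge(u, v, rel))
        except GraphError as err:
            raise GraphError(f"{path}:{ln}: {err}") from None
    return g


def write_edge_list(graph: HeteroGraph, path: str | Path) -> None:
    """Write the edge list deterministically (sorted by relation, then ids)."""
    lines = [EDGE_HEADER]
    for e in sorted(graph.edges, key=lambda e: (e.relation, e.u, e.v)):
        lines.append(f"{e.u}\t{e.v}\t{e.relation}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_node_types(graph: HeteroGraph, path: str | Path) -> None:
    lines = [TYPE_HEADER]
    for nid in graph.node_ids:
        lines.append(f"{nid}\t{graph.node_type(nid)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Fold splitting, stripping, negative sampling
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """One cross-validation fold over positive edges plus matched negatives."""

    fold_index: int
    train_edges: list[Edge]
    test_edges: list[Edge]
    negatives_train: list[Edge] = field(default_factory=list)
    negatives_test: list[Edge] = field(default_factory=list)


def fold_sizes(n_edges: int, k: int) -> list[int]:
    """Test-fold sizes for a k-way partition of n_edges (differ by <= 1)."""
    bounds = np.linspace(0, n_edges, k + 1).astype(int)
    return [int(b - a) for a, b in zip(bounds[:-1], bounds[1:])]


def kfold_split(graph: HeteroGraph, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Partition the positive edges into k mutually exclusive test folds.

    Fold sizes differ by at most one and the split is a pure function of
    (graph, k, seed).
    """
    if k < 2:
        raise GraphError("k must be >= 2")
    edges = sorted(graph.edges, key=lambda e: (e.relation, e.u, e.v))
    if k > len(edges):
        raise GraphError(f"k={k} exceeds number of edges ({len(edges)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    folds: list[FoldSplit] = []
    bounds = np.linspace(0, len(edges), k + 1).astype(int)
    for i in range(k):
        test_idx = set(perm[bounds[i] : bounds[i + 1]].tolist())
        test = [edges[j] for j in sorted(test_idx)]
        train = [edges[j] for j in range(len(edges)) if j not in test_idx]
        folds.append(FoldSplit(i, train, test))
    return folds


def strip_test_edges(graph: HeteroGraph, test_edges: Iterable[Edge]) -> HeteroGraph:
    """Return a copy of ``graph`` without the held-out edges.

    All nodes remain present (nodes isolated by stripping keep degree 0), so
    label information cannot leak into behavior features learned downstream.
    """
    test = set(test_edges)
    missing = test - graph.edges
    if missing:
        e = next(iter(missing))
        raise GraphError(f"test edge ({e.u}, {e.v}, {e.relation}) not in graph")
    kept = [e for e in graph.edges if e not in test]
    return HeteroGraph(graph.nodes.values(), graph.relations.values(), kept)


def sample_negatives(
    graph: HeteroGraph,
    positives: Sequence[Edge],
    seed: int = 0,
    forbidden: Iterable[tuple[str, str]] | None = None,
) -> list[Edge]:
    """Draw unlabeled node pairs as negatives, one per positive.

    Negatives are type-matched: a negative for relation ``r`` is drawn
    uniformly from unordered pairs whose endpoint types equal ``r``'s and
    which are absent from the *entire* positive edge set of ``graph`` (not
    merely the fold being sampled for), so no sampled "negative" is a
    held-out positive.  Per-relation negative counts equal per-relation
    positive counts.  Pure function of (graph, positives, seed).

    ``forbidden`` optionally excludes further pairs (e.g. negatives already
    drawn for another partition of the same fold).
    """
    rng = np.random.default_rng(seed)
    known = graph.positive_pairs()
    banned = set(known)
    if forbidden is not None:
        banned |= {_canon_pair(*p) for p in forbidden}

    counts: dict[str, int] = {}
    for e in positives:
        counts[e.relation] = counts.get(e.relation, 0) + 1

    out: list[Edge] = []
    for rel_label in sorted(counts):
        need = counts[rel_label]
        rel = graph.relations[rel_label]
        ta, tb = rel.endpoint_types
        a_nodes = graph.nodes_of_type(ta)
        b_nodes = graph.nodes_of_type(tb)
        if ta == tb:
            candidates = [
                (a_nodes[i], a_nodes[j])
                for i in range(len(a_nodes))
                for j in range(i + 1, len(a_nodes))
            ]
        else:
            candidates = [_canon_pair(a, b) for a in a_nodes for b in b_nodes]
        candidates = [p for p in candidates if p not in banned]
        if len(candidates) < need:
            raise GraphError(
                f"candidate space exhausted for relation {rel_label!r}: "
                f"need {need}, have {len(candidates)} unlinked type-matched pairs"
            )
        pick = rng.choice(len(candidates), size=need, replace=False)
        for i in sorted(pick.tolist()):
            u, v = candidates[i]
            banned.add((u, v))
            out.append(Edge(u, v, rel_label))
    return out


def attach_negatives(graph: HeteroGraph, fold: FoldSplit, seed: int) -> FoldSplit:
    """Populate a fold's train/test negative sets (train first, disjoint)."""
    fold.negatives_train = sample_negatives(graph, fold.train_edges, seed=seed)
    fold.negatives_test = sample_negatives(
        graph,
        fold.test_edges,
        seed=seed + 1,
        forbidden=[e.pair for e in fold.negatives_train],
    )
    return fold
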