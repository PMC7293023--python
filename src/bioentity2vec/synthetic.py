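"""Synthetic miniature molecular association networks with matching
attribute payloads.

The generator plants a stochastic-block co-membership signal: every node
carries a latent block label (shared across all relation types), edges form
with probability ``p_in`` between same-block endpoints and ``p_out``
otherwise, and every attribute channel (sequence composition, position in a
MeSH-like hierarchy, fingerprint template) is tilted by the same block
label.  Link prediction can therefore recover held-out edges from either
the behavior channel (DeepWalk on the residual graph) or the attribute
channel, which is exactly the structure the full pipeline is supposed to
exploit.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attributes import (
    Fingerprint,
    MeshDescriptor,
    Sequence,
    make_sequence,
    write_fasta,
    write_fingerprints,
    write_mesh_descriptors,
)
from .graph import Edge, HeteroGraph, Node, RelationType, write_edge_list, write_node_types

RNA_TYPES = ("mRNA", "miRNA", "lncRNA", "circRNA")

DEFAULT_RELATIONS: tuple[tuple[str, str, str], ...] = (
    ("drug-disease", "drug", "disease"),
    ("drug-protein", "drug", "protein"),
    ("miRNA-disease", "miRNA", "disease"),
    ("lncRNA-disease", "lncRNA", "disease"),
    ("microbe-disease", "microbe", "disease"),
    ("circRNA-mRNA", "circRNA", "mRNA"),
)

DEFAULT_SEQ_LENGTHS = {
    "protein": 300,
    "mRNA": 500,
    "miRNA": 22,
    "lncRNA": 800,
    "circRNA": 600,
}


@dataclass(frozen=True)
class RelationSpec:
    label: str
    endpoint_types: tuple[str, str]
    p_in: float = 0.3
    p_out: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """The stated world of the planted fixture.

    Defaults: 8 node types x 50 nodes, 6 relations, p_in=0.3, p_out=0.02,
    4 latent blocks (the within-pair fraction 1/4 maximizes the ideal
    separability of held-out edges from type-matched negatives at this
    p_in/p_out ratio).
    """

    nodes_per_type: dict[str, int] = field(
        default_factory=lambda: {
            t: 50
            for t in ("protein", "mRNA", "miRNA", "lncRNA", "circRNA", "drug", "disease", "microbe")
        }
    )
    relations: tuple[RelationSpec, ...] = tuple(
        RelationSpec(lbl, (a, b)) for lbl, a, b in DEFAULT_RELATIONS
    )
    n_blocks: int = 4
    seq_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SEQ_LENGTHS))
    mesh_depth: int = 4
    mesh_branching: int = 3
    fingerprint_bits: int = 1024
    fingerprint_density: float = 0.1
    seed: int = 0

    def node_ids(self, t: str) -> list[str]:
        return [f"{t}_{i:03d}" for i in range(self.nodes_per_type.get(t, 0))]

    def blocks(self) -> dict[str, int]:
        """Latent block per node: round-robin within each type."""
        out = {}
        for t in sorted(self.nodes_per_type):
            for i, nid in enumerate(self.node_ids(t)):
                out[nid] = i % self.n_blocks
        return out


# ---------------------------------------------------------------------------
# Graph
# ---------------------------------------------------------------------------


def generate_graph(spec: SyntheticSpec, seed: int | None = None) -> HeteroGraph:
    """Planted-block heterogeneous graph over the spec's types and relations."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    blocks = spec.blocks()
    nodes = [Node(nid, t) for t in sorted(spec.nodes_per_type) for nid in spec.node_ids(t)]
    relations = [RelationType(r.label, r.endpoint_types) for r in spec.relations]
    g = HeteroGraph(nodes, relations)
    for r in spec.relations:
        ta, tb = r.endpoint_types
        a_nodes, b_nodes = spec.node_ids(ta), spec.node_ids(tb)
        if ta == tb:
            pairs = [
                (a_nodes[i], a_nodes[j])
                for i in range(len(a_nodes))
                for j in range(i + 1, len(a_nodes))
            ]
        else:
            pairs = [(a, b) for a in a_nodes for b in b_nodes]
        for u, v in pairs:
            p = r.p_in if blocks[u] == blocks[v] else r.p_out
            if p > 0 and rng.random() < p:
                g.add_edge(Edge(u, v, r.label))
    return g


def expected_edge_count(spec: SyntheticSpec) -> tuple[float, float]:
    """Binomial mean and SD of the edge count under the spec."""
    mean = var = 0.0
    blocks = spec.blocks()
    for r in spec.relations:
        ta, tb = r.endpoint_types
        a_nodes, b_nodes = spec.node_ids(ta), spec.node_ids(tb)
        if ta == tb:
            pairs = [
                (a_nodes[i], a_nodes[j])
                for i in range(len(a_nodes))
                for j in range(i + 1, len(a_nodes))
            ]
        else:
            pairs = [(a, b) for a in a_nodes for b in b_nodes]
        for u, v in pairs:
            p = r.p_in if blocks[u] == blocks[v] else r.p_out
            mean += p
            var += p * (1 - p)
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def generate_sequences(
    node_ids_by_type: dict[str, list[str]],
    lengths: dict[str, int],
    seed: int = 0,
    blocks: dict[str, int] | None = None,
    concentration: float = 2.0,
) -> list[Sequence]:
    """Random sequences per node; optionally block-biased composition.

    Unbiased mode: uniform letters ({A,C,G,U} for RNA types, the 20 amino
    acids for proteins).  Biased mode (``blocks`` given): each latent block
    draws a letter distribution from a symmetric Dirichlet with the given
    concentration, and a node's sequence is i.i.d. letters from its block's
    distribution, so same-block nodes share a tilted k-mer profile.
    """
    rng = np.random.default_rng(seed)
    rna_alpha = list("ACGU")
    aa_alpha = list("ACDEFGHIKLMNPQRSTVWY")
    block_dists: dict[tuple[str, int], np.ndarray] = {}
    out: list[Sequence] = []
    for t in sorted(node_ids_by_type):
        kind = "protein" if t == "protein" else "rna"
        alpha = aa_alpha if kind == "protein" else rna_alpha
        length = lengths[t]
        for nid in node_ids_by_type[t]:
            if blocks is None:
                p = np.full(len(alpha), 1.0 / len(alpha))
            else:
                key = (kind, blocks[nid])
                if key not in block_dists:
                    block_dists[key] = rng.dirichlet(np.full(len(alpha), concentration))
                p = block_dists[key]
            letters = rng.choice(len(alpha), size=length, p=p)
            out.append(make_sequence(nid, kind, "".join(alpha[i] for i in letters)))
    return out


# ---------------------------------------------------------------------------
# MeSH-like hierarchy
# ---------------------------------------------------------------------------


def _tree_positions(category: str, n_roots: int, depth: int, branching: int) -> list[list[str]]:
    """All positions of ``n_roots`` complete trees, grouped by root."""
    groups = []
    for r in range(n_roots):
        root = f"{category}{r + 1:02d}"
        level = [root]
        positions = [root]
        for _ in range(depth):
            level = [f"{p}.{c + 1:03d}" for p in level for c in range(branching)]
            positions.extend(level)
        groups.append(positions)
    return groups


def generate_mesh_universe(
    depth: int = 4,
    branching: int = 3,
    n_entities: int = 50,
    seed: int = 0,
    category: str = "C",
    n_roots: int = 3,
) -> list[MeshDescriptor]:
    """Entities sampled as random positions of a synthetic code hierarchy."""
    rng = np.random.default_rng(seed)
    positions = [p for grp in _tree_positions(category, n_roots, depth, branching) for p in grp]
    pick = rng.choice(len(positions), size=min(n_entities, len(positions)), replace=False)
    return [
        MeshDescriptor(f"{category.lower()}ent_{i:03d}", (positions[j],))
        for i, j in enumerate(sorted(pick.tolist()))
    ]


def generate_mesh_descriptors(
    node_ids: list[str],
    blocks: dict[str, int],
    n_blocks: int,
    depth: int = 4,
    branching: int = 3,
    seed: int = 0,
    category: str = "C",
) -> list[MeshDescriptor]:
    """Block-correlated descriptors: block k lives in the k-th root subtree,
    so same-block entities share deep ancestors and high semantic similarity.
    """
    rng = np.random.default_rng(seed)
    groups = _tree_positions(category, n_blocks, depth, branching)
    out = []
    for nid in node_ids:
        grp = groups[blocks[nid] % n_blocks]
        non_root = grp[1:]
        out.append(MeshDescriptor(nid, (non_root[rng.integers(len(non_root))],)))
    return out


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


def generate_fingerprints(
    n: int | list[str],
    bits: int = 1024,
    density: float = 0.1,
    seed: int = 0,
    blocks: dict[str, int] | None = None,
    flip: float = 0.02,
) -> list[Fingerprint]:
    """Random sparse bit vectors; optionally block-templated.

    Unbiased mode: i.i.d. Bernoulli(density) bits.  Biased mode: each block
    has a Bernoulli(density) template and a node's bits are the template
    with each bit flipped with probability ``flip``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"fp_{i:03d}" for i in range(n)] if isinstance(n, int) else list(n)
    templates: dict[int, np.ndarray] = {}
    out = []
    for nid in ids:
        if blocks is None:
            v = rng.random(bits) < density
        else:
            b = blocks[nid]
            if b not in templates:
                templates[b] = rng.random(bits) < density
            v = templates[b] ^ (rng.random(bits) < flip)
        out.append(Fingerprint(nid, tuple(int(x) for x in v)))
    return out


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    spec: SyntheticSpec
    graph: HeteroGraph
    sequences: list[Sequence]
    mesh: dict[str, list[MeshDescriptor]]  # category -> descriptors
    fingerprints: list[Fingerprint]
    blocks: dict[str, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "edges.tsv",
            "types": outdir / "types.tsv",
            "seqs": outdir / "seqs.fa",
            "mesh": outdir / "mesh.tsv",
            "fp": outdir / "fp.tsv",
        }
        write_edge_list(self.graph, paths["edges"])
        write_node_types(self.graph, paths["types"])
        write_fasta(self.sequences, paths["seqs"])
        write_mesh_descriptors(
            [d for cat in sorted(self.mesh) for d in self.mesh[cat]], paths["mesh"]
        )
        write_fingerprints(self.fingerprints, paths["fp"])
        return paths


def generate_fixture(spec: SyntheticSpec | None = None, seed: int | None = None) -> FixtureBundle:
    """Mutually consistent five-part bundle: every graph node has exactly one
    attribute payload matching its type, and all channels share the planted
    block structure."""
    spec = spec or SyntheticSpec()
    seed = spec.seed if seed is None else seed
    blocks = spec.blocks()
    graph = generate_graph(spec, seed=seed)
    seq_types = {t: spec.node_ids(t) for t in ("protein",) + RNA_TYPES if t in spec.nodes_per_type}
    sequences = generate_sequences(
        seq_types, spec.seq_lengths, seed=seed + 1, blocks=blocks
    )
    mesh = {
        "disease": generate_mesh_descriptors(
            spec.node_ids("disease"), blocks, spec.n_blocks,
            depth=spec.mesh_depth, branching=spec.mesh_branching,
            seed=seed + 2, category="C",
        ),
        "microbe": generate_mesh_descriptors(
            spec.node_ids("microbe"), blocks, spec.n_blocks,
            depth=spec.mesh_depth, branching=spec.mesh_branching,
            seed=seed + 3, category="B",
        ),
    }
    fingerprints = generate_fingerprints(
        spec.node_ids("drug"), bits=spec.fingerprint_bits,
        density=spec.fingerprint_density, seed=seed + 4, blocks=blocks,
    )
    return FixtureBundle(spec, graph, sequences, mesh, fingerprints, blocks)
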