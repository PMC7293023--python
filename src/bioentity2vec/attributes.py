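"""Node attribute featurization.

Three attribute sources, one per broad entity class:

* **Sequences** (protein, mRNA, miRNA, lncRNA, circRNA): overlapping k-mer
  frequency vectors over a 4-letter alphabet.  RNA uses {A,C,G,U} directly
  (T is mapped to U on load); proteins are first reduced to a 4-letter
  alphabet by side-chain polarity so that, like RNA, k=3 yields a
  4^3 = 64-dimensional vector.
* **MeSH descriptors** (disease, microbe): each entity induces a DAG of
  hierarchy ancestors via its tree numbers; ancestor contributions decay by
  an attenuation factor Delta=0.5 per level under a max rule, and pairwise
  similarity is the shared contribution over the total contribution
  (Wang-style semantic similarity).  An entity's raw attribute vector is its
  row of the pairwise similarity matrix.
* **Fingerprints** (drug): precomputed binary bit vectors (e.g. Morgan
  fingerprints); an optional RDKit adapter converts SMILES.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TySequence

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# 4 side-chain-polarity groups covering the 20 standard residues
_PROTEIN_GROUPS = {
    **dict.fromkeys("AVLIMFWP", "1"),
    **dict.fromkeys("GSTCNQY", "2"),
    **dict.fromkeys("RKH", "3"),
    **dict.fromkeys("DE", "4"),
}
REDUCED_ALPHABET = "1234"

DELTA = 0.5  # semantic attenuation factor per hierarchy level


class AttributeError_(ValueError):
    """Raised on invalid attribute inputs."""


# ---------------------------------------------------------------------------
# Sequences and k-mers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sequence:
    """A validated biological sequence attached to a node."""

    node_id: str
    alphabet_kind: str  # "rna" | "protein"
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet_kind not in ("rna", "protein"):
            raise AttributeError_(f"unknown alphabet kind {self.alphabet_kind!r}")
        if not self.residues:
            raise AttributeError_(f"empty sequence for {self.node_id!r}")
        alpha = set(RNA_ALPHABET) if self.alphabet_kind == "rna" else AMINO_ACIDS
        for i, c in enumerate(self.residues):
            if c not in alpha:
                raise AttributeError_(
                    f"invalid residue {c!r} at position {i + 1} in {self.node_id!r}"
                )


def make_sequence(node_id: str, kind: str, residues: str) -> Sequence:
    """Normalize and validate a raw sequence (uppercase; DNA T -> U for RNA)."""
    residues = residues.upper()
    if kind == "rna":
        residues = residues.replace("T", "U")
    return Sequence(node_id, kind, residues)


def reduce_protein_alphabet(seq: Sequence) -> Sequence:
    """Map a protein sequence onto the 4 side-chain-polarity groups.

    Group 1: A,V,L,I,M,F,W,P; group 2: G,S,T,C,N,Q,Y; group 3: R,K,H;
    group 4: D,E.  Length-preserving and total on the 20 standard residues.
    """
    if seq.alphabet_kind != "protein":
        raise AttributeError_(f"{seq.node_id!r} is not a protein sequence")
    reduced = "".join(_PROTEIN_GROUPS[c] for c in seq.residues)
    # bypass residue validation: the reduced string lives in its own alphabet
    obj = object.__new__(Sequence)
    object.__setattr__(obj, "node_id", seq.node_id)
    object.__setattr__(obj, "alphabet_kind", "reduced")
    object.__setattr__(obj, "residues", reduced)
    return obj


def _alphabet_of(seq: Sequence) -> str:
    if seq.alphabet_kind == "rna":
        return RNA_ALPHABET
    if seq.alphabet_kind == "reduced":
        return REDUCED_ALPHABET
    raise AttributeError_(
        f"k-mer vectors need a 4-letter alphabet; reduce protein {seq.node_id!r} first"
    )


def kmer_vector(seq: Sequence, k: int = 3) -> np.ndarray:
    """Normalized overlapping k-mer frequencies (stride 1).

    Entry for word w = (#windows equal to w) / (L - k + 1); the vector has
    4^k entries in lexicographic word order and sums to 1 for any sequence
    of length >= k.
    """
    alpha = _alphabet_of(seq)
    s = seq.residues
    n_win = len(s) - k + 1
    if n_win < 1:
        raise AttributeError_(f"sequence {seq.node_id!r} shorter than k={k}")
    index = {c: i for i, c in enumerate(alpha)}
    vec = np.zeros(4**k)
    code = 0
    mask = 4 ** (k - 1)
    for i, c in enumerate(s):
        code = (code % mask) * 4 + index[c]
        if i >= k - 1:
            vec[code] += 1
    return vec / n_win


def kmer_index(alphabet: str, k: int = 3) -> list[str]:
    """Lexicographic word order matching :func:`kmer_vector` indices."""
    words = [""]
    for _ in range(k):
        words = [w + c for w in words for c in alphabet]
    return words


def read_fasta(path: str | Path, kinds: Mapping[str, str]) -> dict[str, Sequence]:
    """Read sequences from FASTA; ``kinds`` maps node id -> "rna"|"protein"."""
    out: dict[str, Sequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        nid = rec.id
        if nid not in kinds:
            raise AttributeError_(f"sequence {nid!r} has no declared alphabet kind")
        out[nid] = make_sequence(nid, kinds[nid], str(rec.seq))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    lines = []
    for s in sorted(seqs, key=lambda s: s.node_id):
        lines.append(f">{s.node_id}")
        lines.extend(s.residues[i : i + width] for i in range(0, len(s.residues), width))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# MeSH tree numbers and semantic similarity
# ---------------------------------------------------------------------------

_TREE_RE = re.compile(r"^[A-Z]\d{2}(\.\d{3})*$")


@dataclass(frozen=True)
class MeshDescriptor:
    """An entity located in the MeSH hierarchy by one or more tree numbers."""

    entity_id: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tree_numbers:
            raise AttributeError_(f"{self.entity_id!r} has no tree numbers")
        for t in self.tree_numbers:
            if not _TREE_RE.match(t):
                raise AttributeError_(f"malformed tree number {t!r} for {self.entity_id!r}")


def parent_tree_number(code: str) -> str | None:
    """Parent position in the hierarchy: drop the final dotted segment.

    E.g. B03.353.500 -> B03.353; a top-level code (no dot) has no parent.
    """
    if not _TREE_RE.match(code):
        raise AttributeError_(f"malformed tree number {code!r}")
    if "." not in code:
        return None
    return code.rsplit(".", 1)[0]


@dataclass
class SemanticDAG:
    """Ancestor DAG of one entity with per-position semantic contributions.

    Positions are tree numbers; ``contributions`` maps each position to its
    V value (1 for the entity's own positions, Delta * max over children for
    ancestors).  ``entity_positions`` groups positions by the entity that
    occupies them in the universe (anonymous ancestor positions, present in
    the hierarchy but matching no entity, still carry contributions).
    """

    root_entity: str
    contributions: dict[str, float] = field(default_factory=dict)
    position_entity: dict[str, str | None] = field(default_factory=dict)

    def semantic_value(self) -> float:
        return float(sum(self.contributions.values()))


def build_semantic_dag(
    entity: MeshDescriptor, universe: TySequence[MeshDescriptor]
) -> SemanticDAG:
    """Build the ancestor DAG of ``entity`` and compute contributions.

    The DAG contains every position reachable by iterated parent deletion
    from any of the entity's tree numbers.  The entity's own positions get
    V = 1; every ancestor position gets V = Delta * max(V of its children in
    the DAG), evaluated bottom-up (equivalently Delta^depth with depth the
    minimum hop count to one of the entity's positions).
    """
    ids = {u.entity_id for u in universe}
    if entity.entity_id not in ids:
        raise AttributeError_(f"entity {entity.entity_id!r} absent from universe")

    # shortest hop distance from the entity's own positions, walking parents
    depth: dict[str, int] = {}
    frontier = list(dict.fromkeys(entity.tree_numbers))
    for t in frontier:
        depth[t] = 0
    while frontier:
        nxt = []
        for t in frontier:
            p = parent_tree_number(t)
            if p is not None and (p not in depth or depth[p] > depth[t] + 1):
                depth[p] = depth[t] + 1
                nxt.append(p)
        frontier = nxt

    pos_entity: dict[str, str | None] = {t: None for t in depth}
    for u in universe:
        for t in u.tree_numbers:
            if t in pos_entity:
                pos_entity[t] = u.entity_id

    contrib = {t: DELTA**d for t, d in depth.items()}
    return SemanticDAG(entity.entity_id, contrib, pos_entity)


def semantic_value(dag: SemanticDAG) -> float:
    """Total semantic contribution SV: the sum of V over the DAG's positions."""
    return dag.semantic_value()


def semantic_similarity(i: SemanticDAG, j: SemanticDAG) -> float:
    """Shared contribution over total contribution, in [0, 1].

    similarity(i, j) = sum over shared positions of [V_i + V_j]
    divided by (SV(i) + SV(j)); symmetric; 1 for identical DAGs and 0 for
    disjoint ones.
    """
    shared = set(i.contributions) & set(j.contributions)
    if not shared:
        return 0.0
    num = sum(i.contributions[t] + j.contributions[t] for t in shared)
    return float(num / (i.semantic_value() + j.semantic_value()))


def similarity_matrix(entities: TySequence[MeshDescriptor]) -> tuple[list[str], np.ndarray]:
    """Pairwise semantic similarity; row order = input entity order.

    Each entity's raw attribute vector is its row (width = number of
    entities); it is compressed to 64 dims downstream.
    """
    if not entities:
        raise AttributeError_("need at least one entity")
    dags = [build_semantic_dag(e, entities) for e in entities]
    n = len(entities)
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = semantic_similarity(dags[a], dags[b])
    return [e.entity_id for e in entities], m


def read_mesh_descriptors(path: str | Path) -> list[MeshDescriptor]:
    """Read a descriptor TSV: ``entity_id<TAB>tree_number[;tree_number...]``."""
    out = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("entity_id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise AttributeError_(f"{path}:{ln}: expected entity_id<TAB>tree numbers")
        codes = tuple(c for c in parts[1].split(";") if c)
        out.append(MeshDescriptor(parts[0], codes))
    return out


def write_mesh_descriptors(descriptors: Iterable[MeshDescriptor], path: str | Path) -> None:
    lines = ["entity_id\ttree_numbers"]
    for d in sorted(descriptors, key=lambda d: d.entity_id):
        lines.append(f"{d.entity_id}\t{';'.join(d.tree_numbers)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    node_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise AttributeError_(f"non-binary fingerprint for {self.node_id!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.float64)


def load_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read a fingerprint TSV ``node_id<TAB>bitstring``; constant length enforced."""
    out: list[Fingerprint] = []
    length: int | None = None
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("node_id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise AttributeError_(f"{path}:{ln}: expected node_id<TAB>bitstring")
        nid, bitstr = parts[0], parts[1]
        if set(bitstr) - {"0", "1"}:
            raise AttributeError_(f"{path}:{ln}: non-binary character in fingerprint")
        if length is None:
            length = len(bitstr)
        elif len(bitstr) != length:
            raise AttributeError_(
                f"{path}:{ln}: fingerprint length {len(bitstr)} != {length}"
            )
        out.append(Fingerprint(nid, tuple(int(c) for c in bitstr)))
    return out


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> None:
    lines = ["node_id\tbits"]
    for fp in sorted(fps, key=lambda f: f.node_id):
        lines.append(f"{fp.node_id}\t{''.join(str(b) for b in fp.bits)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def smiles_to_fingerprint(node_id: str, smiles: str, n_bits: int = 1024, radius: int = 2) -> Fingerprint:
    """Optional adapter: SMILES -> Morgan fingerprint (requires rdkit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AttributeError_(f"unparseable SMILES for {node_id!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(node_id, tuple(int(fp.GetBit(i)) for i in range(n_bits)))
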