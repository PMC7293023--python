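"""Model-style front end: build a predictor from data, ``fit`` it, inspect
a results object.

``BioentityLinkPredictor`` wraps the full pipeline (attribute
featurization, per-fold DeepWalk behavior embedding, fusion, random-forest
edge classification) behind a fit/results interface.  ``fit()`` runs
leakage-safe k-fold cross-validation and returns a :class:`CVResults`
carrying per-fold metrics, their mean +- SD, and a printable summary table;
``fit()`` with ``ablation=True`` additionally fits the attribute-only and
behavior-only variants on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .attributes import Fingerprint, MeshDescriptor, Sequence
from .graph import HeteroGraph
from .linkpred import (
    CVResult,
    ExperimentConfig,
    attribute_vectors,
    run_ablation,
    run_full_cv,
    run_proportion_sweep,
    run_single_relation,
)


@dataclass
class CVResults:
    """Cross-validation results for one or more feature sets."""

    runs: dict[str, CVResult]

    def frame(self) -> pd.DataFrame:
        """Per-fold metric table, one row per (feature_set, fold)."""
        rows = []
        for fs, res in self.runs.items():
            for i, rep in enumerate(res.reports):
                rows.append({"feature_set": fs, "fold": i, **rep.as_dict()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Mean +- SD per metric and feature set, Table-style."""
        lines = []
        metrics = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")
        header = f"{'feature_set':<12}" + "".join(f"{m.upper():>16}" for m in metrics)
        lines.append(header)
        lines.append("-" * len(header))
        for fs, res in self.runs.items():
            agg = res.summary
            cells = "".join(
                f"{agg[m][0] * 100:>8.2f}±{agg[m][1] * 100:<7.2f}" for m in metrics
            )
            lines.append(f"{fs:<12}" + cells)
        return "\n".join(lines)

    def mean(self, metric: str = "auc", feature_set: str | None = None) -> float:
        fs = feature_set or next(iter(self.runs))
        return self.runs[fs].mean(metric)

    def to_json_dict(self) -> dict:
        out = {}
        for fs, res in self.runs.items():
            out[fs] = {
                "folds": [r.as_dict() for r in res.reports],
                "aggregate": {m: list(v) for m, v in res.summary.items()},
                "config": {
                    "folds": res.config.folds,
                    "seed": res.config.seed,
                    "feature_set": res.config.feature_set,
                    "mode": res.config.mode,
                    "rf_trees": res.config.rf_trees,
                    "deepwalk": vars(res.config.deepwalk),
                },
            }
        return out


class BioentityLinkPredictor:
    """Multi-type link prediction on a molecular association network.

    Parameters
    ----------
    graph
        The typed heterogeneous network.
    sequences, mesh, fingerprints
        Optional attribute payloads keyed to node ids; nodes without a
        payload fall back to zero attribute vectors.
    config
        Protocol configuration (folds, seeds, DeepWalk and RF settings).
    """

    def __init__(
        self,
        graph: HeteroGraph,
        sequences: Mapping[str, Sequence] | Iterable[Sequence] = (),
        mesh: Mapping[str, list[MeshDescriptor]] | None = None,
        fingerprints: Iterable[Fingerprint] = (),
        config: ExperimentConfig | None = None,
    ) -> None:
        self.graph = graph
        self.config = config or ExperimentConfig()
        self._sequences = sequences
        self._mesh = mesh
        self._fingerprints = list(fingerprints)
        self._attrs: dict[str, np.ndarray] | None = None

    @classmethod
    def from_files(
        cls,
        edges: str | Path,
        types: str | Path,
        fasta: str | Path | None = None,
        mesh: str | Path | None = None,
        fingerprints: str | Path | None = None,
        config: ExperimentConfig | None = None,
    ) -> "BioentityLinkPredictor":
        """Build from the five-file TSV/FASTA bundle."""
        from .attributes import read_fasta, read_mesh_descriptors, load_fingerprints
        from .graph import read_edge_list, read_node_types

        node_types = read_node_types(types)
        graph = read_edge_list(edges, node_types)
        seqs: dict[str, Sequence] = {}
        if fasta is not None:
            kinds = {
                nid: ("protein" if t == "protein" else "rna")
                for nid, t in node_types.items()
                if t in ("protein", "mRNA", "miRNA", "lncRNA", "circRNA")
            }
            seqs = read_fasta(fasta, kinds)
        mesh_by_cat: dict[str, list[MeshDescriptor]] = {}
        if mesh is not None:
            for d in read_mesh_descriptors(mesh):
                t = node_types.get(d.entity_id)
                if t in ("disease", "microbe"):
                    mesh_by_cat.setdefault(t, []).append(d)
        fps = load_fingerprints(fingerprints) if fingerprints is not None else []
        return cls(graph, seqs, mesh_by_cat, fps, config)

    @property
    def attributes(self) -> dict[str, np.ndarray]:
        """64-dim attribute vectors (computed once; edge-free, so shared
        across folds without leakage)."""
        if self._attrs is None:
            self._attrs = attribute_vectors(
                self.graph,
                self._sequences,
                self._mesh,
                self._fingerprints,
                seed=self.config.seed,
                sae_epochs=self.config.sae_epochs,
            )
        return self._attrs

    def fit(self, ablation: bool = False) -> CVResults:
        """Run k-fold cross-validation; with ``ablation`` also fit the
        attribute-only and behavior-only variants on identical folds."""
        if ablation:
            runs = run_ablation(self.graph, self.attributes, self.config)
        else:
            runs = {self.config.feature_set: run_full_cv(self.graph, self.attributes, self.config)}
        return CVResults(runs)

    def fit_proportions(self) -> pd.DataFrame:
        """Behavior-only training-proportion sweep; one row per proportion."""
        rows = []
        for p, rep in run_proportion_sweep(self.graph, self.config).items():
            rows.append({"proportion": p, **rep.as_dict()})
        return pd.DataFrame(rows)

    def fit_single_relation(self, relation: str, modes: tuple[str, ...] | None = None) -> CVResults:
        """Four-strategy comparison on one target relation."""
        from .linkpred import SINGLE_RELATION_MODES

        runs = {}
        for mode in modes or SINGLE_RELATION_MODES:
            runs[mode] = run_single_relation(
                self.graph, relation, mode, self.attributes, self.config
            )
        return CVResults(runs)
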