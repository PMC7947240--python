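"""Discriminative-feature reports, contrast overlap, and network hubs.

Outer-CV folds select different edge sets; the report aggregates them into
per-edge selection frequencies, attaches the direction of the group
difference (increased/decreased in the clinical group), and flags a top-20
display set ranked by frequency then mean |t|.  Overlap between two
contrasts (e.g. patients-vs-controls and relatives-vs-controls) is the
per-modality intersection of reported edges with direction-concordance
flags.

Hub identification is a strength-based convention — top fraction of regions
by nodal strength (sum of absolute edge weights); the underlying studies
display hubs without defining them, so every output labels this as a
convention.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CompatibilityError, ConfigError, InputError
from .pipeline import CVResult, FeatureDataset

HUB_RULE_NOTE = "hubs = top fraction of regions by nodal strength (convention; not a formal definition)"


# ---------------------------------------------------------------------------
# Feature aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureReport:
    """Per-edge selection frequency, direction and mean group difference.

    ``table`` columns: modality, edge_index, region_i, region_j, label_i,
    label_j, frequency, mean_abs_t, mean_difference, direction, display
    (True for the top-20 display set of that modality).
    """

    table: pd.DataFrame
    n_folds: int
    region_labels: tuple[str, ...]
    positive_group: str
    negative_group: str

    def display_set(self, modality: str) -> pd.DataFrame:
        return self.table[(self.table.modality == modality) & self.table.display]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_folds": self.n_folds,
                    "positive_group": self.positive_group,
                    "negative_group": self.negative_group,
                    "edges": self.table.to_dict(orient="records"),
                },
                fh, indent=2, default=str,
            )

    def edge_list(self, path: str | Path, modality: str) -> None:
        """Plain-text node-pair export consumable by connectome viewers."""
        sub = self.table[self.table.modality == modality]
        with open(path, "w") as fh:
            for _, row in sub.iterrows():
                fh.write(f"{row.label_i}\t{row.label_j}\t{row.frequency:.6g}\n")


def direction_of_change(
    features: np.ndarray,
    labels: np.ndarray,
    edge_indices: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Per-edge direction of the clinical-minus-control mean difference.

    Returns (directions, mean differences); a zero difference maps to the
    explicit direction ``"none"``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not (y == 1).any() or not (y == -1).any():
        raise InputError("both groups must be present")
    idx = np.asarray(edge_indices, dtype=int)
    diff = X[y == 1][:, idx].mean(axis=0) - X[y == -1][:, idx].mean(axis=0)
    dirs = ["increased" if d > 0 else "decreased" if d < 0 else "none" for d in diff]
    return dirs, diff


def aggregate_features(
    cv_result: CVResult,
    dataset: FeatureDataset,
    n_display: int = 20,
) -> FeatureReport:
    """Aggregate per-fold edge selections into a frequency report.

    Edges are ranked per modality by selection frequency, then mean |t|
    across the folds that selected them; the top ``n_display`` are flagged
    for display.  Edges never selected are absent.
    """
    if not cv_result.folds:
        raise InputError("CV result has no folds")
    n_folds = len(cv_result.folds)
    rows = []
    for modality in cv_result.config.modalities:
        counts: dict[int, int] = {}
        tsum: dict[int, float] = {}
        for fold in cv_result.folds:
            for e, t in zip(fold.selected_edges[modality], fold.selected_t[modality]):
                e = int(e)
                counts[e] = counts.get(e, 0) + 1
                tsum[e] = tsum.get(e, 0.0) + abs(float(t))
        edges = np.array(sorted(counts), dtype=int)
        dirs, diffs = direction_of_change(dataset.features[modality], dataset.y, edges)
        recs = []
        for e, direction, diff in zip(edges, dirs, diffs):
            i, j = dataset.edge_pairs[e]
            recs.append({
                "modality": modality,
                "edge_index": int(e),
                "region_i": int(i),
                "region_j": int(j),
                "label_i": dataset.region_labels[i],
                "label_j": dataset.region_labels[j],
                "frequency": counts[int(e)] / n_folds,
                "mean_abs_t": tsum[int(e)] / counts[int(e)],
                "mean_difference": float(diff),
                "direction": direction,
            })
        recs.sort(key=lambda r: (-r["frequency"], -r["mean_abs_t"], r["edge_index"]))
        for rank, r in enumerate(recs):
            r["display"] = rank < n_display
        rows.extend(recs)
    return FeatureReport(
        pd.DataFrame(rows), n_folds, dataset.region_labels,
        cv_result.positive_group, cv_result.negative_group,
    )


# ---------------------------------------------------------------------------
# Overlap between two contrasts
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Edges reported in both contrasts, per modality, with direction
    concordance."""

    table: pd.DataFrame
    contrast_a: str
    contrast_b: str

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def overlap_analysis(
    report_a: FeatureReport,
    report_b: FeatureReport,
    display_only: bool = True,
) -> OverlapReport:
    """Per-modality intersection of the two contrasts' reported edges.

    ``display_only`` intersects the top-20 display sets (the sets a study
    would tabulate); with False, all selected edges are intersected.
    Symmetric in its arguments up to column naming.
    """
    if tuple(report_a.region_labels) != tuple(report_b.region_labels):
        raise CompatibilityError("overlap requires the same region table in both reports")
    rows = []
    for modality in sorted(set(report_a.table.modality) & set(report_b.table.modality)):
        a = report_a.table[report_a.table.modality == modality]
        b = report_b.table[report_b.table.modality == modality]
        if display_only:
            a = a[a.display]
            b = b[b.display]
        shared = sorted(set(a.edge_index) & set(b.edge_index))
        for e in shared:
            ra = a[a.edge_index == e].iloc[0]
            rb = b[b.edge_index == e].iloc[0]
            rows.append({
                "modality": modality,
                "edge_index": int(e),
                "label_i": ra.label_i,
                "label_j": ra.label_j,
                "direction_a": ra.direction,
                "direction_b": rb.direction,
                "concordant": ra.direction == rb.direction,
            })
    columns = [
        "modality", "edge_index", "label_i", "label_j",
        "direction_a", "direction_b", "concordant",
    ]
    return OverlapReport(
        pd.DataFrame(rows, columns=columns),
        report_a.positive_group, report_b.positive_group,
    )


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------

def nodal_strength(weights: np.ndarray) -> np.ndarray:
    """Sum of absolute edge weights per region (diagonal ignored)."""
    w = np.abs(np.asarray(weights, dtype=float)).copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def identify_hubs(
    weights: np.ndarray, fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``fraction`` regions by nodal strength.

    Returns (hub region indices ranked by strength descending, ties by
    smaller index; strengths for all regions).  This strength-based rule is
    a stated convention, see :data:`HUB_RULE_NOTE`.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InputError("hub identification needs a square matrix")
    if not np.allclose(w, w.T, atol=1e-8):
        raise InputError("hub identification needs a symmetric matrix")
    strength = nodal_strength(w)
    n_hubs = max(1, math.ceil(fraction * w.shape[0]))
    order = np.lexsort((np.arange(strength.size), -strength))
    return order[:n_hubs], strength


def group_mean_network(feature_matrix: np.ndarray, n_regions: int) -> np.ndarray:
    """Mean edge-feature vector of a group folded back into a matrix."""
    from .networks import EdgeVector, devectorize, edge_pairs
    mean_edges = np.asarray(feature_matrix, dtype=float).mean(axis=0)
    ev = EdgeVector(mean_edges, edge_pairs(n_regions))
    return devectorize(ev, n_regions)
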