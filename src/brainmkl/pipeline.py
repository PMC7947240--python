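"""End-to-end classification experiments on multimodal connectome features.

The experimental contract is strict nesting: for every outer fold, edge-wise
t-tests, top-k edge selection, feature standardization and the inner-CV
choice of (beta, C) are all computed on that fold's training subjects only —
no held-out information enters any stage of model construction.  The outer
loop is leave-one-out by default (10-fold stratified CV is available), and
the seven modality-combination models (three singles, three pairs, one
triple) are run under a shared seed for comparison.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortSpec, SubjectRecord
from .exceptions import (
    CompatibilityError, ConfigError, InputError, StratificationError,
    UndefinedMetricError,
)
from .io_config import MODALITIES
from .mkl import C_GRID, MKLResults, MultiKernelSVM
from .networks import DensityEstimatorConfig, build_networks, edge_pairs, vectorize

logger = logging.getLogger("brainmkl")

#: Canonical order of the seven modality combinations (singles, pairs, all).
COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("functional",),
    ("anatomical",),
    ("morphological",),
    ("functional", "anatomical"),
    ("anatomical", "morphological"),
    ("functional", "morphological"),
    ("functional", "anatomical", "morphological"),
)


# ---------------------------------------------------------------------------
# Feature dataset
# ---------------------------------------------------------------------------

@dataclass
class FeatureDataset:
    """Edge features of a whole cohort: one (n_subjects, n_edges) matrix per
    modality over a shared edge index, plus labels and region identity."""

    features: dict[str, np.ndarray]
    y: np.ndarray                     # +1 clinical / -1 control
    groups: tuple[str, ...]
    subject_ids: tuple[str, ...]
    region_labels: tuple[str, ...]
    edge_pairs: np.ndarray            # (n_edges, 2)
    positive_group: str
    negative_group: str

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_pairs.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            {m: X[idx] for m, X in self.features.items()},
            self.y[idx],
            tuple(self.groups[i] for i in idx),
            tuple(self.subject_ids[i] for i in idx),
            self.region_labels,
            self.edge_pairs,
            self.positive_group,
            self.negative_group,
        )


def build_feature_dataset(
    cohort: Sequence[SubjectRecord],
    modalities: Sequence[str] = MODALITIES,
    region_labels: Sequence[str] | None = None,
    positive_group: str | None = None,
    control_group: str | None = None,
    density_config: DensityEstimatorConfig | None = None,
) -> FeatureDataset:
    """Construct per-subject networks and flatten them to edge features.

    ``positive_group`` defaults to the (single) non-control group; the
    control group defaults to the first group encountered.  The clinical
    group is coded +1, controls -1.
    """
    if not cohort:
        raise InputError("empty cohort")
    groups_order: list[str] = []
    for rec in cohort:
        if rec.group not in groups_order:
            groups_order.append(rec.group)
    if len(groups_order) != 2:
        raise InputError(f"classification needs exactly 2 groups, got {groups_order}")
    control = control_group if control_group is not None else groups_order[0]
    if control not in groups_order:
        raise InputError(f"control group {control!r} not in cohort")
    clinical = next(g for g in groups_order if g != control)
    if positive_group is not None:
        if positive_group not in groups_order:
            raise InputError(f"positive group {positive_group!r} not in cohort")
        clinical = positive_group
        control = next(g for g in groups_order if g != clinical)

    r = cohort[0].time_series.shape[0]
    if region_labels is None:
        from .io_config import RegionTable
        region_labels = RegionTable.default(r).labels
    pairs = edge_pairs(r)
    feats = {m: np.empty((len(cohort), pairs.shape[0])) for m in modalities}
    for si, rec in enumerate(cohort):
        nets = build_networks(rec, modalities, density_config)
        for m in modalities:
            feats[m][si] = vectorize(nets[m]).values
    y = np.array([1.0 if rec.group == clinical else -1.0 for rec in cohort])
    return FeatureDataset(
        feats, y,
        tuple(rec.group for rec in cohort),
        tuple(rec.subject_id for rec in cohort),
        tuple(region_labels), pairs, clinical, control,
    )


# ---------------------------------------------------------------------------
# Edge selection
# ---------------------------------------------------------------------------

def edge_ttests(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided pooled-variance two-sample t-test per edge (clinical vs
    control); returns (t, p) arrays."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    a = X[y == 1]
    b = X[y == -1]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InputError("each group needs >= 2 subjects for edge t-tests")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    return np.asarray(t), np.asarray(p)


def select_top_k(pvalues: np.ndarray, tstats: np.ndarray, k: int) -> np.ndarray:
    """The k edges with smallest p; ties by larger |t|, then smaller index.

    Rank-based selection is used regardless of any p threshold so every fold
    contributes the same feature dimension per modality.
    """
    if k <= 0:
        raise ConfigError(f"k must be positive, got {k}")
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(tstats, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise InputError("pvalues and tstats must be equal-length vectors")
    if k > p.size:
        raise ConfigError(f"k={k} exceeds the number of edges ({p.size})")
    # NaN p (zero-variance edges) sorts last
    p = np.where(np.isnan(p), np.inf, p)
    t = np.where(np.isnan(t), 0.0, t)
    order = np.lexsort((np.arange(p.size), -np.abs(t), p))
    return order[:k]


# ---------------------------------------------------------------------------
# Configuration / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one classification experiment."""

    modalities: tuple[str, ...] = MODALITIES
    k_edges: int = 20
    p_threshold: float = 0.001      # reporting threshold only; selection is top-k
    outer_cv: str = "loo"           # "loo" or "kfold"
    n_outer_folds: int = 10
    inner_cv_folds: int = 5
    c_policy: str = "fixed"         # "fixed" or "grid"
    c_value: float = 1.0
    grid_step: float = 0.1
    seed: int = 0
    standardize: bool = True
    positive_group: str | None = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ConfigError("modality set must be non-empty")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ConfigError(f"unknown modalities {sorted(unknown)}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ConfigError("duplicate modalities")
        if self.k_edges <= 0:
            raise ConfigError("k_edges must be positive")
        if self.outer_cv not in ("loo", "kfold"):
            raise ConfigError(f"outer_cv must be 'loo' or 'kfold', got {self.outer_cv!r}")
        if self.outer_cv == "kfold" and self.n_outer_folds < 2:
            raise ConfigError("n_outer_folds must be >= 2")
        if self.c_policy not in ("fixed", "grid"):
            raise ConfigError(f"c_policy must be 'fixed' or 'grid', got {self.c_policy!r}")

    @property
    def c_grid(self) -> tuple[float, ...]:
        return C_GRID if self.c_policy == "grid" else (self.c_value,)

    def replace(self, **kw) -> "ExperimentConfig":
        from dataclasses import replace
        return replace(self, **kw)


@dataclass
class FoldRecord:
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray
    selected_edges: dict[str, np.ndarray]
    selected_t: dict[str, np.ndarray]
    beta: np.ndarray
    C: float
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    bias: float = 0.0


@dataclass
class CVResult:
    """Per-fold predictions and selections plus the summary metric triple."""

    folds: list[FoldRecord]
    config: ExperimentConfig
    subject_ids: tuple[str, ...]
    positive_group: str
    negative_group: str

    def _stack(self) -> tuple[np.ndarray, np.ndarray]:
        y_true = np.concatenate([f.y_true for f in self.folds])
        y_pred = np.concatenate([f.y_pred for f in self.folds])
        return y_true, y_pred

    @property
    def metrics(self) -> "Metrics":
        y_true, y_pred = self._stack()
        return compute_metrics(y_true, y_pred)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def summary(self) -> str:
        m = self.metrics
        return (
            f"{'+'.join(self.config.modalities)}: "
            f"accuracy {m.accuracy:.2f}%, sensitivity {m.sensitivity:.2f}%, "
            f"specificity {m.specificity:.2f}% "
            f"({len(self.folds)} outer folds, positive={self.positive_group})"
        )

    def to_dict(self) -> dict:
        return {
            "config": {
                "modalities": list(self.config.modalities),
                "k_edges": self.config.k_edges,
                "outer_cv": self.config.outer_cv,
                "seed": self.config.seed,
            },
            "positive_group": self.positive_group,
            "negative_group": self.negative_group,
            "subject_ids": list(self.subject_ids),
            "folds": [
                {
                    "test_indices": f.test_indices.tolist(),
                    "y_true": f.y_true.tolist(),
                    "y_pred": f.y_pred.tolist(),
                    "decision": f.decision.tolist(),
                    "selected_edges": {m: v.tolist() for m, v in f.selected_edges.items()},
                    "selected_t": {m: v.tolist() for m, v in f.selected_t.items()},
                    "beta": f.beta.tolist(),
                    "C": f.C,
                    "alpha": f.alpha.tolist(),
                    "bias": f.bias,
                }
                for f in self.folds
            ],
            "metrics": self.metrics.as_dict(),
        }


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Accuracy / sensitivity (TPR on the clinical class, +1) / specificity
    (TNR on controls, -1), all in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("prediction/truth length mismatch")
    pos = y_true == 1
    neg = y_true == -1
    if not pos.any():
        raise UndefinedMetricError("no positive truth instances; sensitivity undefined")
    if not neg.any():
        raise UndefinedMetricError("no negative truth instances; specificity undefined")
    acc = 100.0 * float((y_true == y_pred).mean())
    sens = 100.0 * float((y_pred[pos] == 1).mean())
    spec = 100.0 * float((y_pred[neg] == -1).mean())
    return Metrics(acc, sens, spec)


# ---------------------------------------------------------------------------
# Fold machinery
# ---------------------------------------------------------------------------

def _outer_folds(y: np.ndarray, config: ExperimentConfig):
    n = y.shape[0]
    if config.outer_cv == "loo":
        for i in range(n):
            te = np.array([i])
            tr = np.delete(np.arange(n), i)
            yield tr, te
    else:
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(
            n_splits=config.n_outer_folds, shuffle=True, random_state=config.seed
        )
        for tr, te in skf.split(np.zeros(n), y):
            yield tr, te


def _fit_fold(
    dataset: FeatureDataset, tr: np.ndarray, config: ExperimentConfig
) -> tuple[MKLResults, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Selection + tuning + fit on the training subjects of one fold."""
    y_tr = dataset.y[tr]
    if len(np.unique(y_tr)) < 2:
        raise StratificationError("an outer training fold lost one class")
    selected: dict[str, np.ndarray] = {}
    sel_t: dict[str, np.ndarray] = {}
    train_feats = []
    for m in config.modalities:
        X = dataset.features[m]
        t, p = edge_ttests(X[tr], y_tr)
        idx = select_top_k(p, t, config.k_edges)
        weak = int((p[idx] >= config.p_threshold).sum())
        if weak:
            logger.warning(
                "%s: %d of the top %d edges have p >= %.3g in this training fold",
                m, weak, config.k_edges, config.p_threshold,
            )
        selected[m] = idx
        sel_t[m] = t[idx]
        train_feats.append(X[np.ix_(tr, idx)])

    model = MultiKernelSVM(
        y_tr, train_feats, modalities=config.modalities,
        standardize=config.standardize,
    )
    res = model.fit(
        beta=None, c_grid=config.c_grid,
        grid_step=config.grid_step, inner_cv_folds=config.inner_cv_folds,
        seed=config.seed,
    )
    return res, selected, sel_t


def run_outer_cv(dataset: FeatureDataset, config: ExperimentConfig) -> CVResult:
    """Nested outer cross-validation with training-fold-only edge selection,
    standardization and (beta, C) tuning."""
    for m in config.modalities:
        if m not in dataset.features:
            raise InputError(f"dataset lacks modality {m!r}")
        if config.k_edges > dataset.n_edges:
            raise ConfigError(f"k_edges={config.k_edges} exceeds {dataset.n_edges} edges")
    folds: list[FoldRecord] = []
    for fold_no, (tr, te) in enumerate(_outer_folds(dataset.y, config)):
        res, selected, sel_t = _fit_fold(dataset, tr, config)
        test_feats = [
            dataset.features[m][np.ix_(te, selected[m])] for m in config.modalities
        ]
        dec = res.decision_function(test_feats)
        pred = np.where(dec >= 0, 1.0, -1.0)
        folds.append(FoldRecord(
            te, dataset.y[te], pred, dec, selected, sel_t,
            res.beta, res.C, res.alpha, res.bias,
        ))
        logger.debug(
            "fold %d: beta=%s C=%g pred=%s true=%s",
            fold_no, np.array2string(res.beta, precision=2), res.C, pred, dataset.y[te],
        )
    return CVResult(
        folds, config, dataset.subject_ids, dataset.positive_group, dataset.negative_group
    )


def run_combination_suite(
    dataset: FeatureDataset, base_config: ExperimentConfig
) -> dict[tuple[str, ...], CVResult]:
    """The seven modality-combination experiments under a shared seed."""
    missing = set(MODALITIES) - set(dataset.features)
    if missing:
        raise InputError(f"dataset lacks modalities {sorted(missing)}")
    out: dict[tuple[str, ...], CVResult] = {}
    for combo in COMBINATIONS:
        cfg = base_config.replace(modalities=combo)
        out[combo] = run_outer_cv(dataset, cfg)
        logger.info(out[combo].summary())
    return out


def combination_table(results: Mapping[tuple[str, ...], CVResult]) -> pd.DataFrame:
    """One row per modality combination with the percent metric triple
    (mirrors the usual multimodal-comparison table layout)."""
    display = {"functional": "fMRI", "anatomical": "DTI", "morphological": "T1"}
    rows = []
    for combo, res in results.items():
        m = res.metrics
        rows.append({
            "modalities": " + ".join(display.get(x, x) for x in combo),
            "accuracy_pct": round(m.accuracy, 2),
            "sensitivity_pct": round(m.sensitivity, 2),
            "specificity_pct": round(m.specificity, 2),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full-cohort model + external application
# ---------------------------------------------------------------------------

@dataclass
class TrainedConnectomeClassifier:
    """A classifier trained on a full source cohort, ready to be applied to
    an independent cohort with the same region table."""

    results: MKLResults
    selected_edges: dict[str, np.ndarray]
    modalities: tuple[str, ...]
    region_labels: tuple[str, ...]
    positive_group: str
    negative_group: str

    def predict(self, external: FeatureDataset) -> np.ndarray:
        self._check_compat(external)
        feats = [
            external.features[m][:, self.selected_edges[m]] for m in self.modalities
        ]
        return self.results.predict(feats)

    def _check_compat(self, external: FeatureDataset) -> None:
        if tuple(external.region_labels) != tuple(self.region_labels):
            raise CompatibilityError("external cohort region table differs from the model's")
        missing = set(self.modalities) - set(external.features)
        if missing:
            raise CompatibilityError(f"external cohort lacks modalities {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        data = {
            "mkl": self.results.to_dict(),
            "selected_edges": {m: v.tolist() for m, v in self.selected_edges.items()},
            "modalities": list(self.modalities),
            "region_labels": list(self.region_labels),
            "positive_group": self.positive_group,
            "negative_group": self.negative_group,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedConnectomeClassifier":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            results=MKLResults.from_dict(data["mkl"]),
            selected_edges={
                m: np.asarray(v, dtype=int) for m, v in data["selected_edges"].items()
            },
            modalities=tuple(data["modalities"]),
            region_labels=tuple(data["region_labels"]),
            positive_group=data["positive_group"],
            negative_group=data["negative_group"],
        )


def fit_full_model(
    dataset: FeatureDataset, config: ExperimentConfig
) -> TrainedConnectomeClassifier:
    """Edge selection, (beta, C) tuning and the final fit on all subjects."""
    tr = np.arange(dataset.n_subjects)
    res, selected, _ = _fit_fold(dataset, tr, config)
    return TrainedConnectomeClassifier(
        res, selected, tuple(config.modalities), dataset.region_labels,
        dataset.positive_group, dataset.negative_group,
    )


def apply_to_external(
    model: TrainedConnectomeClassifier, external: FeatureDataset
) -> tuple[Metrics, np.ndarray]:
    """Apply a trained classifier to an independent cohort; features are
    standardized with the model's stored training parameters."""
    pred = model.predict(external)
    return compute_metrics(external.y, pred), pred
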