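"""Shared file formats, region tables, configuration and run manifests.

Everything on disk is plain text: square or rectangular TSV for matrices,
two/three-column TSV for region tables, YAML for configuration and JSON for
manifests.  Region indices are 1-based in files (atlas-label convention) and
0-based in memory; the conversion happens here and only here.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .exceptions import ConfigError, InputError, ParseError

MODALITIES = ("functional", "anatomical", "morphological")
#: Modality aliases accepted in configuration files (imaging-modality names).
MODALITY_ALIASES = {
    "fmri": "functional",
    "dti": "anatomical",
    "t1": "morphological",
    "smri": "morphological",
    "functional": "functional",
    "anatomical": "anatomical",
    "morphological": "morphological",
}


def canonical_modality(name: str) -> str:
    try:
        return MODALITY_ALIASES[name.strip().lower()]
    except KeyError:
        raise ConfigError(
            f"unknown modality {name!r}; expected one of {sorted(set(MODALITY_ALIASES))}"
        ) from None


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTable:
    """Ordered brain-region labels defining node identity for every network.

    The default parcellation convention has 246 regions; a smaller table is
    used for desk-scale work.  Labels must be unique; file indices start at 1.
    """

    labels: tuple[str, ...]
    subnetworks: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise InputError("a region table needs at least 2 regions")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("region labels must be unique")
        if self.subnetworks is not None and len(self.subnetworks) != len(self.labels):
            raise InputError("subnetwork column length must match labels")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @classmethod
    def default(cls, n_regions: int = 246) -> "RegionTable":
        """Synthetic numbered labels (``R001`` ...) standing in for atlas names."""
        width = max(3, len(str(n_regions)))
        return cls(tuple(f"R{i + 1:0{width}d}" for i in range(n_regions)))

    @classmethod
    def bundled(cls, n_regions: int = 246) -> "RegionTable":
        """Load one of the shipped region-table fixtures (246 regions for
        the full parcellation convention, 30 for desk-scale work).  Labels
        are synthetic numbered stand-ins, not atlas names."""
        from importlib.resources import files
        path = files("brainmkl.data") / f"regions_{n_regions}.tsv"
        if not path.is_file():
            raise ConfigError(f"no bundled region table with {n_regions} regions (have 30, 246)")
        return cls.from_tsv(str(path))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        labels: list[str] = []
        subnet: list[str] = []
        has_subnet = False
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
                try:
                    idx = int(parts[0])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer region index {parts[0]!r}") from None
                if idx != len(labels) + 1:
                    raise ParseError(
                        f"{path}:{lineno}: region indices must be contiguous from 1 (got {idx})"
                    )
                labels.append(parts[1])
                if len(parts) > 2:
                    has_subnet = True
                    subnet.append(parts[2])
                else:
                    subnet.append("")
        if not labels:
            raise ParseError(f"{path}: empty region table")
        return cls(tuple(labels), tuple(subnet) if has_subnet else None)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                if self.subnetworks is not None:
                    fh.write(f"{i + 1}\t{label}\t{self.subnetworks[i]}\n")
                else:
                    fh.write(f"{i + 1}\t{label}\n")


# ---------------------------------------------------------------------------
# Matrix TSV round-trip
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 2-D float matrix as TSV at full float precision (%.17g)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise InputError(f"expected a 2-D matrix, got ndim={matrix.ndim}")
    np.savetxt(path, matrix, delimiter="\t", fmt="%.17g")


def read_matrix_tsv(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a rectangular numeric TSV; raise :class:`ParseError` with a line
    number for ragged or non-numeric rows."""
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} cells, expected {width})"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    out = np.asarray(rows, dtype=float)
    if expected_shape is not None and out.shape != tuple(expected_shape):
        raise ParseError(
            f"{path}: shape {out.shape} does not match expected {tuple(expected_shape)}"
        )
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_COHORT_KEYS = {
    "n_regions", "group_sizes", "effect_edges", "n_timepoints",
    "n_density_samples", "noise_scale", "seed", "control_group",
}
_EXPERIMENT_KEYS = {
    "modalities", "k_edges", "p_threshold", "outer_cv", "n_outer_folds",
    "inner_cv_folds", "c_policy", "c_value", "grid_step", "seed",
    "standardize", "positive_group",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML run configuration.

    Schema: top-level keys ``cohort`` and ``experiment``; unknown keys are
    rejected.  Returns a dict with ``cohort`` (a :class:`~brainmkl.cohort.CohortSpec`)
    and ``experiment`` (an :class:`~brainmkl.pipeline.ExperimentConfig`).
    Defaults are filled by the dataclass constructors (k_edges=20, beta-grid
    step 0.1, LOOCV).
    """
    from .cohort import CohortSpec
    from .pipeline import ExperimentConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"cohort", "experiment"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")

    out: dict[str, Any] = {}
    cohort_raw = raw.get("cohort", {}) or {}
    bad = set(cohort_raw) - _COHORT_KEYS
    if bad:
        raise ConfigError(f"{path}: unknown cohort keys {sorted(bad)}")
    if "group_sizes" not in cohort_raw:
        raise ConfigError(f"{path}: cohort.group_sizes is required")
    effect_edges = {
        canonical_modality(m): [((int(i), int(j)), float(d)) for (i, j), d in
                                (((e[0], e[1]), e[2]) for e in edges)]
        for m, edges in (cohort_raw.get("effect_edges") or {}).items()
    }
    out["cohort"] = CohortSpec(
        group_sizes=dict(cohort_raw["group_sizes"]),
        n_regions=int(cohort_raw.get("n_regions", 246)),
        effect_edges=effect_edges,
        n_timepoints=int(cohort_raw.get("n_timepoints", 240)),
        n_density_samples=int(cohort_raw.get("n_density_samples", 200)),
        noise_scale=float(cohort_raw.get("noise_scale", 1.0)),
        seed=int(cohort_raw.get("seed", 0)),
        control_group=cohort_raw.get("control_group"),
    )

    exp_raw = raw.get("experiment", {}) or {}
    bad = set(exp_raw) - _EXPERIMENT_KEYS
    if bad:
        raise ConfigError(f"{path}: unknown experiment keys {sorted(bad)}")
    modalities = tuple(
        canonical_modality(m) for m in exp_raw.get("modalities", MODALITIES)
    )
    out["experiment"] = ExperimentConfig(
        modalities=modalities,
        k_edges=int(exp_raw.get("k_edges", 20)),
        p_threshold=float(exp_raw.get("p_threshold", 0.001)),
        outer_cv=str(exp_raw.get("outer_cv", "loo")),
        n_outer_folds=int(exp_raw.get("n_outer_folds", 10)),
        inner_cv_folds=int(exp_raw.get("inner_cv_folds", 5)),
        c_policy=str(exp_raw.get("c_policy", "fixed")),
        c_value=float(exp_raw.get("c_value", 1.0)),
        grid_step=float(exp_raw.get("grid_step", 0.1)),
        seed=int(exp_raw.get("seed", 0)),
        standardize=bool(exp_raw.get("standardize", True)),
        positive_group=exp_raw.get("positive_group"),
    )
    return out


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    """Inverse of :func:`load_config` (round-trips through YAML)."""
    cohort = config["cohort"]
    exp = config["experiment"]
    raw = {
        "cohort": {
            "n_regions": cohort.n_regions,
            "group_sizes": dict(cohort.group_sizes),
            "effect_edges": {
                m: [[int(i), int(j), float(d)] for (i, j), d in edges]
                for m, edges in cohort.effect_edges.items()
            },
            "n_timepoints": cohort.n_timepoints,
            "n_density_samples": cohort.n_density_samples,
            "noise_scale": cohort.noise_scale,
            "seed": cohort.seed,
            "control_group": cohort.control_group,
        },
        "experiment": {
            "modalities": list(exp.modalities),
            "k_edges": exp.k_edges,
            "p_threshold": exp.p_threshold,
            "outer_cv": exp.outer_cv,
            "n_outer_folds": exp.n_outer_folds,
            "inner_cv_folds": exp.inner_cv_folds,
            "c_policy": exp.c_policy,
            "c_value": exp.c_value,
            "grid_step": exp.grid_step,
            "seed": exp.seed,
            "standardize": exp.standardize,
            "positive_group": exp.positive_group,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run: enough to re-run bit-identically."""

    command: str
    seed: int
    config_echo: dict[str, Any] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        if p.is_file():
            self.input_checksums[str(p)] = _sha256(p)
        elif p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    self.input_checksums[str(f)] = _sha256(f)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
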