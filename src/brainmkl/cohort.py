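"""Synthetic multimodal cohorts with planted group differences.

Each subject carries three raw payloads that mirror what an MRI pipeline
would hand to the network-construction stage:

* ``density_samples`` — per-region gray-matter density samples (morphological
  modality; regions are summarized by the similarity of their density
  distributions),
* ``time_series`` — region x timepoint BOLD-like signals (functional
  modality; summarized by Pearson correlation),
* ``directed_probability`` — region x region directed connection
  probabilities in [0, 1] (anatomical modality; summarized by symmetrized
  probability).

Group differences are planted on chosen edges in standard-deviation units of
the *downstream edge feature*, so a planted effect of ``d`` means the
clinical-vs-control contrast on that edge's constructed network weight is a
Cohen's d of approximately ``d``:

* functional: the groups differ by ``d / sqrt(T - 3)`` on the Fisher-z scale,
  the sampling SD of the z-transformed sample correlation at ``T`` timepoints;
* anatomical: the Beta mean of the two directed probabilities is shifted by
  ``d * sd(Beta) / sqrt(2)`` (symmetrization averages two independent draws);
* morphological: per-subject region-mean offsets are drawn from a zero-mean
  multivariate normal; on an effect edge the two regions' offsets are given a
  correlation ``rho`` (clinical group only), solved numerically so that the
  analytic mean shift of the similarity feature equals ``d`` pooled SDs.

Non-effect edges are distributionally identical across groups: only joint
structure of the named pair changes, never any marginal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConfigError, InputError
from .io_config import MODALITIES, read_matrix_tsv, write_matrix_tsv

#: SD of the per-subject region-mean offsets, in units of the within-region
#: sample SD (``noise_scale``).  Sets the null level of the similarity
#: feature and the feasible planted-effect range (about -0.25 .. +2.7).
REGION_OFFSET_SD = 1.5
#: Base mean and concentration of the directed-probability Beta draws.
BETA_BASE_MEAN = 0.3
BETA_BASE_CONCENTRATION = 50.0

EffectEdge = tuple[tuple[int, int], float]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical spec + seed gives a
    byte-identical cohort."""

    group_sizes: Mapping[str, int]
    n_regions: int = 246
    effect_edges: Mapping[str, Sequence[EffectEdge]] = field(default_factory=dict)
    n_timepoints: int = 240
    n_density_samples: int = 200
    noise_scale: float = 1.0
    seed: int = 0
    control_group: str | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ConfigError("n_regions must be >= 2")
        if len(self.group_sizes) < 2:
            raise ConfigError("need at least 2 groups")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g!r} must have >= 2 subjects (got {n})")
        if self.n_timepoints < 4:
            raise ConfigError("n_timepoints must be >= 4")
        if self.n_density_samples < 10:
            raise ConfigError("n_density_samples must be >= 10")
        if not self.noise_scale > 0:
            raise ConfigError("noise_scale must be positive")
        ctrl = self.resolved_control_group()
        if ctrl not in self.group_sizes:
            raise ConfigError(f"control_group {ctrl!r} not among groups")
        for modality, edges in self.effect_edges.items():
            if modality not in MODALITIES:
                raise ConfigError(f"unknown modality {modality!r} in effect_edges")
            seen = set()
            for (i, j), d in edges:
                if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                    raise ConfigError(f"effect edge ({i},{j}) out of range for {self.n_regions} regions")
                if i == j:
                    raise ConfigError(f"effect edge on self-pair ({i},{i})")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise ConfigError(f"duplicate effect edge {key} in {modality}")
                seen.add(key)
                if not np.isfinite(d):
                    raise ConfigError(f"non-finite effect size on edge {key}")

    def resolved_control_group(self) -> str:
        if self.control_group is not None:
            return self.control_group
        return next(iter(self.group_sizes))

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SubjectRecord:
    """One subject's group label and the three raw modality payloads."""

    subject_id: str
    group: str
    density_samples: np.ndarray       # (n_regions, n_density_samples)
    time_series: np.ndarray           # (n_regions, n_timepoints)
    directed_probability: np.ndarray  # (n_regions, n_regions), zero diagonal

    def validate(self, spec: CohortSpec) -> None:
        r = spec.n_regions
        if self.density_samples.shape != (r, spec.n_density_samples):
            raise InputError(f"{self.subject_id}: density_samples shape {self.density_samples.shape}")
        if self.time_series.shape != (r, spec.n_timepoints):
            raise InputError(f"{self.subject_id}: time_series shape {self.time_series.shape}")
        if self.directed_probability.shape != (r, r):
            raise InputError(f"{self.subject_id}: directed_probability shape {self.directed_probability.shape}")
        if np.any(self.directed_probability < 0) or np.any(self.directed_probability > 1):
            raise InputError(f"{self.subject_id}: directed probabilities outside [0,1]")


# ---------------------------------------------------------------------------
# Effect-size calibration helpers
# ---------------------------------------------------------------------------

def _kls_feature_mean(v: float) -> float:
    # E[exp(-X^2)] for X ~ N(0, v):   1 / sqrt(1 + 2 v)
    return 1.0 / np.sqrt(1.0 + 2.0 * v)


def _kls_feature_sd(v: float) -> float:
    second = 1.0 / np.sqrt(1.0 + 4.0 * v)
    var = second - _kls_feature_mean(v) ** 2
    return float(np.sqrt(max(var, 0.0)))


def _morph_rho_for_effect(d: float, tau: float = REGION_OFFSET_SD) -> float:
    """Correlation to plant between two regions' mean offsets so the
    similarity-feature contrast is ``d`` pooled SDs.

    The feature is exp(-(eta_i - eta_j)^2 / s^2) with eta offsets of SD
    ``tau * s``; its mean and SD are available in closed form as functions of
    v = 2 tau^2 (1 - rho).  Solved by root finding; raises when ``d`` is
    outside the range the bounded similarity can express.
    """
    v0 = 2.0 * tau * tau  # rho = 0 (control)

    def gap(rho: float) -> float:
        v = 2.0 * tau * tau * (1.0 - rho)
        pooled = np.sqrt((_kls_feature_sd(v) ** 2 + _kls_feature_sd(v0) ** 2) / 2.0)
        return (_kls_feature_mean(v) - _kls_feature_mean(v0)) - d * pooled

    if d == 0.0:
        return 0.0
    lo, hi = -0.9999, 0.99999
    if gap(lo) * gap(hi) > 0:
        raise ConfigError(
            f"morphological effect size d={d} is outside the representable "
            f"range of the bounded similarity feature (about -0.25 .. +2.7 "
            f"at the default region-offset SD)"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _functional_group_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Population correlation matrix for one group's time series."""
    corr = np.eye(spec.n_regions)
    if group == spec.resolved_control_group():
        return corr
    scale = 1.0 / np.sqrt(spec.n_timepoints - 3.0)
    for (i, j), d in spec.effect_edges.get("functional", ()):
        r = np.tanh(d * scale)
        corr[i, j] = corr[j, i] = r
    return corr


def _morph_offset_cov(spec: CohortSpec, group: str) -> np.ndarray:
    tau = REGION_OFFSET_SD * spec.noise_scale
    cov = np.eye(spec.n_regions) * tau * tau
    if group != spec.resolved_control_group():
        for (i, j), d in spec.effect_edges.get("morphological", ()):
            rho = _morph_rho_for_effect(d)
            cov[i, j] = cov[j, i] = rho * tau * tau
    return cov


def _anatomical_group_mean(spec: CohortSpec, group: str) -> np.ndarray:
    """Beta mean per directed pair (shared by both directions)."""
    mu = np.full((spec.n_regions, spec.n_regions), BETA_BASE_MEAN)
    np.fill_diagonal(mu, 0.0)
    if group != spec.resolved_control_group():
        kappa = _beta_concentration(spec)
        sd_feat = np.sqrt(BETA_BASE_MEAN * (1 - BETA_BASE_MEAN) / (kappa + 1.0)) / np.sqrt(2.0)
        for (i, j), d in spec.effect_edges.get("anatomical", ()):
            m = BETA_BASE_MEAN + d * sd_feat
            if not 0.01 < m < 0.99:
                raise ConfigError(
                    f"anatomical effect d={d} pushes the Beta mean to {m:.3f}, "
                    f"outside (0.01, 0.99); reduce |d| or noise_scale"
                )
            mu[i, j] = mu[j, i] = m
    return mu


def _beta_concentration(spec: CohortSpec) -> float:
    kappa = (BETA_BASE_CONCENTRATION + 1.0) / (spec.noise_scale ** 2) - 1.0
    if kappa <= 0:
        raise ConfigError("noise_scale too large for the Beta concentration")
    return kappa


def _check_psd(matrix: np.ndarray, what: str) -> np.ndarray:
    """Validate symmetry + positive semidefiniteness; return a factor L with
    L L^T = matrix (eigendecomposition, tolerant of tiny negative eigs)."""
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InputError(f"{what}: expected a square matrix, got {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise InputError(f"{what}: matrix is not symmetric")
    w, V = np.linalg.eigh(matrix)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise InputError(
            f"{what}: matrix is not positive semidefinite (min eigenvalue "
            f"{w.min():.3e}); planted structure may be jointly inconsistent"
        )
    return V * np.sqrt(np.clip(w, 0.0, None))


def random_effect_edges(
    n_regions: int,
    n_edges: int,
    seed: int | np.random.Generator,
    effect_size: float = 2.0,
    disjoint: bool = True,
) -> list[EffectEdge]:
    """Sample region pairs to plant effects on.

    ``disjoint=True`` (default) draws pairs that share no region.  This is
    required for morphological effects: the similarity plant couples the two
    regions' mean offsets with a correlation near 1, and two such plants
    sharing a region would demand a jointly infeasible (non-PSD) offset
    covariance.  Functional and anatomical plants tolerate shared regions
    but disjoint pairs keep the planted edges statistically independent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if disjoint:
        if 2 * n_edges > n_regions:
            raise ConfigError(
                f"{n_edges} disjoint pairs need {2 * n_edges} regions, have {n_regions}"
            )
        regions = rng.permutation(n_regions)[: 2 * n_edges]
        pairs = [
            (int(min(a, b)), int(max(a, b)))
            for a, b in zip(regions[0::2], regions[1::2])
        ]
    else:
        all_pairs = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
        chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
        pairs = [all_pairs[c] for c in chosen]
    return [(p, effect_size) for p in pairs]


def planted_study_spec(
    seed: int,
    n_regions: int = 30,
    n_per_group: int = 30,
    n_effect_edges: int = 10,
    effect_size: float = 2.0,
    group_names: tuple[str, str] = ("control", "patient"),
) -> CohortSpec:
    """Desk-scale study conditions: two groups with ``n_effect_edges``
    disjoint planted edges per modality at the given effect size.

    The effect-edge sets are drawn per modality from substreams of ``seed``
    and differ across modalities, so each network type carries its own
    ground truth.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(0xE0,))
    streams = ss.spawn(len(MODALITIES))
    effects = {
        m: random_effect_edges(
            n_regions, n_effect_edges, np.random.default_rng(st),
            effect_size=effect_size,
        )
        for m, st in zip(MODALITIES, streams)
    }
    return CohortSpec(
        group_sizes={group_names[0]: n_per_group, group_names[1]: n_per_group},
        n_regions=n_regions,
        effect_edges=effects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_time_series(
    covariance: np.ndarray, n_timepoints: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a region x timepoint matrix whose columns are i.i.d. zero-mean
    multivariate normal with the given covariance."""
    covariance = np.asarray(covariance, dtype=float)
    L = _check_psd(covariance, "time-series covariance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, covariance.shape[0]))
    return (z @ L.T).T


def _generate_subject(
    spec: CohortSpec,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    cache: dict,
) -> SubjectRecord:
    r = spec.n_regions
    # functional ------------------------------------------------------------
    key = ("func", group)
    if key not in cache:
        cache[key] = _check_psd(_functional_group_correlation(spec, group), "functional correlation")
    ts = (rng.standard_normal((spec.n_timepoints, r)) @ cache[key].T).T

    # anatomical ------------------------------------------------------------
    key = ("anat", group)
    if key not in cache:
        cache[key] = _anatomical_group_mean(spec, group)
    mu = cache[key]
    kappa = _beta_concentration(spec)
    a = mu * kappa
    b = (1.0 - mu) * kappa
    off = ~np.eye(r, dtype=bool)
    directed = np.zeros((r, r))
    directed[off] = rng.beta(a[off], b[off])

    # morphological ---------------------------------------------------------
    key = ("morph", group)
    if key not in cache:
        cache[key] = _check_psd(_morph_offset_cov(spec, group), "morphological offset covariance")
    eta = cache[key] @ rng.standard_normal(r)
    density = eta[:, None] + spec.noise_scale * rng.standard_normal((r, spec.n_density_samples))

    rec = SubjectRecord(subject_id, group, density, ts, directed)
    rec.validate(spec)
    return rec


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate all subjects of a cohort.

    One master seed spawns a per-subject substream keyed by (group index,
    subject index), so a given subject's data is reproducible even when
    other groups' sizes change.
    """
    cache: dict = {}
    cohort: list[SubjectRecord] = []
    for gi, (group, n) in enumerate(spec.group_sizes.items()):
        for si in range(n):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(gi, si))
            rng = np.random.default_rng(ss)
            cohort.append(_generate_subject(spec, f"{group}_{si:03d}", group, rng, cache))
    return cohort


# ---------------------------------------------------------------------------
# On-disk layout: one directory per subject + a cohort manifest
# ---------------------------------------------------------------------------

def write_cohort(cohort: Sequence[SubjectRecord], spec: CohortSpec, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        d = out / rec.subject_id
        d.mkdir(exist_ok=True)
        write_matrix_tsv(rec.density_samples, d / "density_samples.tsv")
        write_matrix_tsv(rec.time_series, d / "time_series.tsv")
        write_matrix_tsv(rec.directed_probability, d / "directed_probability.tsv")
    manifest = {
        "subjects": [{"subject_id": r.subject_id, "group": r.group} for r in cohort],
        "spec": {
            "n_regions": spec.n_regions,
            "group_sizes": dict(spec.group_sizes),
            "effect_edges": {
                m: [[int(i), int(j), float(d)] for (i, j), d in edges]
                for m, edges in spec.effect_edges.items()
            },
            "n_timepoints": spec.n_timepoints,
            "n_density_samples": spec.n_density_samples,
            "noise_scale": spec.noise_scale,
            "seed": spec.seed,
            "control_group": spec.resolved_control_group(),
        },
    }
    with open(out / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectRecord], CohortSpec]:
    src = Path(in_dir)
    with open(src / "cohort.json") as fh:
        manifest = json.load(fh)
    s = manifest["spec"]
    spec = CohortSpec(
        group_sizes=s["group_sizes"],
        n_regions=s["n_regions"],
        effect_edges={
            m: [((int(i), int(j)), float(d)) for i, j, d in edges]
            for m, edges in s.get("effect_edges", {}).items()
        },
        n_timepoints=s["n_timepoints"],
        n_density_samples=s["n_density_samples"],
        noise_scale=s["noise_scale"],
        seed=s["seed"],
        control_group=s.get("control_group"),
    )
    cohort = []
    for entry in manifest["subjects"]:
        d = src / entry["subject_id"]
        rec = SubjectRecord(
            entry["subject_id"],
            entry["group"],
            read_matrix_tsv(d / "density_samples.tsv", (spec.n_regions, spec.n_density_samples)),
            read_matrix_tsv(d / "time_series.tsv", (spec.n_regions, spec.n_timepoints)),
            read_matrix_tsv(d / "directed_probability.tsv", (spec.n_regions, spec.n_regions)),
        )
        rec.validate(spec)
        cohort.append(rec)
    return cohort, spec
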