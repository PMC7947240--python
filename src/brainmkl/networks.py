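"""Per-subject connectivity networks and their edge-vector representation.

Three symmetric region x region networks are built per subject:

* morphological — divergence-based similarity of the regions' gray-matter
  density distributions: ``exp(-[KL(p||q) + KL(q||p)])`` on kernel-density
  estimates evaluated on a shared support grid (1 for identical
  distributions, decaying toward 0 as the distributions separate);
* functional — Pearson correlation of the regional time series (no global
  signal regression);
* anatomical — symmetrized directed connection probability
  ``(P_ij + P_ji) / 2``.

Diagonals are stored as 0 and excluded from features.  ``vectorize`` flattens
the strictly upper triangle in row-major order, giving the stable
edge <-> region-pair indexing every downstream stage shares.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .cohort import SubjectRecord
from .exceptions import InputError

_VALID_MODALITIES = ("morphological", "functional", "anatomical", "mixed")


@dataclass
class ConnectivityMatrix:
    modality: str
    weights: np.ndarray
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.modality not in _VALID_MODALITIES:
            raise InputError(f"unknown modality {self.modality!r}")
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InputError(f"connectivity matrix must be square, got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-8):
            raise InputError("connectivity matrix must be symmetric")
        if self.region_labels is not None and len(self.region_labels) != w.shape[0]:
            raise InputError("region label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class EdgeVector:
    """Strictly-upper-triangular edge weights plus the edge <-> pair map."""

    values: np.ndarray
    pairs: np.ndarray  # (n_edges, 2) with i < j, row-major triu order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.values.shape[0] != self.pairs.shape[0]:
            raise InputError("values/pairs length mismatch")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    def index_of(self, i: int, j: int) -> int:
        return edge_index(i, j, n_regions_from_edges(self.n_edges))


def n_regions_from_edges(n_edges: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise InputError(f"{n_edges} is not a valid edge count R(R-1)/2")
    return r


def edge_index(i: int, j: int, n_regions: int) -> int:
    """Row-major upper-triangle index of the pair (i, j), i != j."""
    if i == j:
        raise InputError("self-pairs are not edges")
    i, j = (i, j) if i < j else (j, i)
    if not 0 <= i < j < n_regions:
        raise InputError(f"pair ({i},{j}) out of range for {n_regions} regions")
    return i * (2 * n_regions - i - 1) // 2 + (j - i - 1)


def edge_pairs(n_regions: int) -> np.ndarray:
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


# ---------------------------------------------------------------------------
# Morphological (divergence-based similarity)
# ---------------------------------------------------------------------------

def kls_similarity(p: np.ndarray, q: np.ndarray, eps: float = 1e-10) -> float:
    """Similarity of two discrete distributions: exp of minus the symmetric
    Kullback-Leibler divergence.  1.0 iff p == q; always in (0, 1].

    Zero bins are handled by additive smoothing (``eps`` added to every bin,
    then renormalized) so the result is finite and continuous.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise InputError(f"p and q must be equal-length vectors, got {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise InputError("probability vectors must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6) or not np.isclose(q.sum(), 1.0, atol=1e-6):
        raise InputError("probability vectors must each sum to 1")
    p = p + eps
    q = q + eps
    p = p / p.sum()
    q = q / q.sum()
    sym_kl = float(np.sum((p - q) * (np.log(p) - np.log(q))))
    return float(np.exp(-sym_kl))


@dataclass(frozen=True)
class DensityEstimatorConfig:
    """KDE settings for the morphological network: Gaussian kernel, Silverman
    bandwidth, 2**7-point shared grid spanning the pooled sample range."""

    grid_size: int = 128
    bandwidth: str = "silverman"
    min_samples: int = 10
    eps: float = 1e-10


def _density_grid(samples: np.ndarray, config: DensityEstimatorConfig) -> np.ndarray:
    """Per-region discrete density distributions on a common support grid.

    ``samples`` is (n_regions, n_samples); returns (n_regions, grid_size)
    rows each summing to 1.
    """
    r = samples.shape[0]
    if samples.shape[1] < config.min_samples:
        raise InputError(
            f"need at least {config.min_samples} density samples per region, got {samples.shape[1]}"
        )
    grid = np.linspace(samples.min(), samples.max(), config.grid_size)
    dens = np.empty((r, config.grid_size))
    for i in range(r):
        row = samples[i]
        if np.ptp(row) == 0.0:
            raise InputError(
                f"region {i}: all density samples identical (zero spread); "
                f"cannot estimate a distribution"
            )
        kde = gaussian_kde(row, bw_method=config.bandwidth)
        dens[i] = kde(grid)
    total = dens.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise InputError("degenerate density estimate (all-zero mass on grid)")
    return dens / total


def morphological_network(
    subject: SubjectRecord | np.ndarray,
    config: DensityEstimatorConfig | None = None,
) -> ConnectivityMatrix:
    """Pairwise similarity of regional density distributions."""
    config = config or DensityEstimatorConfig()
    samples = subject.density_samples if isinstance(subject, SubjectRecord) else np.asarray(subject, float)
    dens = _density_grid(samples, config)
    # Pairwise symmetric KL via  D_ij = H_i + H_j - A_ij - A_ji,
    # A = P log(P)^T after smoothing; avoids an O(R^2) python loop.
    p = dens + config.eps
    p /= p.sum(axis=1, keepdims=True)
    logp = np.log(p)
    a = p @ logp.T
    h = np.diag(a)
    d = h[:, None] + h[None, :] - a - a.T
    w = np.exp(-np.maximum(d, 0.0))
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # symmetrize away rounding noise
    return ConnectivityMatrix("morphological", w)


# ---------------------------------------------------------------------------
# Functional (Pearson correlation)
# ---------------------------------------------------------------------------

def functional_network(subject: SubjectRecord | np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation of regional time series; diagonal set to 0."""
    ts = subject.time_series if isinstance(subject, SubjectRecord) else np.asarray(subject, float)
    if ts.ndim != 2:
        raise InputError("time series must be a region x timepoint matrix")
    if ts.shape[1] < 3:
        raise InputError(f"need >= 3 timepoints, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise InputError(f"region(s) {dead.tolist()} have zero temporal variance")
    w = np.corrcoef(ts)
    w = np.clip(w, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix("functional", w)


# ---------------------------------------------------------------------------
# Anatomical (symmetrized connection probability)
# ---------------------------------------------------------------------------

def anatomical_network(subject: SubjectRecord | np.ndarray) -> ConnectivityMatrix:
    """Average of the two directed connection probabilities per pair."""
    p = subject.directed_probability if isinstance(subject, SubjectRecord) else np.asarray(subject, float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise InputError(f"directed probability matrix must be square, got {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("directed probabilities must lie in [0, 1]")
    w = (p + p.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix("anatomical", w)


# ---------------------------------------------------------------------------
# Edge vectorization
# ---------------------------------------------------------------------------

def vectorize(matrix: ConnectivityMatrix | np.ndarray, atol: float = 1e-8) -> EdgeVector:
    """Flatten the strictly upper triangle, row-major; R(R-1)/2 entries."""
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InputError(f"expected a square matrix, got {w.shape}")
    if not np.allclose(w, w.T, atol=atol):
        raise InputError("matrix asymmetry exceeds tolerance; cannot vectorize")
    iu = np.triu_indices(w.shape[0], k=1)
    return EdgeVector(w[iu], np.column_stack(iu))


def devectorize(edges: EdgeVector, n_regions: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize` (diagonal restored as 0)."""
    if n_regions is None:
        n_regions = int(round((1 + np.sqrt(1 + 8 * edges.n_edges)) / 2))
    expected = n_regions * (n_regions - 1) // 2
    if edges.n_edges != expected:
        raise InputError(f"{edges.n_edges} edges does not match R={n_regions} ({expected} expected)")
    w = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    w[iu] = edges.values
    return w + w.T


NETWORK_BUILDERS = {
    "functional": functional_network,
    "anatomical": anatomical_network,
    "morphological": morphological_network,
}


def build_networks(
    subject: SubjectRecord,
    modalities=("functional", "anatomical", "morphological"),
    density_config: DensityEstimatorConfig | None = None,
) -> dict[str, ConnectivityMatrix]:
    out = {}
    for m in modalities:
        if m == "morphological":
            out[m] = morphological_network(subject, density_config)
        else:
            out[m] = NETWORK_BUILDERS[m](subject)
    return out
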