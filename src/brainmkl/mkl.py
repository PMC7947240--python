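"""Simplex-weighted multi-kernel soft-margin SVM.

One linear kernel per imaging modality is mixed into a single precomputed
kernel ``K = sum_m beta_m K_m`` with non-negative weights constrained to the
probability simplex (``sum beta_m = 1``).  The mixed kernel is handed to a
standard soft-margin SVM dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C,

solved by sequential minimal optimization (SMO) over maximal-KKT-violating
pairs.  The decision value for a test sample is
``f(x) = sum_i y_i a_i sum_m beta_m k_m(x_i, x) + b`` and the predicted label
is its sign (an exact 0 predicts the positive class).  With a single
modality, or beta at a simplex vertex, the machine reduces exactly to a
conventional single-kernel SVM.

The kernel weights are not optimized jointly with the dual: they are chosen
by a coarse grid search over the 0.1-step simplex lattice via stratified
inner cross-validation on the training samples, then frozen before the final
fit.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, InputError, SolverError

_DEFAULT_TOL = 1e-6
_DEFAULT_MAX_ITER = 100_000
#: Inner-CV C candidates when C selection is enabled (2^-5 .. 2^5, odd powers).
C_GRID = tuple(2.0 ** e for e in (-5, -3, -1, 1, 3, 5))


# ---------------------------------------------------------------------------
# SMO core (numba-jitted when available; identical arithmetic either way)
# ---------------------------------------------------------------------------

def _smo_kernel(K, y, C, tol, max_iter):  # pragma: no cover - thin numeric core
    n = K.shape[0]
    alpha = np.zeros(n)
    # G_i = d(1/2 a^T Q a - sum a)/d a_i with Q_ij = y_i y_j K_ij
    G = -np.ones(n)
    it = 0
    gmax = 0.0
    gmin = 0.0
    while it < max_iter:
        gmax = -1e300
        gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * G[t]
            up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            low = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if up and v > gmax:
                gmax = v
                i = t
            if low and v < gmin:
                gmin = v
                j = t
        if gmax - gmin < tol or i < 0 or j < 0:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < 1e-12:
            eta = 1e-12
        # step s moves alpha_i by +y_i s and alpha_j by -y_j s
        s = (gmax - gmin) / eta
        if y[i] > 0:
            lo_i = -alpha[i]
            hi_i = C - alpha[i]
        else:
            lo_i = alpha[i] - C
            hi_i = alpha[i]
        if y[j] > 0:
            lo_j = alpha[j] - C
            hi_j = alpha[j]
        else:
            lo_j = -alpha[j]
            hi_j = C - alpha[j]
        lo = lo_i if lo_i > lo_j else lo_j
        hi = hi_i if hi_i < hi_j else hi_j
        if s > hi:
            s = hi
        if s < lo:
            s = lo
        dai = y[i] * s
        daj = -y[j] * s
        alpha[i] += dai
        alpha[j] += daj
        for t in range(n):
            G[t] += y[t] * (y[i] * K[t, i] * dai + y[j] * K[t, j] * daj)
        it += 1
    # bias from unbounded support vectors, averaged; midpoint fallback
    nfree = 0
    bsum = 0.0
    for t in range(n):
        if 1e-9 * C < alpha[t] < C * (1.0 - 1e-9):
            bsum += -y[t] * G[t]
            nfree += 1
    if nfree > 0:
        b = bsum / nfree
    else:
        b = (gmax + gmin) / 2.0
    return alpha, b, gmax - gmin, it


try:  # numba accelerates the pairwise loop ~100x; results are identical
    from numba import njit

    _smo_compiled = njit(cache=False, fastmath=False)(_smo_kernel)
except Exception:  # pragma: no cover - exercised only without numba
    _smo_compiled = _smo_kernel


def solve_dual(
    kernel: np.ndarray,
    labels: Sequence[int],
    C: float,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, float]:
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Returns ``(alpha, bias)`` with ``0 <= alpha_i <= C`` and
    ``sum alpha_i y_i = 0``; raises :class:`SolverError` if the maximal KKT
    violation is still above ``tol`` after ``max_iter`` pair updates.
    """
    K = np.ascontiguousarray(kernel, dtype=float)
    y = np.asarray(labels, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError(f"kernel must be square, got {K.shape}")
    if y.shape != (K.shape[0],):
        raise InputError("labels length must match kernel size")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InputError("labels must be +1/-1")
    if np.all(y == y[0]):
        raise InputError("training requires both classes present")
    if not C > 0:
        raise ConfigError("C must be positive")
    alpha, b, viol, it = _smo_compiled(K, y, float(C), float(tol), int(max_iter))
    if it >= max_iter and viol >= tol:
        raise SolverError(
            f"SMO did not converge in {max_iter} iterations "
            f"(final KKT violation {viol:.3e}, tol {tol:.1e})"
        )
    return alpha, float(b)


def dual_objective(alpha: np.ndarray, kernel: np.ndarray, labels: np.ndarray) -> float:
    ay = alpha * labels
    return float(alpha.sum() - 0.5 * ay @ kernel @ ay)


# ---------------------------------------------------------------------------
# Kernels, mixing, standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature z-scoring with parameters fitted on training data only.

    Features with zero spread are centered and left unscaled (they then
    contribute nothing to a linear kernel).
    """

    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise InputError("Standardizer used before fit")
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def linear_kernel(
    features_a: np.ndarray,
    features_b: np.ndarray | None = None,
    standardizer: Standardizer | None = None,
) -> np.ndarray:
    """Inner-product kernel between two stacks of feature vectors.

    If a fitted :class:`Standardizer` is given both sides are transformed
    with it (training-fold parameters) before the product.
    """
    A = np.asarray(features_a, dtype=float)
    B = A if features_b is None else np.asarray(features_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise InputError(f"feature dimension mismatch: {A.shape} vs {B.shape}")
    if standardizer is not None:
        A = standardizer.transform(A)
        B = standardizer.transform(B)
    return A @ B.T


def validate_simplex(beta: Sequence[float], atol: float = 1e-8) -> np.ndarray:
    b = np.asarray(beta, dtype=float)
    if b.ndim != 1 or b.size == 0:
        raise InputError("kernel weights must be a non-empty vector")
    if np.any(b < -atol) or abs(b.sum() - 1.0) > atol:
        raise InputError(f"kernel weights must be on the probability simplex, got {b}")
    return np.clip(b, 0.0, None)


def mix_kernels(kernels: Sequence[np.ndarray], beta: Sequence[float]) -> np.ndarray:
    """Convex combination ``sum_m beta_m K_m`` (PSD when the inputs are)."""
    b = validate_simplex(beta)
    if len(kernels) != b.size:
        raise InputError(f"{len(kernels)} kernels but {b.size} weights")
    shapes = {np.asarray(k).shape for k in kernels}
    if len(shapes) != 1:
        raise InputError(f"kernel shape mismatch: {shapes}")
    out = np.zeros(shapes.pop())
    for w, k in zip(b, kernels):
        out += w * np.asarray(k, dtype=float)
    return out


def simplex_grid(n_modalities: int, step: float = 0.1) -> np.ndarray:
    """All weight vectors on the simplex lattice with the given step
    (66 points for 3 modalities at step 0.1)."""
    if n_modalities < 1:
        raise ConfigError("need at least one modality")
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ConfigError(f"step {step} must divide 1 exactly")
    grids = [
        np.array(c, dtype=float) / units
        for c in _compositions(units, n_modalities)
    ]
    return np.array(grids)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head,) + rest


# ---------------------------------------------------------------------------
# Decision values
# ---------------------------------------------------------------------------

def decision_value(
    alpha: np.ndarray,
    bias: float,
    labels: np.ndarray,
    test_kernels: Sequence[np.ndarray],
    beta: Sequence[float],
) -> np.ndarray:
    """``f(x) = sum_i y_i a_i sum_m beta_m k_m(x_i, x) + b`` per test sample.

    ``test_kernels[m]`` holds the m-th modality kernel rows between test
    samples and the stored training samples, shape (n_test, n_train).
    """
    b = validate_simplex(beta)
    if len(test_kernels) != b.size:
        raise InputError(
            f"{len(test_kernels)} test kernels but {b.size} modality weights"
        )
    mixed = mix_kernels(test_kernels, b)
    if mixed.shape[1] != alpha.shape[0]:
        raise InputError("test kernel columns must align with training samples")
    return mixed @ (alpha * labels) + bias


def predict_label(decision: np.ndarray) -> np.ndarray:
    """Sign of the decision value; an exact 0 predicts +1 by convention."""
    return np.where(np.asarray(decision) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# Grid search over (beta, C)
# ---------------------------------------------------------------------------

def grid_search(
    features_per_modality: Sequence[np.ndarray],
    labels: np.ndarray,
    grid_step: float = 0.1,
    c_grid: Sequence[float] = (1.0,),
    inner_cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-4,
) -> tuple[np.ndarray, float, float]:
    """Coarse grid search for the kernel weights (and optionally C) by
    stratified inner cross-validation on the training samples.

    Returns ``(beta, C, mean_inner_accuracy)``.  Ties in mean accuracy are
    broken toward smaller C, then the most uniform beta (minimum variance),
    then lexicographically — a fixed, modality-neutral rule.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=float)
    betas = simplex_grid(len(features_per_modality), grid_step)
    c_grid = tuple(c_grid)
    if len(c_grid) == 0:
        raise ConfigError("empty C grid")
    if len(betas) == 1 and len(c_grid) == 1:
        return betas[0], c_grid[0], float("nan")

    n = y.shape[0]
    counts = min(int((y == 1).sum()), int((y == -1).sum()))
    n_folds = min(inner_cv_folds, counts)
    if n_folds < 2:
        raise InputError("need >= 2 samples per class for inner cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    correct = np.zeros((len(betas), len(c_grid)))
    total = 0
    for tr, va in skf.split(np.zeros(n), y):
        k_tr, k_va = [], []
        for X in features_per_modality:
            std = Standardizer().fit(X[tr]) if standardize else None
            k_tr.append(linear_kernel(X[tr], standardizer=std))
            k_va.append(linear_kernel(X[va], X[tr], standardizer=std))
        k_tr = np.ascontiguousarray(k_tr)
        k_va = np.ascontiguousarray(k_va)
        y_tr = y[tr]
        total += va.size
        for bi, beta in enumerate(betas):
            # mix + compiled core directly; validation already done above
            K = np.ascontiguousarray(np.tensordot(beta, k_tr, axes=1))
            Kv = np.tensordot(beta, k_va, axes=1)
            for ci, C in enumerate(c_grid):
                alpha, b, viol, it = _smo_compiled(K, y_tr, float(C), float(tol), _DEFAULT_MAX_ITER)
                if viol >= tol and it >= _DEFAULT_MAX_ITER:
                    raise SolverError(f"inner-CV fit failed to converge (violation {viol:.2e})")
                pred = predict_label(Kv @ (alpha * y_tr) + b)
                correct[bi, ci] += int((pred == y[va]).sum())
    acc = correct / total
    best = acc.max()
    cands = [
        (c_grid[ci], float(np.var(betas[bi])), tuple(betas[bi]), bi, ci)
        for bi in range(len(betas))
        for ci in range(len(c_grid))
        if acc[bi, ci] >= best - 1e-12
    ]
    cands.sort()
    _, _, _, bi, ci = cands[0]
    return betas[bi], c_grid[ci], float(acc[bi, ci])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MultiKernelSVM:
    """Multi-kernel SVM on per-modality edge-feature matrices.

    Parameters
    ----------
    labels : array of +1/-1 per training sample.
    features_per_modality : one (n_samples, n_features_m) matrix per
        modality, in a fixed modality order shared with prediction.
    standardize : z-score each feature with training-sample statistics
        before the linear kernel (recommended; prevents any one edge from
        dominating the inner products).
    """

    def __init__(
        self,
        labels: Sequence[int],
        features_per_modality: Sequence[np.ndarray],
        modalities: Sequence[str] | None = None,
        standardize: bool = True,
    ) -> None:
        self.y = np.asarray(labels, dtype=float)
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise InputError("labels must be +1/-1")
        if np.all(self.y == self.y[0]):
            raise InputError("both classes must be present")
        self.features = [np.asarray(X, dtype=float) for X in features_per_modality]
        if not self.features:
            raise InputError("at least one modality is required")
        for X in self.features:
            if X.ndim != 2 or X.shape[0] != self.y.shape[0]:
                raise InputError("each modality needs one feature row per sample")
        self.modalities = (
            tuple(modalities) if modalities is not None
            else tuple(f"modality_{i}" for i in range(len(self.features)))
        )
        if len(self.modalities) != len(self.features):
            raise InputError("modality names must match feature blocks")
        self.standardize = standardize

    @property
    def n_modalities(self) -> int:
        return len(self.features)

    def fit(
        self,
        beta: Sequence[float] | None = None,
        C: float | None = None,
        *,
        c_grid: Sequence[float] | None = None,
        grid_step: float = 0.1,
        inner_cv_folds: int = 5,
        seed: int = 0,
        tol: float = _DEFAULT_TOL,
    ) -> "MKLResults":
        """Fit the dual on the mixed kernel.

        ``beta=None`` triggers the coarse inner-CV grid search; ``C=None``
        with ``c_grid=None`` uses the default C=1 (the grid in ``C_GRID`` can
        be passed for inner-CV selection of C as well).
        """
        inner_acc = float("nan")
        if beta is None:
            cg = tuple(c_grid) if c_grid is not None else ((C,) if C is not None else (1.0,))
            beta, C, inner_acc = grid_search(
                self.features, self.y,
                grid_step=grid_step, c_grid=cg,
                inner_cv_folds=inner_cv_folds, seed=seed,
                standardize=self.standardize,
            )
        beta = validate_simplex(beta)
        if beta.size != self.n_modalities:
            raise InputError("beta length must equal the number of modalities")
        if C is None:
            C = 1.0

        standardizers = []
        grams = []
        for X in self.features:
            std = Standardizer().fit(X) if self.standardize else None
            standardizers.append(std)
            grams.append(linear_kernel(X, standardizer=std))
        mixed = mix_kernels(grams, beta)
        alpha, bias = solve_dual(mixed, self.y, C, tol=tol)
        return MKLResults(
            model=self, alpha=alpha, bias=bias, beta=beta, C=float(C),
            standardizers=standardizers, inner_cv_accuracy=inner_acc, tol=tol,
        )


@dataclass
class MKLResults:
    """A fitted multi-kernel SVM: dual coefficients, bias, kernel weights.

    Carries the training features (through ``model``) and the fitted
    standardization parameters, so it is self-contained for prediction on
    new cohorts and for serialization.
    """

    model: MultiKernelSVM
    alpha: np.ndarray
    bias: float
    beta: np.ndarray
    C: float
    standardizers: list[Standardizer | None]
    inner_cv_accuracy: float = float("nan")
    tol: float = _DEFAULT_TOL

    # -- prediction ---------------------------------------------------------
    def test_kernels(self, features_per_modality: Sequence[np.ndarray]) -> list[np.ndarray]:
        if len(features_per_modality) != self.model.n_modalities:
            raise InputError(
                f"expected {self.model.n_modalities} modality blocks, "
                f"got {len(features_per_modality)}"
            )
        return [
            linear_kernel(Xt, Xtr, standardizer=std)
            for Xt, Xtr, std in zip(features_per_modality, self.model.features, self.standardizers)
        ]

    def decision_function(self, features_per_modality: Sequence[np.ndarray]) -> np.ndarray:
        return decision_value(
            self.alpha, self.bias, self.model.y,
            self.test_kernels(features_per_modality), self.beta,
        )

    def predict(self, features_per_modality: Sequence[np.ndarray]) -> np.ndarray:
        return predict_label(self.decision_function(features_per_modality))

    # -- diagnostics --------------------------------------------------------
    @property
    def n_support(self) -> int:
        return int((self.alpha > 1e-9 * self.C).sum())

    @property
    def dual_feasibility_gap(self) -> float:
        return float(abs((self.alpha * self.model.y).sum()))

    def dual_objective(self) -> float:
        grams = [
            linear_kernel(X, standardizer=std)
            for X, std in zip(self.model.features, self.standardizers)
        ]
        return dual_objective(self.alpha, mix_kernels(grams, self.beta), self.model.y)

    def kkt_violation(self) -> float:
        """Maximal complementary-slackness violation over the training set."""
        f = self.decision_function(self.model.features)
        y = self.model.y
        margin = y * f
        viol = np.zeros_like(margin)
        at_zero = self.alpha <= 1e-9 * self.C
        at_cap = self.alpha >= self.C * (1 - 1e-9)
        free = ~(at_zero | at_cap)
        viol[at_zero] = np.maximum(0.0, 1.0 - margin[at_zero])
        viol[free] = np.abs(1.0 - margin[free])
        viol[at_cap] = np.maximum(0.0, margin[at_cap] - 1.0)
        return float(viol.max()) if viol.size else 0.0

    def summary(self) -> str:
        lines = [
            "Multi-kernel SVM results",
            "=" * 38,
            f"training samples        {self.model.y.size:>8d}",
            f"modalities              {', '.join(self.model.modalities)}",
            f"kernel weights (beta)   {np.array2string(self.beta, precision=3)}",
            f"soft-margin C           {self.C:>8g}",
            f"support vectors         {self.n_support:>8d}",
            f"bias (b)                {self.bias:>12.6f}",
            f"dual objective          {self.dual_objective():>12.6f}",
            f"|sum alpha_i y_i|       {self.dual_feasibility_gap:>12.3e}",
            f"max KKT violation       {self.kkt_violation():>12.3e}",
        ]
        if np.isfinite(self.inner_cv_accuracy):
            lines.append(f"inner-CV accuracy       {self.inner_cv_accuracy:>12.4f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "beta": self.beta.tolist(),
            "C": self.C,
            "labels": self.model.y.tolist(),
            "modalities": list(self.model.modalities),
            "standardize": self.model.standardize,
            "training_features": [X.tolist() for X in self.model.features],
            "standardizer_means": [
                None if s is None else s.mean.tolist() for s in self.standardizers
            ],
            "standardizer_scales": [
                None if s is None else s.scale.tolist() for s in self.standardizers
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MKLResults":
        model = MultiKernelSVM(
            np.asarray(data["labels"], dtype=float),
            [np.asarray(X, dtype=float) for X in data["training_features"]],
            modalities=data["modalities"],
            standardize=data["standardize"],
        )
        standardizers: list[Standardizer | None] = []
        for m, s in zip(data["standardizer_means"], data["standardizer_scales"]):
            if m is None:
                standardizers.append(None)
            else:
                std = Standardizer()
                std.mean = np.asarray(m, dtype=float)
                std.scale = np.asarray(s, dtype=float)
                standardizers.append(std)
        return cls(
            model=model,
            alpha=np.asarray(data["alpha"], dtype=float),
            bias=float(data["bias"]),
            beta=np.asarray(data["beta"], dtype=float),
            C=float(data["C"]),
            standardizers=standardizers,
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "MKLResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
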