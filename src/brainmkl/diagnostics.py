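"""Independent audit tools for the SVM dual solver.

Two reference routes that share no code with the SMO path:

* :func:`brute_force_dual` — equality-constraint-eliminated grid search with
  iterative refinement (vectorized; practical for n <= 6),
* :func:`active_set_dual` — exact solution of the concave QP by enumerating
  all 3^n active-set assignments (each alpha at 0, at C, or free) and
  solving the KKT system for each feasible one.

Both maximize the same dual objective
``sum a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij`` under ``sum a_i y_i = 0`` and
``0 <= a_i <= C``; they exist to check the production solver, never to
replace it.
"""
from __future__ import annotations

import itertools

import numpy as np

from .exceptions import InputError


def _objective_batch(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    # A: (batch, n) candidate alphas; Q = yy^T * K
    return A.sum(axis=1) - 0.5 * np.einsum("bi,ij,bj->b", A, Q, A)


def brute_force_dual(
    kernel: np.ndarray,
    labels: np.ndarray,
    C: float,
    levels: int = 4,
    base_points: int = 11,
    refine_points: int = 21,
    max_batch: int = 2_000_000,
) -> tuple[float, np.ndarray]:
    """Grid-search maximization of the SVM dual for tiny problems.

    The equality constraint eliminates the last variable:
    ``a_n = -y_n sum_{i<n} a_i y_i`` (infeasible grid points are masked).
    A coarse grid over ``[0, C]^(n-1)`` is refined ``levels`` times around
    the incumbent, each level shrinking the step by the refinement factor,
    so the final objective is within ~1e-4 of the optimum for n <= 6, C ~ 1.

    Returns (best objective, best alpha).
    """
    K = np.asarray(kernel, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = y.size
    if n < 2 or n > 7:
        raise InputError("brute-force oracle is for 2 <= n <= 7")
    Q = np.outer(y, y) * K
    d = n - 1

    lo = np.zeros(d)
    hi = np.full(d, C)
    points = base_points
    best_obj = -np.inf
    best_alpha = None
    for level in range(levels):
        axes = [np.linspace(lo[k], hi[k], points) for k in range(d)]
        best_level = -np.inf
        best_point = None
        for chunk in _grid_chunks(axes, max_batch):
            a_last = -y[-1] * (chunk * y[:-1]).sum(axis=1)
            feas = (a_last >= -1e-12) & (a_last <= C + 1e-12)
            if not feas.any():
                continue
            A = np.column_stack([chunk[feas], np.clip(a_last[feas], 0.0, C)])
            obj = _objective_batch(A, Q)
            k = int(np.argmax(obj))
            if obj[k] > best_level:
                best_level = float(obj[k])
                best_point = A[k]
        if best_point is None:
            raise InputError("no feasible grid point; check labels")
        if best_level > best_obj:
            best_obj = best_level
            best_alpha = best_point
        # refine around the incumbent: window of +-1 current step per axis
        step = (hi - lo) / (points - 1)
        center = best_alpha[:-1]
        lo = np.clip(center - step, 0.0, C)
        hi = np.clip(center + step, 0.0, C)
        points = refine_points
    return best_obj, best_alpha


def _grid_chunks(axes: list[np.ndarray], max_batch: int):
    sizes = [a.size for a in axes]
    total = int(np.prod(sizes))
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])
    for start in range(0, total, max_batch):
        yield flat[start:start + max_batch]


def active_set_dual(
    kernel: np.ndarray, labels: np.ndarray, C: float
) -> tuple[float, np.ndarray]:
    """Exact dual optimum by enumeration of active sets (concave QP).

    For each assignment of every sample to {alpha=0, alpha=C, free}, solve
    the stationarity system for the free alphas and the multiplier of the
    equality constraint; keep feasible solutions and return the best.
    """
    K = np.asarray(kernel, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = y.size
    if n > 10:
        raise InputError("active-set enumeration is exponential; use n <= 10")
    Q = np.outer(y, y) * K
    best_obj = -np.inf
    best_alpha = None
    for assign in itertools.product((0, 1, 2), repeat=n):
        alpha = np.zeros(n)
        fixed_c = [i for i, a in enumerate(assign) if a == 1]
        free = [i for i, a in enumerate(assign) if a == 2]
        alpha[fixed_c] = C
        if free:
            # stationarity: Q_ff a_f + Q_fc a_c - 1 + mu * y_f = 0
            # equality:     y_f a_f = -y_c a_c
            m = len(free)
            lhs = np.zeros((m + 1, m + 1))
            lhs[:m, :m] = Q[np.ix_(free, free)]
            lhs[:m, m] = y[free]
            lhs[m, :m] = y[free]
            rhs = np.zeros(m + 1)
            rhs[:m] = 1.0 - Q[np.ix_(free, fixed_c)] @ alpha[fixed_c] if fixed_c else 1.0
            rhs[m] = -float(y[fixed_c] @ alpha[fixed_c]) if fixed_c else 0.0
            try:
                sol = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(sol)):
                continue
            alpha[free] = sol[:m]
            if np.any(alpha[free] < -1e-9) or np.any(alpha[free] > C + 1e-9):
                continue
        if abs(float(alpha @ y)) > 1e-8 * max(1.0, C * n):
            continue
        obj = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)
        if obj > best_obj:
            best_obj = obj
            best_alpha = np.clip(alpha, 0.0, C)
    if best_alpha is None:
        raise InputError("no feasible active set; check labels")
    return best_obj, best_alpha
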