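"""Independent LP oracle: a dense Bland's-rule primal simplex.

This is a deliberately separate route to the optimum of the ellipsoid
separation LP: the tableau is assembled here directly from the deviation
constants (its own variable ordering and sign conventions, upper bounds as
explicit rows) and solved by a textbook single-phase primal simplex --
feasible from the start because every right-hand side is non-negative and
the origin satisfies all constraints. Bland's anti-cycling rule guarantees
termination. No scipy involvement.
"""

from __future__ import annotations

import numpy as np


def simplex_min(c: np.ndarray, A: np.ndarray, b: np.ndarray,
                max_iter: int = 20000) -> tuple[float, np.ndarray]:
    """Minimise c@x subject to A@x <= b, x >= 0, with b >= 0.

    Returns (objective, x). Raises RuntimeError on an unbounded ray or
    iteration overrun.
    """
    c = np.asarray(c, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if (b < 0).any():
        raise ValueError("this simplex requires b >= 0 (origin-feasible form)")
    n_rows, n_cols = A.shape
    # tableau over structural + slack columns
    T = np.zeros((n_rows + 1, n_cols + n_rows + 1))
    T[:n_rows, :n_cols] = A
    T[:n_rows, n_cols:n_cols + n_rows] = np.eye(n_rows)
    T[:n_rows, -1] = b
    T[-1, :n_cols] = c
    basis = list(range(n_cols, n_cols + n_rows))

    for _ in range(max_iter):
        reduced = T[-1, :-1]
        entering_candidates = np.flatnonzero(reduced < -1e-10)
        if entering_candidates.size == 0:
            x = np.zeros(n_cols + n_rows)
            x[basis] = T[:n_rows, -1]
            return float(-T[-1, -1]), x[:n_cols]
        e = int(entering_candidates[0])  # Bland: smallest index
        col = T[:n_rows, e]
        rows = np.flatnonzero(col > 1e-10)
        if rows.size == 0:
            raise RuntimeError("LP is unbounded along entering column")
        ratios = T[rows, -1] / col[rows]
        best = ratios.min()
        # Bland tie-break: smallest basis variable index among minimal ratios
        tied = rows[np.flatnonzero(ratios <= best + 1e-12)]
        leave = int(min(tied, key=lambda r: basis[r]))
        piv = T[leave, e]
        T[leave, :] /= piv
        for r in range(n_rows + 1):
            if r != leave and T[r, e] != 0.0:
                T[r, :] -= T[r, e] * T[leave, :]
        basis[leave] = e
    raise RuntimeError("simplex iteration limit exceeded")


def solve_selection_lp_oracle(
    deviations: np.ndarray,
    in_class: np.ndarray,
    lambda_: float,
    alpha: float,
    penalty_C: float,
    n_edge_features: int,
) -> float:
    """Optimal objective of the ellipsoid separation LP, assembled here.

    Variable order (different from the package's): per-class blocks first
    [Z1_1..Z1_K, Z2_1..Z2_K], then eta (class-major), then w. Upper bounds
    w <= 1 become explicit rows.
    """
    D = np.asarray(deviations, dtype=float)
    in_class = np.asarray(in_class, dtype=bool)
    m, q, K = D.shape
    p = n_edge_features

    def z1(k):
        return k

    def z2(k):
        return K + k

    def eta(j, k):
        return 2 * K + k * m + j

    def wvar(i):
        return 2 * K + m * K + i

    n_vars = 2 * K + m * K + q
    c = np.zeros(n_vars)
    for k in range(K):
        c[z1(k)] = alpha
        c[z2(k)] = -alpha
    for k in range(K):
        for j in range(m):
            c[eta(j, k)] = penalty_C
    for i in range(q):
        c[wvar(i)] = 1.0 if i < p else lambda_

    rows = []
    rhs = []
    for k in range(K):
        for j in range(m):
            row = np.zeros(n_vars)
            if in_class[j, k]:
                for i in range(q):
                    row[wvar(i)] = D[j, i, k]
                row[z1(k)] = -1.0
                row[eta(j, k)] = -1.0
            else:
                for i in range(q):
                    row[wvar(i)] = -D[j, i, k]
                row[z2(k)] = 1.0
                row[eta(j, k)] = -1.0
            rows.append(row)
            rhs.append(0.0)
    for k in range(K):
        row = np.zeros(n_vars)
        row[z1(k)] = 1.0
        row[z2(k)] = -1.0
        rows.append(row)
        rhs.append(0.0)
    for i in range(q):  # w_i <= 1
        row = np.zeros(n_vars)
        row[wvar(i)] = 1.0
        rows.append(row)
        rhs.append(1.0)
    obj, _ = simplex_min(c, np.asarray(rows), np.asarray(rhs))
    return obj


def random_selection_instance(rng: np.random.Generator):
    """Random bounded small instance: (D, in_class, params dict)."""
    m = int(rng.integers(4, 13))
    q = int(rng.integers(1, 7))
    p = int(rng.integers(0, q + 1))
    K = 2
    # membership with both classes non-empty
    labels = np.zeros(m, dtype=int)
    labels[rng.permutation(m)[: int(rng.integers(1, m))] ] = 1
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    in_class = np.zeros((m, K), dtype=bool)
    in_class[np.arange(m), labels] = True
    D = rng.exponential(scale=2.0, size=(m, q, K))
    params = {
        "lambda_": float(rng.uniform(0.5, 2.0)),
        # penalty_C >= 1 >= alpha keeps every instance bounded
        "alpha": float(rng.uniform(0.02, 1.0)),
        "penalty_C": float(rng.uniform(1.0, 100.0)),
    }
    return D, in_class, params, p
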