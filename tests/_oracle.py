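"""Brute-force LP oracle: exhaustive vertex enumeration.

Independent of the package's solver path: enumerates every basic
feasible point of {x : A x = b, lb <= x <= ub} by fixing n - rank(A)
variables at a bound and solving the remaining square system.  Only
usable for tiny fixtures (n <= ~10), which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(A, b, lb, ub, tol=1e-8):
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = A.shape
    rank = np.linalg.matrix_rank(A) if A.size else 0
    vertices = []
    for basic in itertools.combinations(range(n), rank):
        basic = list(basic)
        nonbasic = [j for j in range(n) if j not in basic]
        A_B = A[:, basic]
        if np.linalg.matrix_rank(A_B) < rank:
            continue
        for pattern in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.empty(n)
            for j, at_ub in zip(nonbasic, pattern):
                x[j] = ub[j] if at_ub else lb[j]
            rhs = b - A[:, nonbasic] @ x[nonbasic] if nonbasic else b
            sol, *_ = np.linalg.lstsq(A_B, rhs, rcond=None)
            x[basic] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            vertices.append(np.clip(x, lb, ub))
    if not vertices:
        return np.empty((0, n))
    V = np.array(vertices)
    # deduplicate
    keep = []
    for v in V:
        if not any(np.allclose(v, w, atol=1e-7) for w in keep):
            keep.append(v)
    return np.array(keep)


def oracle_fba(S, lb, ub, c):
    """(optimum, argmax vertex) of max c.x over {S x = 0, lb <= x <= ub}."""
    V = enumerate_vertices(S, np.zeros(S.shape[0]), lb, ub)
    if V.size == 0:
        return None, None
    vals = V @ c
    i = int(np.argmax(vals))
    return float(vals[i]), V[i]


def oracle_fva(S, lb, ub, c, opt, tol=1e-7):
    """Per-variable min/max over the optimal face, via vertex enumeration
    of the polytope augmented with the optimality equality."""
    A = np.vstack([S, c[None, :]])
    b = np.concatenate([np.zeros(S.shape[0]), [opt]])
    V = enumerate_vertices(A, b, lb, ub)
    assert V.size, "optimal face unexpectedly empty"
    return V.min(axis=0), V.max(axis=0)
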