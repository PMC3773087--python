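"""Brute-force LP oracle for small flux polytopes.

Independent of the solver under test: enumerates every basic solution of
{v : S v = 0, lb <= v <= ub} (choose n - rank(S) variables pinned at a
bound, solve the square system for the rest) and evaluates the objective at
each feasible vertex.  Exponential, usable only for networks with about a
dozen reactions.
"""

from __future__ import annotations

import itertools

import numpy as np

FEAS_TOL = 1e-8


def _independent_rows(S: np.ndarray) -> np.ndarray:
    rows: list[np.ndarray] = []
    rank = 0
    for row in S:
        candidate = rows + [row]
        if np.linalg.matrix_rank(np.array(candidate)) > rank:
            rows.append(row)
            rank += 1
    return np.array(rows) if rows else S[:0]


def enumerate_vertices(S, lb, ub) -> list[np.ndarray]:
    """All basic feasible solutions of S v = 0, lb <= v <= ub."""
    S = _independent_rows(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape if S.size else (0, len(lb))
    vertices: list[np.ndarray] = []
    if m == 0:
        for pattern in itertools.product(*[(lo, hi) for lo, hi in zip(lb, ub)]):
            vertices.append(np.array(pattern))
        return vertices
    for basis in itertools.combinations(range(n), m):
        SB = S[:, basis]
        if np.linalg.matrix_rank(SB) < m:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            vN = np.array(pattern)
            rhs = -S[:, nonbasic] @ vN if nonbasic else np.zeros(m)
            vB = np.linalg.solve(SB, rhs)
            v = np.empty(n)
            v[list(basis)] = vB
            v[nonbasic] = vN
            if np.all(v >= lb - FEAS_TOL) and np.all(v <= ub + FEAS_TOL):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def brute_force_optimum(model, objective_id: str, sense: str, fixed=None):
    """Optimal objective value over all enumerated vertices, or None if the
    polytope has no feasible vertex."""
    from electroflux import stoichiometric_matrix

    fixed = fixed or {}
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    ids = [r.id for r in model.reactions]
    for rid, value in fixed.items():
        j = ids.index(rid)
        lb[j] = ub[j] = value
    j_obj = ids.index(objective_id)
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    values = [v[j_obj] for v in vertices]
    return max(values) if sense == "maximize" else min(values)
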