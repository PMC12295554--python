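"""Independent LP oracle: exhaustive basic-solution (vertex) enumeration.

For a bounded flux polytope {v : S v = 0, lb <= v <= ub} every LP optimum is
attained at a vertex, i.e. a basic solution: choose rank(S) basic columns,
pin every nonbasic variable at one of its bounds, and solve the square
system.  Enumerating all bases x bound assignments visits every vertex, so
the maximum objective over feasible enumerated points equals the LP optimum.
Deliberately brute force and solver-free - usable only for tiny models
(<= 12 reactions) but trustworthy as ground truth.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import qr

FEAS_TOL = 1e-7


def enumerate_optimum(S, lb, ub, c, sense="maximize"):
    """Return (status, optimum) by exhaustive vertex enumeration.

    status is "optimal" or "infeasible"; optimum is the best c.v over all
    feasible vertices (None when infeasible).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    sign = 1.0 if sense == "maximize" else -1.0

    r = np.linalg.matrix_rank(S, tol=1e-10) if S.size else 0
    if r == 0:
        # box only: optimize each coordinate independently
        v = np.where(sign * c >= 0, ub, lb)
        return "optimal", float(c @ v)

    # row basis of S via column-pivoted QR of S^T
    _, _, piv = qr(S.T, pivoting=True)
    S_red = S[piv[:r], :]

    best = None
    for basis in itertools.combinations(range(n), r):
        B = np.array(basis)
        N = np.array([j for j in range(n) if j not in basis])
        S_B = S_red[:, B]
        if abs(np.linalg.det(S_B)) < 1e-12:
            continue
        S_B_inv = np.linalg.inv(S_B)
        k = len(N)
        if k:
            # all 2^k assignments of nonbasic variables to their bounds
            choices = np.array(list(itertools.product([0, 1], repeat=k)))
            X_N = np.where(choices == 0, lb[N], ub[N])  # (2^k, k)
            X_B = -(S_B_inv @ (S_red[:, N] @ X_N.T)).T  # (2^k, r)
        else:
            X_N = np.zeros((1, 0))
            X_B = np.zeros((1, r))
        feas = np.all((X_B >= lb[B] - FEAS_TOL) & (X_B <= ub[B] + FEAS_TOL), axis=1)
        if not feas.any():
            continue
        obj = X_B[feas] @ c[B] + (X_N[feas] @ c[N] if k else 0.0)
        cand = float((sign * obj).max())
        if best is None or cand > best:
            best = cand
    if best is None:
        return "infeasible", None
    return "optimal", sign * best


def enumerate_model_optimum(model, sense="maximize"):
    """Vertex-enumeration optimum for a MetabolicModel's declared objective."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_reaction_id)] = 1.0
    return enumerate_optimum(S, lb, ub, c, sense=sense)
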