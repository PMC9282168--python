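"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the non-negative
sparse-coding solution is found by enumerating support patterns, and LCA
fixed points are characterised directly by their KKT conditions.
"""

import itertools

import numpy as np


def nnsc_active_set(A: np.ndarray, I: np.ndarray, beta: float) -> np.ndarray:
    """Brute-force solution of min_s 0.5||I - A s||^2 + beta * sum(s),
    s >= 0, by enumeration over active sets.

    The LCA fixed point u* = A^T I - (A^T A - Id) s*, s* = max(u* - beta,
    0) satisfies exactly these KKT conditions: a_j^T (I - A s) = beta on
    the active set and <= beta elsewhere.
    """
    n = A.shape[1]
    best_s, best_obj = np.zeros(n), 0.5 * float(I @ I)
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            P = list(support)
            G = A[:, P].T @ A[:, P]
            rhs = A[:, P].T @ I - beta
            try:
                sP = np.linalg.solve(G, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(sP <= 0):
                continue
            s = np.zeros(n)
            s[P] = sP
            resid = I - A @ s
            grad = A.T @ resid
            if np.any(grad[[j for j in range(n) if j not in support]]
                      > beta + 1e-9):
                continue
            obj = 0.5 * float(resid @ resid) + beta * float(s.sum())
            if obj < best_obj - 1e-12:
                best_s, best_obj = s, obj
    return best_s
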