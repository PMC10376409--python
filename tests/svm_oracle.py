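"""Brute-force maximum-margin linear classifier for tiny 2-D instances.

Independent oracle for the package's linear SVM: enumerate every candidate
support-vector subset (size 2 or 3 in two dimensions), solve the KKT
equality system exactly, keep the feasible candidate with the largest
geometric margin.  Only valid for linearly separable data.
"""

from itertools import combinations

import numpy as np


def hard_margin_svm_2d(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Return ``(w, b, margin)`` of the max-margin separator.

    ``y`` must be in {-1, +1} and the classes linearly separable; raises if
    no feasible candidate subset exists.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(X)
    best = None
    for k in (2, 3):
        for S in combinations(range(n), k):
            ys = y[list(S)]
            if len(np.unique(ys)) < 2:
                continue
            Xs = X[list(S)]
            # unknowns: alpha_1..alpha_k, b
            # equations: y_i (sum_j alpha_j y_j x_j.x_i + b) = 1  (i in S)
            #            sum_j alpha_j y_j = 0
            G = (ys[:, None] * ys[None, :]) * (Xs @ Xs.T)
            A = np.zeros((k + 1, k + 1))
            A[:k, :k] = G
            A[:k, k] = ys
            A[k, :k] = ys
            rhs = np.concatenate([np.ones(k), [0.0]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            alpha, b = sol[:k], sol[k]
            if np.any(alpha < -1e-9):
                continue
            w = (alpha * ys) @ Xs
            if np.any(y * (X @ w + b) < 1 - 1e-6):
                continue
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                continue
            margin = 1.0 / norm
            if best is None or margin > best[2] + 1e-12:
                best = (w, b, margin)
    if best is None:
        raise ValueError("no feasible max-margin separator (data not separable?)")
    return best
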