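"""Independent oracles shared across test modules.

These are deliberately written without using any partworth internals so
they can serve as cross-checks on the package's own code paths.
"""

import numpy as np


def oracle_conditional_logit(X, chosen, tol=1e-12, max_iter=200):
    """Plain pooled conditional-logit fit by full Newton iteration.

    X: (T, A, P) effects-coded alternatives; chosen: (T,) 0-based.
    Returns (beta, loglik) at the maximum-likelihood solution.
    """
    T, A, P = X.shape
    beta = np.zeros(P)
    for _ in range(max_iter):
        u = np.einsum("tap,p->ta", X, beta)
        u -= u.max(axis=1, keepdims=True)
        e = np.exp(u)
        p = e / e.sum(axis=1, keepdims=True)
        xbar = np.einsum("ta,tap->tp", p, X)
        grad = (X[np.arange(T), chosen] - xbar).sum(axis=0)
        hess = np.zeros((P, P))
        for t in range(T):
            hess += (X[t].T * p[t]) @ X[t] - np.outer(xbar[t], xbar[t])
        beta = beta + np.linalg.solve(hess + 1e-12 * np.eye(P), grad)
        if np.abs(grad).max() < tol:
            break
    u = np.einsum("tap,p->ta", X, beta)
    ll = float((u[np.arange(T), chosen] - np.log(np.exp(u).sum(axis=1))).sum())
    return beta, ll
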