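"""Independent numerical oracles used by the tests.

Kept free of any grsxe import so the oracles cannot share code with
the implementation they check.
"""

import numpy as np
from scipy.special import expit


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Newton-Raphson (IRLS) logistic regression: the ML oracle.

    Returns (beta, se) including an intercept prepended to X.
    """
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        p = expit(Xd @ beta)
        W = p * (1 - p)
        H = (Xd * W[:, None]).T @ Xd
        g = Xd.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(Xd @ beta)
    cov = np.linalg.inv((Xd * (p * (1 - p))[:, None]).T @ Xd)
    return beta, np.sqrt(np.diag(cov))
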