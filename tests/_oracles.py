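"""Independent straight-line reference implementations used as oracles.

Deliberately simple and separate from the package's vectorized/JIT code
paths: plain-Python trial loops, grid searches and closed forms.
"""

import numpy as np
from scipy.stats import multivariate_normal, norm


def hybrid_loglik_reference(theta, trials, q_init=0.0, mf0_updated=True):
    """Plain-Python hybrid-model session log-likelihood.

    ``trials`` is an iterable of (c1, state, c2, reward, missed) tuples.
    """
    alpha, b2, bmb, bmf0, bmf1, bstick = theta
    q2 = {(s, c): q_init for s in (0, 1) for c in (0, 1)}
    qmf0 = {0: q_init, 1: q_init}
    qmf1 = {0: q_init, 1: q_init}
    prev = None
    ll = 0.0
    for c1, st, c2, r, missed in trials:
        if missed:
            continue
        qmb = {c: max(q2[(c, 0)], q2[(c, 1)]) for c in (0, 1)}
        v = {}
        for c in (0, 1):
            v[c] = bmb * qmb[c] + bmf0 * qmf0[c] + bmf1 * qmf1[c]
            if prev is not None and c == prev:
                v[c] += bstick
        z = np.exp(v[0]) + np.exp(v[1])
        ll += v[c1] - np.log(z)
        w = {c: b2 * q2[(st, c)] for c in (0, 1)}
        z2 = np.exp(w[0]) + np.exp(w[1])
        ll += w[c2] - np.log(z2)
        # updates
        pre = q2[(st, c2)]
        for key in q2:
            q2[key] *= 1 - alpha
        q2[(st, c2)] = (1 - alpha) * pre + r
        target = q2[(st, c2)] if mf0_updated else pre
        old0, old1 = qmf0[c1], qmf1[c1]
        for d in (qmf0, qmf1):
            for key in d:
                d[key] *= 1 - alpha
        qmf0[c1] = (1 - alpha) * old0 + target
        qmf1[c1] = (1 - alpha) * old1 + r
        prev = c1
    return ll


def logistic_newton_reference(X, y, tol=1e-12, max_iter=200):
    """Brute-force Newton-Raphson ML logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        g = X.T @ (y - p)
        H = (X.T * (p * (1 - p))) @ X
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def ridge_closed_form(X, y, lam):
    """Minimizer of 1/2n ||y - Xb||^2 + lam/2 ||b||^2."""
    n, p = X.shape
    return np.linalg.solve(X.T @ X + n * lam * np.eye(p), X.T @ y)


def tetrachoric_grid_reference(table, step=0.002):
    """Grid-search ML tetrachoric correlation for a 2x2 table.

    Thresholds are the exact 2x2 ML values (from the margins); rho is
    found by brute force using scipy's bivariate normal CDF.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    tx = norm.ppf(table[0].sum() / n)
    ty = norm.ppf(table[:, 0].sum() / n)
    best_rho, best_ll = 0.0, -np.inf
    for rho in np.arange(-0.995, 0.995 + 1e-12, step):
        mv = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        p00 = mv.cdf([tx, ty])
        p0x = norm.cdf(tx)
        px0 = norm.cdf(ty)
        probs = np.array(
            [[p00, p0x - p00], [px0 - p00, 1 - p0x - px0 + p00]]
        )
        if np.any(probs <= 0):
            continue
        ll = float(np.sum(table * np.log(probs)))
        if ll > best_ll:
            best_ll, best_rho = ll, rho
    return best_rho


def bayes_modal_grid_reference(responses, a, b, prior_sd=1.0, step=0.001):
    """Grid-search posterior mode of 2PL ability."""
    grid = np.arange(-6.0, 6.0 + 1e-12, step)
    r = np.asarray(responses, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(np.outer(grid, a) - a * b)))
    ll = (r * np.log(p) + (1 - r) * np.log(1 - p)).sum(axis=1)
    if prior_sd is not None:
        ll = ll - 0.5 * grid**2 / prior_sd**2
    return float(grid[np.argmax(ll)])
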