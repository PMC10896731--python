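"""Independent brute-force oracles used to validate the LP fitting path."""

import numpy as np


def grid_search_loss(X, y, a, tau, lo=-4.0, hi=4.0, step=0.05):
    """Exhaustive grid minimum of the area-weighted pinball loss.

    Evaluates the loss on a regular lattice over each coefficient and
    returns (best loss, slack): the loss is piecewise linear with
    Lipschitz constant at most max(τ, 1−τ)·Σᵢ aᵢ‖Xᵢ‖₁ / Σa per unit of
    coefficient ∞-norm, so the lattice minimum is within
    step × Lipschitz of the true optimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    a = np.asarray(a, float)
    p = X.shape[1]
    axes = [np.arange(lo, hi + step / 2, step) for _ in range(p)]
    grids = np.meshgrid(*axes, indexing="ij")
    betas = np.stack([g.ravel() for g in grids], axis=1)  # (G, p)
    Q = betas @ X.T  # (G, n)
    W = np.where(y[None, :] <= Q, 1.0 - tau, tau)  # y > q gets tau, ties 1−tau
    losses = (W * np.abs(y[None, :] - Q) * a[None, :]).sum(axis=1) / a.sum()
    best = float(losses.min())
    lipschitz = max(tau, 1 - tau) * float((a * np.abs(X).sum(axis=1)).sum() / a.sum())
    return best, step * lipschitz


def brute_weighted_percentile(values, weights, q):
    """Reference weighted percentile by explicit CDF scan."""
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w) / w.sum()
    for vi, ci in zip(v, cum):
        if ci >= q - 1e-12:
            return float(vi)
    return float(v[-1])


def pinball_loss_reference(y, q, a, tau):
    """Straight-from-the-definition loss used to cross-check quantile_loss."""
    total = 0.0
    for yi, qi, ai in zip(y, q, a):
        if yi > qi:
            total += tau * abs(yi - qi) * ai
        else:
            total += (1 - tau) * abs(yi - qi) * ai
    return total / np.sum(a)
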