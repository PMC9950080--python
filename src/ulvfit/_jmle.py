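"""Joint maximum-likelihood engine shared by the SDT and Rasch models.

Both models place P persons and I items on one latent scale and model each
trial as Bernoulli with success probability ``link(theta_p - b_i)``; only the
link differs (Gaussian m-AFC proportion correct vs logistic).  Estimation is
alternating per-parameter Newton updates: given the item block, each person's
likelihood is a one-dimensional concave-shaped function, so a damped Newton
step per coordinate is cheap and vectorizes over the whole block.  The scale
origin is identified by re-centering person measures to mean zero after every
cycle (the likelihood is invariant under a common shift of both blocks, so
re-centering never changes it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ModelSpec:
    """Numerical settings for the joint fit.

    quadrature_order : Gauss-Hermite order for the m-AFC integral (>= 20).
    max_iter         : maximum alternation cycles.
    tol              : convergence threshold on the log-likelihood change.
    param_bound      : cap on |theta| and |b|; perfect/zero scorers land here.
    epsilon_clip     : floor/ceiling applied to success probabilities.
    """

    quadrature_order: int = 61
    max_iter: int = 500
    tol: float = 1e-8
    param_bound: float = 5.0
    epsilon_clip: float = 1e-6

    def __post_init__(self) -> None:
        if self.quadrature_order < 20:
            raise ValueError("quadrature_order must be >= 20")
        if not 0 < self.epsilon_clip < 0.01:
            raise ValueError("epsilon_clip must lie in (0, 0.01)")


class JMLEFit:
    """Raw array-level result of a joint fit (ids are attached by callers)."""

    def __init__(self, theta, b, loglik, converged, n_iter, se_theta, se_b,
                 at_bound_theta, at_bound_b, se_unreliable_theta, se_unreliable_b):
        self.theta = theta
        self.b = b
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.se_theta = se_theta
        self.se_b = se_b
        self.at_bound_theta = at_bound_theta
        self.at_bound_b = at_bound_b
        self.se_unreliable_theta = se_unreliable_theta
        self.se_unreliable_b = se_unreliable_b


def _cell_loglik_terms(K, N, P, eps):
    P = np.clip(P, eps, 1.0 - eps)
    return K * np.log(P) + (N - K) * np.log1p(-P)


def loglik_matrix(K, N, link, theta, b, eps):
    """Bernoulli log-likelihood of the score matrix under the link."""
    D = theta[:, None] - b[None, :]
    p, _, _ = link.evaluate(D)
    return float(np.sum(_cell_loglik_terms(K, N, p, eps)))


def _block_derivatives(K, N, link, theta, b, eps):
    """Per-cell first/second derivatives of the cell log-likelihood wrt d."""
    D = theta[:, None] - b[None, :]
    p, dp, d2p = link.evaluate(D)
    p = np.clip(p, eps, 1.0 - eps)
    W1 = K / p - (N - K) / (1.0 - p)
    W2 = K / p**2 + (N - K) / (1.0 - p) ** 2
    f1 = W1 * dp                  # d/dd of cell loglik
    f2 = W1 * d2p - W2 * dp**2    # d2/dd2 of cell loglik
    # cells with no trials contribute nothing
    mask = N > 0
    return np.where(mask, f1, 0.0), np.where(mask, f2, 0.0)


def _newton_step(g, h, max_step=1.0):
    with np.errstate(divide="ignore", invalid="ignore"):
        step = np.where(h < -1e-12, -g / h, np.sign(g) * 0.5)
    return np.clip(step, -max_step, max_step)


def jmle_fit(K, N, link, spec: ModelSpec, theta0=None, b0=None) -> JMLEFit:
    """Alternating Newton JMLE with mean-zero anchoring of the person block.

    K, N are P x I arrays of successes and trial counts (N = 0 marks a cell
    that was never administered).  Returns parameter vectors capped at
    ``spec.param_bound`` with at-bound flags, and split-block standard errors
    (each block's observed information with the other block held at the MLE).
    """
    K = np.asarray(K, dtype=float)
    N = np.asarray(N, dtype=float)
    nP, nI = K.shape
    if np.any(N.sum(axis=1) == 0):
        raise ValueError(f"person(s) with no responses at rows {np.where(N.sum(axis=1) == 0)[0]}")
    if np.any(N.sum(axis=0) == 0):
        raise ValueError(f"item(s) with no responses at columns {np.where(N.sum(axis=0) == 0)[0]}")
    eps, bound = spec.epsilon_clip, spec.param_bound

    theta = np.zeros(nP) if theta0 is None else np.array(theta0, dtype=float)
    b = np.zeros(nI) if b0 is None else np.array(b0, dtype=float)
    theta = np.clip(theta - theta.mean(), -bound, bound)
    b = np.clip(b, -bound, bound)

    ll = loglik_matrix(K, N, link, theta, b, eps)
    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        # person block
        f1, f2 = _block_derivatives(K, N, link, theta, b, eps)
        theta = np.clip(theta + _newton_step(f1.sum(axis=1), f2.sum(axis=1)), -bound, bound)
        # item block (d/db = -d/dd, so the gradient flips sign; curvature does not)
        f1, f2 = _block_derivatives(K, N, link, theta, b, eps)
        b = np.clip(b + _newton_step(-f1.sum(axis=0), f2.sum(axis=0)), -bound, bound)
        # re-anchor: shift both blocks so mean(theta)=0 (loglik unchanged)
        shift = theta.mean()
        theta = np.clip(theta - shift, -bound, bound)
        b = np.clip(b - shift, -bound, bound)
        ll_new = loglik_matrix(K, N, link, theta, b, eps)
        if abs(ll_new - ll) < spec.tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    at_theta = np.abs(theta) >= bound - 1e-9
    at_b = np.abs(b) >= bound - 1e-9
    se_theta, se_b, bad_theta, bad_b = split_block_se(K, N, link, theta, b, eps)
    return JMLEFit(theta, b, ll, converged, it, se_theta, se_b, at_theta, at_b,
                   bad_theta | at_theta, bad_b | at_b)


def split_block_se(K, N, link, theta, b, eps):
    """SEs from each block's diagonal observed information, other block fixed."""
    f1, f2 = _block_derivatives(K, N, link, theta, b, eps)
    info_theta = -f2.sum(axis=1)
    info_b = -f2.sum(axis=0)
    bad_theta = info_theta <= 0
    bad_b = info_b <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se_theta = np.where(bad_theta, np.nan, 1.0 / np.sqrt(np.abs(info_theta)))
        se_b = np.where(bad_b, np.nan, 1.0 / np.sqrt(np.abs(info_b)))
    return se_theta, se_b, bad_theta, bad_b


def joint_se(K, N, link, theta, b, eps):
    """SEs from the full joint observed information.

    The likelihood is invariant under a common shift of both blocks, so the
    joint Hessian has a null direction along (1_P, 1_I); the information is
    inverted with a pseudo-inverse, which fixes the variance of the
    anchored (mean-zero) combination.
    """
    f1, f2 = _block_derivatives(K, N, link, theta, b, eps)
    nP, nI = K.shape
    H = np.zeros((nP + nI, nP + nI))
    H[:nP, :nP] = np.diag(f2.sum(axis=1))
    H[nP:, nP:] = np.diag(f2.sum(axis=0))
    H[:nP, nP:] = -f2
    H[nP:, :nP] = -f2.T
    cov = np.linalg.pinv(-H, hermitian=True)
    var = np.clip(np.diag(cov), 0.0, np.inf)
    se = np.sqrt(var)
    return se[:nP], se[nP:]
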