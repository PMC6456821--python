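"""Random-intercept binomial logistic regression, fit by quadrature ML.

This is the model behind the per-type probability tables: for expert (or
participant) ``e`` and design cell ``c`` (here the nine trend x trust
situations), the number of answers using a statement type is

    y_ec ~ Binomial(n_ec, p_ec),   logit(p_ec) = beta_c + b_e,
    b_e ~ Normal(0, sigma^2),

with a saturated cell-means fixed part, so the fitted cell probabilities
are invariant to contrast coding.  The marginal likelihood integrates the
random intercept out with Gauss-Hermite quadrature and is maximized over
(beta_1..beta_C, log sigma) with BFGS.  Population-level probabilities are
``expit(beta_c)``, i.e. the prediction at a random intercept of zero.

Only sufficient statistics (per-group, per-cell success and trial counts)
are needed, which keeps each fit to a few milliseconds even for hundreds
of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["RandomInterceptLogitResult", "fit_random_intercept_logit"]

_LOGIT_CLIP = 8.0  # |logit| bound used for starting values on degenerate cells
_PROB_EPS = 1e-6


@dataclass
class RandomInterceptLogitResult:
    """ML fit of the random-intercept logistic cell-means model."""

    beta: np.ndarray  # per-cell logits, conditional on b = 0
    sigma: float  # random-intercept standard deviation (log-odds scale)
    loglik: float
    converged: bool
    n_groups: int

    @property
    def probabilities(self) -> np.ndarray:
        """Population-level per-cell probabilities (random intercept at 0)."""
        return np.clip(special.expit(self.beta), _PROB_EPS, 1 - _PROB_EPS)


def _neg_loglik_grad(
    params: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    # b values at the quadrature nodes: shape (K,)
    b = np.sqrt(2.0) * sigma * nodes
    # logits: (K, C)
    eta = beta[None, :] + b[:, None]
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    p = np.exp(log_p)
    # per-group conditional log-likelihood at each node: (E, K)
    ll = successes @ log_p.T + (trials - successes) @ log_q.T
    ll = ll + log_weights[None, :]
    group_ll = special.logsumexp(ll, axis=1)
    # posterior node weights per group: (E, K)
    post = np.exp(ll - group_ll[:, None])
    # dA_ek/dbeta_c = y_ec - n_ec p_kc; the score is its posterior average.
    resid = successes[:, None, :] - trials[:, None, :] * p[None, :, :]  # (E,K,C)
    grad_beta = np.einsum("ek,ekc->c", post, resid)
    # dA_ek/dlog_sigma = b_k * sum_c (y_ec - n_ec p_kc)
    grad_logsig = float((post * resid.sum(axis=2) * b[None, :]).sum())
    grad = -np.append(grad_beta, grad_logsig)
    return -float(group_ll.sum()), grad


def fit_random_intercept_logit(
    successes: np.ndarray,
    trials: np.ndarray,
    n_quad: int = 25,
) -> RandomInterceptLogitResult:
    """Fit the model from per-group, per-cell binomial counts.

    Parameters
    ----------
    successes, trials
        Arrays of shape ``(n_groups, n_cells)``; groups are experts (the
        random-intercept units), cells the fixed-effect design cells.
        Cells a group never saw may have zero trials.
    n_quad
        Number of Gauss-Hermite nodes.

    Notes
    -----
    On optimizer failure or non-finite results the fit falls back to the
    fixed-effects-only model (pooled cell proportions, ``sigma = 0``) with
    ``converged=False``; completely separated cells are handled by clipping
    starting logits, and the reported probabilities always lie strictly
    inside (0, 1).
    """
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if successes.shape != trials.shape or successes.ndim != 2:
        raise ValueError("successes and trials must be (n_groups, n_cells)")
    if successes.shape[0] < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if (successes > trials).any() or (successes < 0).any():
        raise ValueError("successes must lie in [0, trials]")
    n_groups, n_cells = successes.shape

    pooled_n = trials.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_p = np.where(pooled_n > 0, successes.sum(axis=0) / pooled_n, 0.5)
    pooled_p = np.clip(pooled_p, _PROB_EPS, 1 - _PROB_EPS)
    beta0 = np.clip(special.logit(pooled_p), -_LOGIT_CLIP, _LOGIT_CLIP)

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    x0 = np.append(beta0, np.log(0.3))
    args = (successes, trials, nodes, log_weights)
    try:
        res = optimize.minimize(
            _neg_loglik_grad,
            x0,
            args=args,
            method="L-BFGS-B",
            jac=True,
            # log_sigma bounded below: sigma ~ 1e-4 is numerically zero.
            bounds=[(-30.0, 30.0)] * n_cells + [(-9.0, 3.0)],
            options={"maxiter": 500},
        )
        ok = np.isfinite(res.fun) and np.isfinite(res.x).all()
    except (ValueError, FloatingPointError):  # pragma: no cover - defensive
        ok = False
        res = None
    if not ok:
        loglik = -_neg_loglik_grad(np.append(beta0, -9.0), *args)[0]
        return RandomInterceptLogitResult(
            beta=beta0, sigma=0.0, loglik=loglik,
            converged=False, n_groups=n_groups,
        )
    beta = np.clip(res.x[:-1], -2 * _LOGIT_CLIP, 2 * _LOGIT_CLIP)
    sigma = float(np.exp(res.x[-1]))
    if sigma < 1e-3:  # variance at the zero boundary: a legitimate optimum
        sigma = 0.0
    # A fit at or beyond the separation boundary (|logit| ~ 10 means a
    # fitted probability within 5e-5 of 0 or 1) is reported but flagged.
    converged = bool(res.success) and bool(
        (np.abs(res.x[:-1]) < 10.0).all()
    )
    return RandomInterceptLogitResult(
        beta=beta, sigma=sigma, loglik=-float(res.fun),
        converged=converged, n_groups=n_groups,
    )
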