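"""Pointwise log-likelihoods for the two outcome families.

Shared by the MCMC samplers and the penalized-MAP fitter: a Bernoulli
logit for "any recreational walking" and a cumulative-logit
(proportional-odds) likelihood for the 5-category neighborhood walking
time, parametrized as P(y <= k) = sigma(kappa_k - eta).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_TINY = 1e-300


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Pointwise log-likelihood y*eta - log(1 + exp(eta)), stable."""
    return y * eta - np.logaddexp(0.0, eta)


def bernoulli_score_eta(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y - expit(eta)


def _bounds(y: np.ndarray, eta: np.ndarray, kappa: np.ndarray):
    """Lower/upper latent bounds (kappa_{y-1} - eta, kappa_y - eta)."""
    kk = np.concatenate(([-np.inf], kappa, [np.inf]))
    return kk[y - 1] - eta, kk[y] - eta


def cumlogit_loglik(y: np.ndarray, eta: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Pointwise cumulative-logit log-likelihood for categories 1..K.

    ``kappa`` holds the K-1 strictly increasing cutpoints.
    """
    a, b = _bounds(y, eta, kappa)
    p = expit(b) - expit(a)
    return np.log(np.maximum(p, _TINY))


def cumlogit_grads(y: np.ndarray, eta: np.ndarray, kappa: np.ndarray):
    """Gradient of the pointwise log-likelihood w.r.t. eta and kappa.

    Returns ``(d_eta, d_kappa)`` where ``d_eta`` is pointwise and
    ``d_kappa`` has shape (K-1,), already summed over observations.
    """
    a, b = _bounds(y, eta, kappa)
    p = np.maximum(expit(b) - expit(a), _TINY)
    fa = np.where(np.isfinite(a), expit(a) * expit(-a), 0.0)
    fb = np.where(np.isfinite(b), expit(b) * expit(-b), 0.0)
    d_eta = (fa - fb) / p
    K1 = kappa.size
    d_kappa = np.zeros(K1)
    for k in range(1, K1 + 1):
        mk = y == k
        if mk.any():
            d_kappa[k - 1] += np.sum(fb[mk] / p[mk])
        mk1 = y == k + 1
        if mk1.any():
            d_kappa[k - 1] -= np.sum(fa[mk1] / p[mk1])
    return d_eta, d_kappa
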