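"""Adaptive Metropolis-within-Gibbs samplers.

One engine drives both the convolution (BYM) outcome models and the
ecometric measurement models:

* fixed-effect blocks move by adaptive joint random-walk Metropolis
  (Haario-style empirical covariance, scale tuned to ~23% acceptance
  during burn-in, frozen afterwards);
* exchangeable random effects are conditionally independent across
  sites given everything else, so all sites propose and accept/reject
  simultaneously, with per-site scales tuned to ~44% acceptance;
* intrinsic-CAR effects are updated by simultaneous single-site moves
  within graph-coloring classes (sites of one color are mutually
  non-adjacent, so their full conditionals do not couple), followed by
  sum-to-zero recentering absorbed into the intercept / cutpoints;
* standard-deviation parameters move by exact univariate slice sampling
  on the log scale.

Adaptation happens only during burn-in, so the post-burn-in chain is a
fixed-kernel Markov chain with the correct stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .families import bernoulli_loglik, cumlogit_loglik

__all__ = ["MCMCConfig"]

_TARGET_SINGLE = 0.44  # optimal-ish acceptance for 1-d random walks
_TARGET_JOINT = 0.234  # for multivariate random walks


@dataclass
class MCMCConfig:
    """Chain settings for the Gibbs samplers.

    Defaults are desk-scale: 2 chains of 6000 iterations with 2000
    burn-in and thinning 2, i.e. 2000 retained draws per chain.
    """

    n_chains: int = 2
    n_iter: int = 6000
    n_burnin: int = 2000
    thin: int = 2
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self):
        if self.n_chains < 1:
            raise InvalidArgumentError("need at least one chain")
        if self.n_iter <= self.n_burnin:
            raise InvalidArgumentError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise InvalidArgumentError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


def slice_sample_log(logf, x0: float, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """One update of Neal's stepping-out slice sampler on the real line."""
    y = logf(x0) + np.log(rng.uniform())
    lo = x0 - w * rng.uniform()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) < y:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < y:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # numerically stuck; keep current point


class _ScaleAdapter:
    """Per-site proposal scales tuned toward a target acceptance rate in
    batches, with diminishing adjustments; frozen after burn-in."""

    def __init__(self, n_sites: int, target: float, window: int, init_scale: float = 0.3):
        self.log_s = np.full(n_sites, np.log(init_scale))
        self.target = target
        self.window = window
        self.acc = np.zeros(n_sites)
        self.count = 0
        self.batch = 0
        self.frozen = False

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self.acc += accepted
        self.count += 1
        if self.count >= self.window:
            self.batch += 1
            step = min(0.25, 1.0 / np.sqrt(self.batch))
            rate = self.acc / self.count
            self.log_s += np.where(rate > self.target, step, -step)
            self.acc[:] = 0.0
            self.count = 0


class _JointAdapter:
    """Haario-style adaptive covariance for a joint random-walk block:
    proposal covariance ``exp(log_mult) * (2.38^2/d) * empirical cov``,
    with the global multiplier tuned toward ~23% acceptance."""

    def __init__(self, dim: int, window: int, init_scale: float = 0.1):
        self.dim = dim
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.n = 0
        self.log_mult = 0.0
        self.window = window
        self.frozen = False
        self._chol = np.eye(dim) * (init_scale / np.sqrt(dim))

    def observe(self, x: np.ndarray, accepted: bool) -> None:
        if self.frozen:
            return
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += np.outer(d, x - self.mean)
        step = min(0.1, 1.0 / np.sqrt(self.n))
        self.log_mult += step * ((1.0 if accepted else 0.0) - _TARGET_JOINT)
        if self.n >= 2 * self.dim and self.n % self.window == 0:
            cov = self.m2 / (self.n - 1) * (2.38**2 / self.dim)
            cov += 1e-9 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def propose(self, x: np.ndarray, rng) -> np.ndarray:
        return x + np.exp(self.log_mult / 2) * (self._chol @ rng.standard_normal(self.dim))


def _halfnormal_logpdf_sd(sd: float, scale: float) -> float:
    return -0.5 * (sd / scale) ** 2


# ---------------------------------------------------------------------------
# BYM convolution model sampler
# ---------------------------------------------------------------------------


class BYMSampler:
    """Gibbs sampler for logit(p_i) (or cumulative logits) =
    x_i' beta + u_{j(i)} + v_{j(i)} with u exchangeable and v intrinsic CAR.

    Parameters are documented on :class:`neighwalk.model.BYMLogistic`.
    ``graph`` may be ``None`` for a fixed-effects-only model (used by the
    small-instance oracle checks and single-neighborhood data).
    """

    def __init__(
        self,
        y,
        X,
        groups,
        graph,
        family: str,
        beta_prior_sd: float = 10.0,
        sd_prior_scale: float = 1.0,
        start: dict | None = None,
        include_car: bool = True,
        n_categories: int | None = None,
    ):
        self.y = np.asarray(y)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.family = family
        self.graph = graph
        self.beta_prior_sd = beta_prior_sd
        self.sd_prior_scale = sd_prior_scale
        self.include_car = include_car
        if family == "ordinal":
            self.K = int(n_categories) if n_categories else int(self.y.max())
            self.K1 = self.K - 1
        else:
            self.K1 = 0
            self.yf = self.y.astype(float)
        if graph is not None:
            self.g = np.asarray(groups, dtype=int)
            self.J = graph.n_nodes
            self.colors = graph.coloring()
            self.nbr_i, self.nbr_j = graph.edge_index_arrays()
            self.deg = graph.degrees()
            # observations whose neighborhood belongs to each color class
            node_color = np.empty(self.J, dtype=int)
            for c, idx in enumerate(self.colors):
                node_color[idx] = c
            self.obs_color = node_color[self.g]
        else:
            self.g = None
            self.J = 0
        self.start = start or {}

    # -- likelihood helpers ---------------------------------------------
    def _ll(self, eta, kappa):
        if self.family == "logistic":
            return bernoulli_loglik(self.yf, eta)
        return cumlogit_loglik(self.y, eta, kappa)

    def _ll_subset(self, idx, eta, kappa):
        if self.family == "logistic":
            return bernoulli_loglik(self.yf[idx], eta)
        return cumlogit_loglik(self.y[idx], eta, kappa)

    # -- main loop -------------------------------------------------------
    def run_chain(self, cfg: MCMCConfig, rng: np.random.Generator) -> dict:
        p, J, K1 = self.p, self.J, self.K1
        beta = np.array(self.start.get("beta", np.zeros(p)), dtype=float).copy()
        beta += 0.05 * rng.standard_normal(p)  # overdispersed chain starts
        if K1:
            kappa = np.array(self.start.get("kappa", np.linspace(-1, 1, K1)), dtype=float).copy()
            kappa += 0.02 * rng.standard_normal(K1)
            kappa = np.sort(kappa)
        else:
            kappa = None
        u = np.zeros(J)
        v = np.zeros(J)
        sigma_u = 0.3 if J else 0.0
        tau_v = 0.3 if (J and self.include_car) else 0.0

        eta = self.X @ beta + (u[self.g] + v[self.g] if J else 0.0)

        ad_beta = _JointAdapter(p, cfg.adapt_window)
        ad_u = _ScaleAdapter(J, _TARGET_SINGLE, cfg.adapt_window) if J else None
        ad_v = _ScaleAdapter(J, _TARGET_SINGLE, cfg.adapt_window) if J else None
        ad_kap = _ScaleAdapter(K1, _TARGET_SINGLE, cfg.adapt_window, init_scale=0.1) if K1 else None

        n_draws = cfg.n_draws
        out = {
            "beta": np.empty((n_draws, p)),
            "sigma_u": np.empty(n_draws),
            "tau_v": np.empty(n_draws),
            "u": np.empty((n_draws, J)),
            "v": np.empty((n_draws, J)),
        }
        if K1:
            out["kappa"] = np.empty((n_draws, K1))

        b_var = self.beta_prior_sd**2
        idx_draw = 0
        for it in range(cfg.n_iter):
            # ---- beta (joint RWM)
            prop = ad_beta.propose(beta, rng)
            eta_prop = eta + self.X @ (prop - beta)
            d = self._ll(eta_prop, kappa).sum() - self._ll(eta, kappa).sum()
            d += (np.dot(beta, beta) - np.dot(prop, prop)) / (2 * b_var)
            accepted = np.log(rng.uniform()) < d
            if accepted:
                beta, eta = prop, eta_prop
            ad_beta.observe(beta, accepted)

            # ---- cutpoints (componentwise RWM with ordering)
            if K1:
                order = rng.permutation(K1)
                scales_k = ad_kap.scales
                acc_k = np.zeros(K1)
                for k in order:
                    propk = kappa[k] + scales_k[k] * rng.standard_normal()
                    lo = kappa[k - 1] if k > 0 else -np.inf
                    hi = kappa[k + 1] if k < K1 - 1 else np.inf
                    if not (lo < propk < hi):
                        continue
                    mask = (self.y == k + 1) | (self.y == k + 2)
                    kap_new = kappa.copy()
                    kap_new[k] = propk
                    d = (
                        self._ll_subset(mask, eta[mask], kap_new).sum()
                        - self._ll_subset(mask, eta[mask], kappa).sum()
                        + (kappa[k] ** 2 - propk**2) / (2 * b_var)
                    )
                    if np.log(rng.uniform()) < d:
                        kappa = kap_new
                        acc_k[k] = 1.0
                ad_kap.update(acc_k)

            if J:
                # ---- u (all sites simultaneously; conditionally independent)
                delta = ad_u.scales * rng.standard_normal(J)
                eta_prop = eta + delta[self.g]
                dll = np.bincount(
                    self.g,
                    weights=self._ll(eta_prop, kappa) - self._ll(eta, kappa),
                    minlength=J,
                )
                dlp = (u**2 - (u + delta) ** 2) / (2 * sigma_u**2)
                acc = np.log(rng.uniform(size=J)) < dll + dlp
                u = u + delta * acc
                eta = eta + (delta * acc)[self.g]
                ad_u.update(acc.astype(float))

                # ---- v (color classes; ICAR pairwise-difference prior)
                tau2 = tau_v**2
                scales_v = ad_v.scales
                acc_all = np.zeros(J)
                for c, sites in (enumerate(self.colors) if self.include_car else ()):
                    nbr_sum = np.zeros(J)
                    np.add.at(nbr_sum, self.nbr_i, v[self.nbr_j])
                    np.add.at(nbr_sum, self.nbr_j, v[self.nbr_i])
                    delta = np.zeros(J)
                    delta[sites] = scales_v[sites] * rng.standard_normal(sites.size)
                    om = self.obs_color == c
                    idx = np.flatnonzero(om)
                    eta_sub = eta[idx]
                    eta_sub_prop = eta_sub + delta[self.g[idx]]
                    dll_obs = self._ll_subset(idx, eta_sub_prop, kappa) - self._ll_subset(
                        idx, eta_sub, kappa
                    )
                    dll = np.bincount(self.g[idx], weights=dll_obs, minlength=J)
                    vp = v + delta
                    dlp = (
                        -(
                            self.deg * (vp**2 - v**2)
                            - 2 * nbr_sum * delta
                        )
                        / (2 * tau2)
                        if tau2 > 0
                        else np.where(delta != 0, -np.inf, 0.0)
                    )
                    acc = np.log(rng.uniform(size=J)) < dll + dlp
                    acc &= delta != 0
                    v = v + delta * acc
                    eta = eta + (delta * acc)[self.g]
                    acc_all[sites] = acc[sites]
                ad_v.update(acc_all)

                # ---- recenter v (sum-to-zero), absorb shift
                m = v.mean()
                if m != 0.0:
                    v = v - m
                    if self.family == "logistic":
                        beta = beta.copy()
                        beta[0] += m  # intercept absorbs the shift; eta unchanged
                    else:
                        kappa = kappa - m
                        eta = eta - m  # kappa - eta invariant

                # ---- variance parameters (slice on log scale)
                ssq_u = float(np.dot(u, u))
                scale = self.sd_prior_scale

                def lp_sigma(t):
                    s2 = np.exp(2 * t)
                    return -J * t - ssq_u / (2 * s2) + _halfnormal_logpdf_sd(np.exp(t), scale) + t

                sigma_u = float(np.exp(slice_sample_log(lp_sigma, np.log(sigma_u), rng)))

                if self.include_car:
                    dv = v[self.nbr_i] - v[self.nbr_j]
                    ssq_v = float(np.dot(dv, dv))

                    def lp_tau(t):
                        s2 = np.exp(2 * t)
                        return (
                            -(J - 1) * t
                            - ssq_v / (2 * s2)
                            + _halfnormal_logpdf_sd(np.exp(t), scale)
                            + t
                        )

                    tau_v = float(np.exp(slice_sample_log(lp_tau, np.log(tau_v), rng)))

            if it == cfg.n_burnin - 1:
                ad_beta.frozen = True
                if J:
                    ad_u.frozen = ad_v.frozen = True
                if K1:
                    ad_kap.frozen = True
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                out["beta"][idx_draw] = beta
                out["sigma_u"][idx_draw] = sigma_u
                out["tau_v"][idx_draw] = tau_v
                out["u"][idx_draw] = u
                out["v"][idx_draw] = v
                if K1:
                    out["kappa"][idx_draw] = kappa
                idx_draw += 1
        return out

    def run(self, cfg: MCMCConfig) -> dict:
        """Run all chains; returns a dict of stacked (chain, draw, ...) arrays."""
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains = [self.run_chain(cfg, np.random.default_rng(s)) for s in seeds]
        return {k: np.stack([c[k] for c in chains]) for k in chains[0]}


# ---------------------------------------------------------------------------
# Hierarchical ordinal sampler for the ecometric measurement models
# ---------------------------------------------------------------------------


class HierOrdinalSampler:
    """Cumulative-logit measurement model with item fixed effects and
    random intercepts for individuals (3-level) and neighborhoods.

    eta = delta_item + e_indiv + b_nbhd with delta_1 = 0 (reference
    item), e ~ N(0, sigma_e^2), b ~ N(0, sigma_b^2); shared cutpoints.
    The 2-level variant drops the individual random intercepts.
    """

    def __init__(self, resp, item_idx, indiv_idx, nbhd_idx, n_items, n_indiv, n_nbhd,
                 three_level: bool = True, beta_prior_sd: float = 10.0,
                 sd_prior_scale: float = 1.0):
        self.y = np.asarray(resp, dtype=int)
        self.item = np.asarray(item_idx, dtype=int)
        self.indiv = np.asarray(indiv_idx, dtype=int)
        self.nbhd = np.asarray(nbhd_idx, dtype=int)
        self.M, self.I, self.J = n_items, n_indiv, n_nbhd
        self.three_level = three_level
        self.K = int(self.y.max())
        self.K1 = self.K - 1
        self.b_var = beta_prior_sd**2
        self.sd_prior_scale = sd_prior_scale

    def _grouped_update(self, vals, idx_map, n_sites, eta, kappa, prior_var, adapter, rng,
                        skip_first=False):
        delta = adapter.scales * rng.standard_normal(n_sites)
        if skip_first:
            delta[0] = 0.0
        eta_prop = eta + delta[idx_map]
        dll_obs = cumlogit_loglik(self.y, eta_prop, kappa) - cumlogit_loglik(self.y, eta, kappa)
        dll = np.bincount(idx_map, weights=dll_obs, minlength=n_sites)
        dlp = (vals**2 - (vals + delta) ** 2) / (2 * prior_var)
        acc = np.log(rng.uniform(size=n_sites)) < dll + dlp
        if skip_first:
            acc[0] = False
        vals = vals + delta * acc
        eta = eta + (delta * acc)[idx_map]
        adapter.update(acc.astype(float))
        return vals, eta

    def run_chain(self, cfg: MCMCConfig, rng: np.random.Generator) -> dict:
        K1 = self.K1
        cum = np.clip([(self.y <= k).mean() for k in range(1, K1 + 1)], 0.01, 0.99)
        kappa = np.maximum.accumulate(np.log(cum / (1 - cum)) + 1e-3 * np.arange(K1))
        kappa = kappa + 0.02 * rng.standard_normal(K1)
        kappa = np.sort(kappa)
        delta_item = np.zeros(self.M)
        e = np.zeros(self.I)
        b = np.zeros(self.J)
        sigma_e = 0.5
        sigma_b = 0.3

        eta = delta_item[self.item] + b[self.nbhd]
        if self.three_level:
            eta = eta + e[self.indiv]

        ad_item = _ScaleAdapter(self.M, _TARGET_SINGLE, cfg.adapt_window)
        ad_e = _ScaleAdapter(self.I, _TARGET_SINGLE, cfg.adapt_window)
        ad_b = _ScaleAdapter(self.J, _TARGET_SINGLE, cfg.adapt_window)
        ad_kap = _ScaleAdapter(K1, _TARGET_SINGLE, cfg.adapt_window, init_scale=0.1)

        n_draws = cfg.n_draws
        out = {
            "kappa": np.empty((n_draws, K1)),
            "delta_item": np.empty((n_draws, self.M)),
            "b": np.empty((n_draws, self.J)),
            "sigma_b": np.empty(n_draws),
            "sigma_e": np.empty(n_draws),
        }
        idx_draw = 0
        for it in range(cfg.n_iter):
            # item effects (fixed, reference item pinned at 0)
            delta_item, eta = self._grouped_update(
                delta_item, self.item, self.M, eta, kappa, self.b_var, ad_item, rng,
                skip_first=True,
            )
            if self.three_level:
                e, eta = self._grouped_update(
                    e, self.indiv, self.I, eta, kappa, sigma_e**2, ad_e, rng
                )
            b, eta = self._grouped_update(b, self.nbhd, self.J, eta, kappa, sigma_b**2, ad_b, rng)

            # cutpoints
            scales_k = ad_kap.scales
            acc_k = np.zeros(K1)
            for k in range(K1):
                propk = kappa[k] + scales_k[k] * rng.standard_normal()
                lo = kappa[k - 1] if k > 0 else -np.inf
                hi = kappa[k + 1] if k < K1 - 1 else np.inf
                if not (lo < propk < hi):
                    continue
                mask = (self.y == k + 1) | (self.y == k + 2)
                kap_new = kappa.copy()
                kap_new[k] = propk
                d = (
                    cumlogit_loglik(self.y[mask], eta[mask], kap_new).sum()
                    - cumlogit_loglik(self.y[mask], eta[mask], kappa).sum()
                    + (kappa[k] ** 2 - propk**2) / (2 * self.b_var)
                )
                if np.log(rng.uniform()) < d:
                    kappa = kap_new
                    acc_k[k] = 1.0
            ad_kap.update(acc_k)

            # variance parameters
            scale = self.sd_prior_scale
            if self.three_level:
                ssq_e = float(np.dot(e, e))

                def lp_se(t):
                    return (
                        -self.I * t
                        - ssq_e / (2 * np.exp(2 * t))
                        + _halfnormal_logpdf_sd(np.exp(t), scale)
                        + t
                    )

                sigma_e = float(np.exp(slice_sample_log(lp_se, np.log(sigma_e), rng)))
            ssq_b = float(np.dot(b, b))

            def lp_sb(t):
                return (
                    -self.J * t
                    - ssq_b / (2 * np.exp(2 * t))
                    + _halfnormal_logpdf_sd(np.exp(t), scale)
                    + t
                )

            sigma_b = float(np.exp(slice_sample_log(lp_sb, np.log(sigma_b), rng)))

            if it == cfg.n_burnin - 1:
                for ad in (ad_item, ad_e, ad_b, ad_kap):
                    ad.frozen = True
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                out["kappa"][idx_draw] = kappa
                out["delta_item"][idx_draw] = delta_item
                out["b"][idx_draw] = b
                out["sigma_b"][idx_draw] = sigma_b
                out["sigma_e"][idx_draw] = sigma_e
                idx_draw += 1
        return out

    def run(self, cfg: MCMCConfig) -> dict:
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains = [self.run_chain(cfg, np.random.default_rng(s)) for s in seeds]
        return {k: np.stack([c[k] for c in chains]) for k in chains[0]}
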