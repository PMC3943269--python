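"""Interquartile odds ratios and the structured-variance decomposition.

A neighborhood random-effect SD ``sigma`` on the log-odds scale is
summarized as an interquartile odds ratio (IqOR): the odds contrast
between individuals in the top versus bottom quartile of the
neighborhood-effect distribution. For a Normal effect the mean of the
upper quartile sits at ``k * sigma`` with ``k = phi(z_0.75)/0.25 ≈
1.27110``, so

    IqOR(sigma) = exp(2 * k * sigma).

Per MCMC iteration, the unstructured SD is the model's ``sigma_u`` draw
and the structured SD is the *empirical* across-neighborhood SD of the
CAR effects v_j (the ICAR conditional SD tau_v is not the marginal
spread). Squared log-IqORs are additive, so the total IqOR and the
percentage of between-neighborhood variance that is spatially
structured follow from each iteration's pair and are summarized by
posterior medians and 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ContractError, InvalidArgumentError

__all__ = [
    "IQOR_K",
    "sd_to_iqor",
    "empirical_structured_sd",
    "combine_iqors",
    "decompose",
    "VarianceDecomposition",
]

# mean of the upper quartile of a standard Normal: phi(z_0.75) / 0.25
IQOR_K = float(norm.pdf(norm.ppf(0.75)) / 0.25)


def sd_to_iqor(sigma):
    """Map a random-effect SD (log-odds scale) to an interquartile OR."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise InvalidArgumentError("sigma must be >= 0")
    out = np.exp(2.0 * IQOR_K * sigma)
    return float(out) if out.ndim == 0 else out


def iqor_to_sd(iqor):
    """Inverse of :func:`sd_to_iqor`."""
    iqor = np.asarray(iqor, dtype=float)
    if (iqor < 1).any():
        raise InvalidArgumentError("an IqOR is >= 1 by construction")
    out = np.log(iqor) / (2.0 * IQOR_K)
    return float(out) if out.ndim == 0 else out


def empirical_structured_sd(v_draws) -> np.ndarray:
    """Across-neighborhood sample SD (ddof=1) of the CAR effects, per draw.

    ``v_draws`` is (n_draws, J) or a single (J,) field.
    """
    v = np.atleast_2d(np.asarray(v_draws, dtype=float))
    if v.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 neighborhoods")
    return v.std(axis=1, ddof=1)


def combine_iqors(iqor_u: float, iqor_s: float) -> tuple[float, float]:
    """Combine unstructured and structured IqORs on the log-variance scale.

    Squared log-IqORs add (both are ``(2k sigma)^2``, and variances add),
    so the constant k cancels from both outputs::

        total = exp(sqrt(ln^2 iqor_u + ln^2 iqor_s))
        pct_structured = 100 * ln^2 iqor_s / (ln^2 iqor_u + ln^2 iqor_s)

    Returns ``(iqor_total, pct_structured)``.
    """
    if iqor_u < 1 or iqor_s < 1:
        raise InvalidArgumentError("IqOR inputs must be >= 1")
    lu2 = np.log(iqor_u) ** 2
    ls2 = np.log(iqor_s) ** 2
    total = float(np.exp(np.sqrt(lu2 + ls2)))
    if lu2 + ls2 == 0:
        return 1.0, 0.0
    return total, float(100.0 * ls2 / (lu2 + ls2))


@dataclass
class VarianceDecomposition:
    """Posterior decomposition of between-neighborhood variation.

    Each triple is (median, 2.5%, 97.5%) over MCMC iterations; within a
    single iteration ln^2(total) = ln^2(unstructured) + ln^2(structured).
    """

    iqor_unstructured: tuple[float, float, float]
    iqor_structured: tuple[float, float, float]
    iqor_total: tuple[float, float, float]
    pct_structured: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "IqOR unstructured": self.iqor_unstructured,
            "IqOR structured": self.iqor_structured,
            "IqOR total": self.iqor_total,
            "% structured": self.pct_structured,
        }
        return pd.DataFrame(rows, index=["median", "ci_2.5%", "ci_97.5%"]).T

    def __str__(self) -> str:
        def fmt(t, pct=False):
            if pct:
                return f"{t[0]:.0f}% ({t[1]:.0f}%, {t[2]:.0f}%)"
            return f"{t[0]:.2f} ({t[1]:.2f}, {t[2]:.2f})"

        return (
            f"IqOR unstructured {fmt(self.iqor_unstructured)} | "
            f"IqOR structured {fmt(self.iqor_structured)} | "
            f"IqOR total {fmt(self.iqor_total)} | "
            f"structured {fmt(self.pct_structured, pct=True)}"
        )


def _summ(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
    return float(med), float(lo), float(hi)


def decompose(samples) -> VarianceDecomposition:
    """Decompose a fitted convolution model's between-neighborhood variance.

    ``samples`` is a :class:`neighwalk.model.PosteriorSamples` holding
    ``sigma_u`` and ``v`` draws.
    """
    draws = samples.draws if hasattr(samples, "draws") else samples
    if "sigma_u" not in draws or "v" not in draws or not np.asarray(draws["v"]).size:
        raise ContractError("posterior lacks sigma_u / v draws; was the model spatial?")
    s_u = np.asarray(draws["sigma_u"], dtype=float).reshape(-1)
    v = np.asarray(draws["v"], dtype=float)
    v = v.reshape(-1, v.shape[-1])
    s_v = empirical_structured_sd(v)
    total = np.sqrt(s_u**2 + s_v**2)
    with np.errstate(invalid="ignore"):
        pct = np.where(total > 0, 100.0 * s_v**2 / (s_u**2 + s_v**2), 0.0)
    return VarianceDecomposition(
        iqor_unstructured=_summ(sd_to_iqor(s_u)),
        iqor_structured=_summ(sd_to_iqor(s_v)),
        iqor_total=_summ(sd_to_iqor(total)),
        pct_structured=_summ(pct),
    )
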