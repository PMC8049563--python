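"""Closed-form TT estimators of divergence time, drift and ancestral size.

Setting the observed configuration frequencies ``m_ij / m_tot`` equal to
their constant-ancestor model probabilities and solving gives closed-form
method-of-moments estimators which are also the maximum-likelihood
estimates under the multinomial sampling model.  Negative time estimates
are possible (and informative — they flag violated model assumptions) and
are returned as-is with a diagnostic flag rather than clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .model import DEFAULT_G, DEFAULT_MU, ConfigCounts, ModelError

__all__ = ["EstimationError", "TTEstimates", "estimate_tt", "mutation_time_to_years"]


class EstimationError(ModelError):
    """An estimator is undefined on the supplied counts."""


def mutation_time_to_years(T: float, mu: float = DEFAULT_MU, G: float = DEFAULT_G) -> float:
    """Convert a mutation-scaled time ``T = mu * t`` to years: ``(G / mu) * T``.

    ``mu`` is the per-site per-generation mutation rate and ``G`` the
    generation time in years.
    """
    if mu <= 0:
        raise EstimationError("mutation rate mu must be positive")
    if G <= 0:
        raise EstimationError("generation time G must be positive")
    return (G / mu) * T


@dataclass(frozen=True)
class TTEstimates:
    """TT parameter estimates with unit conversions and diagnostics.

    Mutation-scaled quantities (``T``, ``V``, ``theta``) divide by ``mu``
    to give generations / chromosomes; ``NA_diploid_hat = theta_hat/(2 mu)``
    and ``t_years = (G/mu) T``.  ``flags`` collects diagnostics such as
    negative time estimates or undefined components (which are ``nan``).
    """

    alpha1_hat: float
    alpha2_hat: float
    theta_hat: float
    T1_hat: float
    T2_hat: float
    V1_hat: float
    V2_hat: float
    mu: float
    G: float
    flags: tuple[str, ...] = ()

    @property
    def NA_diploid_hat(self) -> float:
        return self.theta_hat / (2.0 * self.mu)

    @property
    def t1_generations(self) -> float:
        return self.T1_hat / self.mu

    @property
    def t2_generations(self) -> float:
        return self.T2_hat / self.mu

    @property
    def t1_years(self) -> float:
        return mutation_time_to_years(self.T1_hat, self.mu, self.G)

    @property
    def t2_years(self) -> float:
        return mutation_time_to_years(self.T2_hat, self.mu, self.G)

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha1": self.alpha1_hat, "alpha2": self.alpha2_hat,
            "theta": self.theta_hat, "T1": self.T1_hat, "T2": self.T2_hat,
            "V1": self.V1_hat, "V2": self.V2_hat,
            "NA_diploid": self.NA_diploid_hat,
            "t1_years": self.t1_years, "t2_years": self.t2_years,
        }


def estimate_tt(counts: ConfigCounts, mu: float = DEFAULT_MU, G: float = DEFAULT_G) -> TTEstimates:
    """TT estimates from configuration counts (constant ancestral size).

    The drift, size and time estimators are::

        alpha1 = 2 m11 / (2 m21 + m11)
        alpha2 = 2 m11 / (2 m12 + m11)
        theta  = (3/8) (2 m21 + m11)(2 m12 + m11) / (m11 m_tot)
        T1     = [m10/2 + m20 - (2 m21 + m11)(6 m12 + m11)/(8 m11)] / m_tot

    (``T2`` index-swapped).  The within-branch coalescence times are pinned
    by the exact inversion of the forward model,
    ``V1 = p10/2 + (p12 - 2 alpha1 p20) / (2 (1 - alpha1))`` with
    ``p = m / m_tot``, which guarantees an exact round-trip against
    :func:`~twotwo.model.tt_forward_probs`.

    Requires ``m11 > 0`` (shared polymorphism); ``V_k`` is undefined
    (``nan``, flagged) when its denominator ``2 m_k' - m11`` is not
    positive or when ``alpha_k = 1``.
    """
    m = counts.m
    m_tot = counts.m_tot
    m10, m01 = m[1, 0], m[0, 1]
    m20, m02 = m[2, 0], m[0, 2]
    m11, m21, m12 = m[1, 1], m[2, 1], m[1, 2]

    if m11 <= 0:
        raise EstimationError(
            "insufficient shared polymorphism: m11 = 0, so the drift and "
            "ancestral-size estimators are undefined"
        )

    flags: list[str] = []
    d1 = 2 * m21 + m11
    d2 = 2 * m12 + m11
    alpha1 = 2 * m11 / d1
    alpha2 = 2 * m11 / d2
    for name, a in (("alpha1", alpha1), ("alpha2", alpha2)):
        if a > 1:
            flags.append(f"{name} > 1 (sampling noise or model violation)")

    theta = 3.0 * d1 * d2 / (8.0 * m11 * m_tot)
    T1 = (m10 / 2 + m20 - d1 * (6 * m12 + m11) / (8 * m11)) / m_tot
    T2 = (m01 / 2 + m02 - (6 * m21 + m11) * d2 / (8 * m11)) / m_tot

    def _v(m_same, m_cross_num, m_fixed, denom, label):
        # V_k = [m_k0/2 + (m_cross (2 m_other + m11) - 4 m11 m_k0-fixed) /
        #        (2 (2 m_other - m11))] / m_tot, the count form of the
        # round-trip identity.
        if denom <= 0:
            warnings.warn(
                f"{label} undefined: denominator 2*m - m11 = {denom:g} is not positive",
                RuntimeWarning, stacklevel=3,
            )
            flags.append(f"{label} undefined (nonpositive denominator)")
            return math.nan
        return (m_same / 2 + (m_cross_num - 4 * m11 * m_fixed) / (2 * denom)) / m_tot

    V1 = _v(m10, m12 * d1, m20, 2 * m21 - m11, "V1")
    V2 = _v(m01, m21 * d2, m02, 2 * m12 - m11, "V2")

    for name, v in (("T1", T1), ("T2", T2), ("V1", V1), ("V2", V2)):
        if v < 0:
            flags.append(f"{name} < 0 (model assumptions likely violated)")

    return TTEstimates(
        alpha1_hat=alpha1, alpha2_hat=alpha2, theta_hat=theta,
        T1_hat=T1, T2_hat=T2, V1_hat=V1, V2_hat=V2,
        mu=mu, G=G, flags=tuple(flags),
    )
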