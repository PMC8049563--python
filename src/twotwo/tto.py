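"""Outgroup-ascertained (TTo) estimators and tree-ness tests.

Restricting to sites whose derived allele is carried by an outgroup
guarantees the variant predates the studied split, so no new-mutation
terms enter the ascertained configuration probabilities.  This yields

* drift estimates ``alpha*`` that make no assumption about the ancestral
  population,
* two tree-ness statistics ``Y1, Y2`` (both zero in expectation under a
  true outgroup and no gene flow; ``Y2`` is closely related to the
  D-statistic), and
* divergence-time estimates ``T* = B* - tau4*`` that replace the
  constant-ancestor assumption with the ratio approximation
  ``tau4* = (3/2) (tau3*)^2 / tau2*`` (exact when the ancestral size is
  constant, since then ``tau3/tau2 = 1/3`` and ``tau4 = theta/6``).

The drift parameters fed to :func:`estimate_tto` may be ``alpha*``
estimates from ascertained counts, or externally known true values; the
configuration counts it consumes are the *full* (unascertained) ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .model import DEFAULT_G, DEFAULT_MU, ConfigCounts
from .tt import EstimationError, mutation_time_to_years

__all__ = ["TToEstimates", "estimate_alpha_ascertained", "treeness_tests", "estimate_tto"]


def estimate_alpha_ascertained(counts_star: ConfigCounts) -> tuple[float, float]:
    """Drift estimates from outgroup-ascertained configuration counts.

    ``alpha1* = 2 (m10* + m12* + m11*) / (2 (m10* + 2 m20* + m21*) + m11*)``
    and the index-swapped ``alpha2*``.  This is the exact solution of the
    no-new-mutation configuration equations for ``alpha1`` (verifiable
    symbolically: substituting the ascertained probabilities expressed in
    ``alpha1, alpha2`` and the ascertained ancestral spectrum reduces it to
    ``alpha1`` identically, for any spectrum).  Valid only on counts
    restricted to sites whose derived allele is present in the outgroup.
    Estimates above 1 (possible under sampling noise) are returned as-is
    with a warning.
    """
    m = counts_star.m
    num1 = 2 * (m[1, 0] + m[1, 2] + m[1, 1])
    den1 = 2 * (m[1, 0] + 2 * m[2, 0] + m[2, 1]) + m[1, 1]
    num2 = 2 * (m[0, 1] + m[2, 1] + m[1, 1])
    den2 = 2 * (m[0, 1] + 2 * m[0, 2] + m[1, 2]) + m[1, 1]
    if den1 <= 0 or den2 <= 0:
        raise EstimationError(
            "ascertained drift estimate undefined: zero denominator "
            f"(den1={den1:g}, den2={den2:g})"
        )
    a1, a2 = num1 / den1, num2 / den2
    for name, a in (("alpha1*", a1), ("alpha2*", a2)):
        if a > 1:
            warnings.warn(f"{name} = {a:g} exceeds 1 (sampling noise?)",
                          RuntimeWarning, stacklevel=2)
    return a1, a2


def treeness_tests(counts_star: ConfigCounts) -> tuple[float, float]:
    """Tree-ness statistics ``(Y1, Y2)`` from ascertained counts.

    ``Y1 = (2 m10* + m11*)/(2 m01* + m11*) - (2 m12* + m11*)/(2 m21* + m11*)``
    and
    ``Y2 = [(m10* - m01*) + 2 (m20* - m02*) + (m21* - m12*)] / m_tot*``.
    Both have expectation 0 when the ascertaining population is a true
    outgroup and there is no gene flow; a nonzero ``Y2`` tracks the
    direction of gene flow like the D-statistic.
    """
    m = counts_star.m
    den_a = 2 * m[0, 1] + m[1, 1]
    den_b = 2 * m[2, 1] + m[1, 1]
    if den_a <= 0:
        raise EstimationError("Y1 undefined: 2*m01* + m11* = 0 (empty cells m01*, m11*)")
    if den_b <= 0:
        raise EstimationError("Y1 undefined: 2*m21* + m11* = 0 (empty cells m21*, m11*)")
    y1 = (2 * m[1, 0] + m[1, 1]) / den_a - (2 * m[1, 2] + m[1, 1]) / den_b
    y2 = ((m[1, 0] - m[0, 1]) + 2 * (m[2, 0] - m[0, 2]) + (m[2, 1] - m[1, 2])) / counts_star.m_tot
    return y1, y2


@dataclass(frozen=True)
class TToEstimates:
    """TTo estimates; mutation-scaled like :class:`~twotwo.tt.TTEstimates`.

    ``tau2_star``/``tau3_star`` are the averages of their two printed
    variants (one via ``m21``, one via ``m12``); both variants are retained
    as diagnostics, since they diverge when the symmetric-model assumptions
    do not hold.  ``B_k* = mu*t_k + tau4`` and ``T_k* = B_k* - tau4*``.
    """

    alpha1: float
    alpha2: float
    tau2_star: float
    tau3_star: float
    tau4_star: float
    B1_star: float
    B2_star: float
    V1_star: float
    V2_star: float
    T1_star: float
    T2_star: float
    tau2_star_variants: tuple[float, float]
    tau3_star_variants: tuple[float, float]
    mu: float
    G: float
    flags: tuple[str, ...] = ()

    @property
    def t1_generations(self) -> float:
        return self.T1_star / self.mu

    @property
    def t2_generations(self) -> float:
        return self.T2_star / self.mu

    @property
    def t1_years(self) -> float:
        return mutation_time_to_years(self.T1_star, self.mu, self.G)

    @property
    def t2_years(self) -> float:
        return mutation_time_to_years(self.T2_star, self.mu, self.G)

    @property
    def NA_diploid_from_tau4(self) -> float:
        """Ancestral diploid size implied by ``tau4*`` alone: ``6 tau4*/(2 mu)``."""
        return 6.0 * self.tau4_star / (2.0 * self.mu)

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha1": self.alpha1, "alpha2": self.alpha2,
            "tau2": self.tau2_star, "tau3": self.tau3_star, "tau4": self.tau4_star,
            "B1": self.B1_star, "B2": self.B2_star,
            "V1": self.V1_star, "V2": self.V2_star,
            "T1": self.T1_star, "T2": self.T2_star,
            "t1_years": self.t1_years, "t2_years": self.t2_years,
        }


def estimate_tto(
    counts: ConfigCounts,
    alpha1: float,
    alpha2: float,
    mu: float = DEFAULT_MU,
    G: float = DEFAULT_G,
) -> TToEstimates:
    """TTo estimates from *full* counts given externally obtained drift.

    ``alpha1, alpha2`` are typically the ascertained estimates from
    :func:`estimate_alpha_ascertained` (or known true values in
    simulations).  The ancestral-coalescent summaries come in two printed
    variants each, which are averaged::

        tau2* = (3/2) [(2 m21 + m11)/alpha2 - m11/(alpha1 alpha2)] / m_tot
        tau3* = [(5/2) m11/(alpha1 alpha2) - (2 m21 + m11)/alpha2] / m_tot

    (variants use ``(2 m12 + m11)/alpha1``).  Then
    ``tau4* = (3/2)(tau3*)^2 / tau2*`` and ``T_k* = B_k* - tau4*``.

    When ``tau2* <= 0`` the ``tau4*`` step and the time estimates are
    undefined (``nan``, flagged); when ``alpha_k = 1``, ``V_k*`` is
    undefined (division by ``1 - alpha_k``).
    """
    if not (0 < alpha1 <= 1 and 0 < alpha2 <= 1):
        raise EstimationError(f"alpha inputs must be in (0, 1], got ({alpha1}, {alpha2})")
    m = counts.m
    m_tot = counts.m_tot
    m11 = m[1, 1]
    if m11 <= 0:
        raise EstimationError("insufficient shared polymorphism: m11 = 0")

    flags: list[str] = []
    a12 = alpha1 * alpha2
    shared = m11 / a12

    tau2_a = 1.5 * ((2 * m[2, 1] + m11) / alpha2 - shared) / m_tot
    tau2_b = 1.5 * ((2 * m[1, 2] + m11) / alpha1 - shared) / m_tot
    tau3_a = (2.5 * shared - (2 * m[2, 1] + m11) / alpha2) / m_tot
    tau3_b = (2.5 * shared - (2 * m[1, 2] + m11) / alpha1) / m_tot
    tau2 = 0.5 * (tau2_a + tau2_b)
    tau3 = 0.5 * (tau3_a + tau3_b)

    B1 = (m[1, 0] / 2 + m[2, 0] + m[2, 1] / 2 - (5 - a12) / a12 * m11 / 4) / m_tot
    B2 = (m[0, 1] / 2 + m[0, 2] + m[1, 2] / 2 - (5 - a12) / a12 * m11 / 4) / m_tot

    def _v(m_same, m_fixed, m_cross, alpha, label):
        if alpha >= 1:
            flags.append(f"{label} undefined (alpha = 1)")
            return math.nan
        return (m_same / 2 - alpha * m_fixed / (1 - alpha) + m_cross / (2 * (1 - alpha))) / m_tot

    V1 = _v(m[1, 0], m[2, 0], m[1, 2], alpha1, "V1*")
    V2 = _v(m[0, 1], m[0, 2], m[2, 1], alpha2, "V2*")

    if tau2 <= 0:
        warnings.warn(
            f"tau2* = {tau2:g} is not positive; tau4* and T* are undefined",
            RuntimeWarning, stacklevel=2,
        )
        flags.append("tau4*/T* undefined (tau2* <= 0)")
        tau4 = math.nan
    else:
        tau4 = 1.5 * tau3 * tau3 / tau2
    T1 = B1 - tau4
    T2 = B2 - tau4

    for name, v in (("tau3*", tau3), ("T1*", T1), ("T2*", T2)):
        if v < 0:
            flags.append(f"{name} < 0 (model assumptions likely violated)")

    return TToEstimates(
        alpha1=alpha1, alpha2=alpha2,
        tau2_star=tau2, tau3_star=tau3, tau4_star=tau4,
        B1_star=B1, B2_star=B2, V1_star=V1, V2_star=V2,
        T1_star=T1, T2_star=T2,
        tau2_star_variants=(tau2_a, tau2_b), tau3_star_variants=(tau3_a, tau3_b),
        mu=mu, G=G, flags=tuple(flags),
    )
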