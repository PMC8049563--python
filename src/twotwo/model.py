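"""Forward model for the 2+2 sample-configuration spectrum.

Two chromosomes are sampled from each of two populations that diverged from
a common ancestral population.  At a bi-allelic site with known ancestral
state, the data reduce to the pair ``(i, j)`` of derived-allele counts
(each in ``{0, 1, 2}``) — nine possible sample configurations.  Under an
infinite-sites, independent-sites (composite-likelihood) model, the
probability of each polymorphic configuration is linear in the mutation
rate and depends only on expected branch lengths of the underlying 4-leaf
genealogy.

Two parametrizations are provided:

* :class:`GeneralParams` — the general divergence model, which makes no
  assumption about the ancestral population beyond panmixia.  The ancestral
  coalescent enters only through ``tau_i = mu * E[T4_i]``, the
  mutation-scaled expected time a 4-lineage coalescent spends with ``i``
  lineages.
* :class:`TTParams` — the constant-ancestral-size special case, where
  ``(tau2, tau3, tau4) = (theta, theta/3, theta/6)`` with
  ``theta = mu * N_A`` and ``N_A`` the ancestral size in chromosomes.

All probabilities are exact closed forms; ``p_{0,0}`` and ``p_{2,2}`` are
identifiable only as the lump ``p00 + p22 = 1 - sum(polymorphic)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "POLYMORPHIC_CONFIGS",
    "ModelError",
    "ModelDomainError",
    "ConfigCounts",
    "ConfigProbs",
    "TTParams",
    "GeneralParams",
    "AncestralSpectrum",
    "tt_forward_probs",
    "general_forward_probs",
    "constant_tau_and_b",
    "downsample_spectrum",
]

#: The seven polymorphic sample configurations (i, j), i = derived count in
#: the population-1 sample, j in the population-2 sample.
POLYMORPHIC_CONFIGS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2),
)

DEFAULT_MU = 1.25e-8  #: per-site per-generation mutation rate
DEFAULT_G = 30.0      #: generation time in years


class ModelError(ValueError):
    """Invalid model parameters or malformed spectrum objects."""


class ModelDomainError(ModelError):
    """Parameters outside the linear-in-mu regime (negative probability)."""


def _as33(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (3, 3):
        raise ModelError(f"expected a 3x3 array of configurations, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ConfigCounts:
    """Site counts ``m[i][j]`` by sample configuration, plus the total.

    ``m_tot`` counts *all* investigated sites, monomorphic included; the
    ``m[0][0]`` cell therefore normally dominates.  Counts may be
    real-valued (expected counts from the simulator).
    """

    m: np.ndarray
    m_tot: float

    def __post_init__(self):
        object.__setattr__(self, "m", _as33(self.m))
        if np.any(self.m < 0):
            raise ModelError("negative configuration counts")
        if self.m_tot <= 0:
            raise ModelError("m_tot must be positive")
        if not np.isclose(self.m.sum(), self.m_tot, rtol=1e-6, atol=1e-6):
            raise ModelError(
                f"configuration counts sum to {self.m.sum():g} but m_tot={self.m_tot:g}"
            )

    @classmethod
    def from_cells(cls, m_tot: float, **cells: float) -> "ConfigCounts":
        """Build from keyword cells ``m10=..., m11=...``; the monomorphic
        remainder is placed in ``m00`` unless given explicitly."""
        m = np.zeros((3, 3))
        for key, val in cells.items():
            if len(key) != 3 or not key.startswith("m"):
                raise ModelError(f"unrecognized cell name {key!r}")
            i, j = int(key[1]), int(key[2])
            m[i, j] = val
        if "m00" not in cells:
            m[0, 0] = m_tot - m.sum()
        return cls(m=m, m_tot=m_tot)

    def transpose(self) -> "ConfigCounts":
        """Swap the roles of population 1 and population 2."""
        return ConfigCounts(m=self.m.T.copy(), m_tot=self.m_tot)

    def __add__(self, other: "ConfigCounts") -> "ConfigCounts":
        return ConfigCounts(m=self.m + other.m, m_tot=self.m_tot + other.m_tot)

    def __sub__(self, other: "ConfigCounts") -> "ConfigCounts":
        return ConfigCounts(m=self.m - other.m, m_tot=self.m_tot - other.m_tot)

    def scale(self, factor: float) -> "ConfigCounts":
        return ConfigCounts(m=self.m * factor, m_tot=self.m_tot * factor)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.m[ij])

    def to_dict(self) -> dict[str, float]:
        d = {f"m{i}{j}": float(self.m[i, j]) for i in range(3) for j in range(3)}
        d["m_tot"] = float(self.m_tot)
        return d


@dataclass(frozen=True)
class ConfigProbs:
    """The nine configuration probabilities ``p[i][j]``.

    The forward model cannot separate ``p00`` from ``p22`` (no branch of a
    4-leaf genealogy subtends all four leaves), so ``p[0][0]`` carries the
    lump ``p00 + p22`` and ``p[2][2]`` is zero unless the probabilities were
    produced with an outgroup that resolves fixed-derived sites.
    """

    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", _as33(self.p))
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-12):
            raise ModelError("configuration probabilities outside [0, 1]")
        if not np.isclose(self.p.sum(), 1.0, atol=1e-9):
            raise ModelError(f"configuration probabilities sum to {self.p.sum():g}, not 1")

    @property
    def lump(self) -> float:
        """The unidentifiable monomorphic + fixed-derived lump p00 + p22."""
        return float(self.p[0, 0] + self.p[2, 2])

    @property
    def polymorphic_sum(self) -> float:
        return 1.0 - self.lump

    def transpose(self) -> "ConfigProbs":
        return ConfigProbs(p=self.p.T.copy())

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.p[ij])

    def expected_counts(self, m_tot: float) -> ConfigCounts:
        """Expected (real-valued) ConfigCounts at ``m_tot`` sites."""
        return ConfigCounts(m=self.p * m_tot, m_tot=m_tot)


@dataclass(frozen=True)
class TTParams:
    """Parameters of the constant-ancestral-size (TT) divergence model.

    ``alpha_k`` is the probability that the two lineages sampled in
    population *k* do not coalesce before the split; ``T_k = mu * t_k`` and
    ``V_k = mu * nu_k`` are the split time and the conditional
    within-population coalescence time in mutation units; ``theta = mu * N_A``
    with ``N_A`` the ancestral size in chromosomes (so the diploid ancestral
    size is ``theta / (2 mu)``).
    """

    alpha1: float
    alpha2: float
    T1: float
    T2: float
    V1: float
    V2: float
    theta: float
    mu: float = DEFAULT_MU
    G: float = DEFAULT_G

    def __post_init__(self):
        for k, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2)):
            if not 0 < a <= 1:
                raise ModelError(f"{k}={a} must be in (0, 1]")
        for k, v in (("theta", self.theta), ("T1", self.T1), ("T2", self.T2),
                     ("V1", self.V1), ("V2", self.V2)):
            if v < 0:
                raise ModelError(f"{k}={v} must be nonnegative")

    def swap_populations(self) -> "TTParams":
        return replace(self, alpha1=self.alpha2, alpha2=self.alpha1,
                       T1=self.T2, T2=self.T1, V1=self.V2, V2=self.V1)

    @property
    def NA_diploid(self) -> float:
        return self.theta / (2.0 * self.mu)


@dataclass(frozen=True)
class GeneralParams:
    """Parameters of the general divergence model.

    The ancestral population enters only through ``tau_i = mu * E[T4_i]``,
    the mutation-scaled expected duration with ``i`` lineages of a 4-lineage
    coalescent started at the split.  Split times are supplied separately to
    :func:`general_forward_probs` (they co-occur with ``tau4`` only as the
    sums ``B_k = mu*t_k + tau4``).
    """

    alpha1: float
    alpha2: float
    V1: float
    V2: float
    tau2: float
    tau3: float
    tau4: float
    mu: float = DEFAULT_MU
    G: float = DEFAULT_G

    def __post_init__(self):
        for k, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2)):
            if not 0 <= a <= 1:
                raise ModelError(f"{k}={a} must be in [0, 1]")
        for k, v in (("V1", self.V1), ("V2", self.V2), ("tau2", self.tau2),
                     ("tau3", self.tau3), ("tau4", self.tau4)):
            if v < 0:
                raise ModelError(f"{k}={v} must be nonnegative")


@dataclass(frozen=True)
class AncestralSpectrum:
    """Probabilities ``b_i = P(A4 = i)`` that a size-4 sample drawn at the
    split in the ancestral population carries ``i`` derived variants."""

    b1: float
    b2: float
    b3: float

    def __post_init__(self):
        if min(self.b1, self.b2, self.b3) < 0:
            raise ModelError("ancestral spectrum probabilities must be nonnegative")
        if self.b1 + self.b2 + self.b3 > 1 + 1e-12:
            raise ModelError("ancestral spectrum probabilities sum above 1")


def _pack_probs(cells: dict[tuple[int, int], float]) -> ConfigProbs:
    p = np.zeros((3, 3))
    total = 0.0
    for (i, j), v in cells.items():
        if v < 0:
            raise ModelDomainError(
                f"configuration p{i},{j} = {v:g} is negative; parameters are "
                "outside the linear-in-mu regime"
            )
        p[i, j] = v
        total += v
    if total >= 1:
        raise ModelDomainError(
            f"polymorphic probabilities sum to {total:g} >= 1; parameters are "
            "outside the linear-in-mu regime"
        )
    p[0, 0] = 1.0 - total
    return ConfigProbs(p=p)


def tt_forward_probs(params: TTParams) -> ConfigProbs:
    """Configuration probabilities under a constant ancestral population.

    Exact closed forms, linear in the mutation rate.  The monomorphic lump
    ``p00 + p22`` is returned in the ``(0, 0)`` cell.
    """
    a1, a2 = params.alpha1, params.alpha2
    T1, T2, V1, V2 = params.T1, params.T2, params.V1, params.V2
    th = params.theta
    cells = {
        (1, 0): 2 * a1 * T1 + 2 * (1 - a1) * V1 + a1 * (4 - a2) * th / 3,
        (0, 1): 2 * a2 * T2 + 2 * (1 - a2) * V2 + a2 * (4 - a1) * th / 3,
        (2, 0): (1 - a1) * (T1 - V1) + (6 - 4 * a1 - 2 * a2 + a1 * a2) * th / 6,
        (0, 2): (1 - a2) * (T2 - V2) + (6 - 2 * a1 - 4 * a2 + a1 * a2) * th / 6,
        (1, 1): 2 * a1 * a2 * th / 3,
        (2, 1): (2 - a1) * a2 * th / 3,
        (1, 2): (2 - a2) * a1 * th / 3,
    }
    return _pack_probs(cells)


def general_forward_probs(params: GeneralParams, T1: float, T2: float) -> ConfigProbs:
    """Configuration probabilities under the general divergence model.

    ``T1, T2`` are the split times in mutation units (``mu * t_k``); they
    appear only through ``B_k = T_k + tau4``.
    """
    if T1 < 0 or T2 < 0:
        raise ModelError("split times must be nonnegative")
    a1, a2 = params.alpha1, params.alpha2
    V1, V2 = params.V1, params.V2
    t2_, t3_, t4_ = params.tau2, params.tau3, params.tau4
    S = 2 * t2_ + 3 * t3_
    cells = {
        (1, 0): 2 * (1 - a1) * V1 + 2 * a1 * (T1 + t4_) + a1 * (4 - a2) * S / 9 - a1 * t2_ / 3,
        (0, 1): 2 * (1 - a2) * V2 + 2 * a2 * (T2 + t4_) + a2 * (4 - a1) * S / 9 - a2 * t2_ / 3,
        (2, 0): (1 - a1) * (T1 + t4_ - V1)
                + (5 - 4 * a1 - a2 + a1 * a2) * S / 18 + (a1 - a2) * t2_ / 6,
        (0, 2): (1 - a2) * (T2 + t4_ - V2)
                + (5 - a1 - 4 * a2 + a1 * a2) * S / 18 + (a2 - a1) * t2_ / 6,
        (1, 1): 2 * a1 * a2 * S / 9,
        (2, 1): a2 * (1 - a1) * S / 9 + a2 * t2_ / 3,
        (1, 2): a1 * (1 - a2) * S / 9 + a1 * t2_ / 3,
    }
    return _pack_probs(cells)


def constant_tau_and_b(theta: float) -> tuple[float, float, float, AncestralSpectrum]:
    """Ancestral-coalescent summaries under a constant ancestral size.

    With ``E[T4_k] = 2 N_A / (k (k-1))`` (``N_A`` in chromosomes) and
    ``theta = mu * N_A``:

    * ``(tau2, tau3, tau4) = (theta, theta/3, theta/6)``
    * ``b = (2 theta, theta, (2/3) theta)`` via
      ``b1 = (2/3) tau2 + 2 tau3 + 4 tau4``, ``b2 = (2/3) tau2 + tau3``,
      ``b3 = (2/3) tau2``.
    """
    if theta < 0:
        raise ModelError("theta must be nonnegative")
    tau2, tau3, tau4 = theta, theta / 3.0, theta / 6.0
    b = AncestralSpectrum(
        b1=(2 / 3) * tau2 + 2 * tau3 + 4 * tau4,
        b2=(2 / 3) * tau2 + tau3,
        b3=(2 / 3) * tau2,
    )
    return tau2, tau3, tau4, b


def downsample_spectrum(b: AncestralSpectrum) -> tuple[float, float, float]:
    """Hypergeometric downsampling of the size-4 ancestral spectrum.

    A random subsample of size ``n`` from a size-4 sample is distributed as
    a direct size-``n`` sample, giving

    * ``a2_1 = b1/2 + 2 b2/3 + b3/2``
    * ``a3_1 = 3 b1/4 + b2/2``
    * ``a3_2 = b2/2 + 3 b3/4``
    """
    a2_1 = b.b1 / 2 + 2 * b.b2 / 3 + b.b3 / 2
    a3_1 = 3 * b.b1 / 4 + b.b2 / 2
    a3_2 = b.b2 / 2 + 3 * b.b3 / 4
    return a2_1, a3_1, a3_2
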