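"""Per-site coalescent simulator for the 2+2 (plus optional outgroup) sample.

Generates 4-leaf (or 6-leaf, with an outgroup) genealogies under a
two-population split demography with a piecewise-constant ancestral size
(one altered epoch, e.g. a bottleneck) and an optional single pulse of
admixture.  Under the independent-sites composite-likelihood assumption,
the probability that a site shows configuration ``(i, j)`` equals the
mutation rate times the expected total length of branches subtending
``i`` population-1 leaves and ``j`` population-2 leaves.  The simulator
therefore averages per-genealogy branch lengths over ``R`` Monte-Carlo
genealogies and converts them to expected (or multinomially sampled)
configuration counts — statistically equivalent to simulating one
genealogy per site, at a tiny fraction of the cost for genome-scale
``m_tot``.

Sizes are configured in *diploid individuals*; the pairwise coalescence
rate in a population of ``N`` diploids is ``1 / (2N)`` per generation
(``2N`` chromosomes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import DEFAULT_MU, ConfigCounts, ConfigProbs, ModelError
from .sites import BlockedCounts

__all__ = [
    "Bottleneck",
    "AdmixturePulse",
    "OutgroupConfig",
    "DemographyConfig",
    "Genealogy4",
    "TruthRecord",
    "SimulationResult",
    "simulate_genealogy",
    "genealogy_config_probs",
    "simulate_counts",
    "true_alpha",
    "ancestral_t4",
    "write_site_table",
]


@dataclass(frozen=True)
class Bottleneck:
    """One altered epoch in the ancestral population.

    Looking backwards from the split: the ancestral size is ``NA`` for
    ``phi`` generations, then ``lam * NA`` for ``tau_b`` generations, then
    ``NA`` again.  ``lam < 1`` is a bottleneck, ``lam > 1`` an expansion.
    """

    lam: float
    tau_b: float
    phi: float = 0.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ModelError("bottleneck size multiplier lam must be positive")
        if self.tau_b < 0 or self.phi < 0:
            raise ModelError("bottleneck tau_b and phi must be nonnegative")


@dataclass(frozen=True)
class AdmixturePulse:
    """A single pulse: fraction ``gamma`` of the recipient daughter
    population is replaced by migrants from the donor, ``delta``
    generations ago.  Backwards in time, each lineage in the recipient
    jumps to the donor with probability ``gamma`` at time ``delta``.
    The donor defaults to the other daughter; ``"outgroup"`` is allowed
    when an outgroup is configured."""

    gamma: float
    delta: float
    recipient: int = 2
    donor: "int | str | None" = None

    def __post_init__(self):
        if not 0 <= self.gamma <= 1:
            raise ModelError("admixture gamma must be in [0, 1]")
        if self.delta < 0:
            raise ModelError("admixture delta must be nonnegative")
        if self.recipient not in (1, 2):
            raise ModelError("admixture recipient must be population 1 or 2")
        if self.donor not in (None, 1, 2, "outgroup"):
            raise ModelError("admixture donor must be 1, 2, 'outgroup' or None")
        if self.donor == self.recipient:
            raise ModelError("admixture donor and recipient must differ")

    def donor_pop(self) -> "int | str":
        if self.donor is not None:
            return self.donor
        return 2 if self.recipient == 1 else 1


@dataclass(frozen=True)
class OutgroupConfig:
    """A third, deeper-branching population (two sampled chromosomes),
    joining the ancestor of populations 1 and 2 ``t_out`` generations ago."""

    t_out: float
    N_out: float

    def __post_init__(self):
        if self.t_out <= 0 or self.N_out <= 0:
            raise ModelError("outgroup t_out and N_out must be positive")


@dataclass(frozen=True)
class DemographyConfig:
    """A two-population split scenario for the per-site simulator.

    ``N1, N2, NA`` are diploid sizes (daughters constant; ancestral
    piecewise-constant via ``bottleneck``); ``t_split`` in generations.
    ``m_tot`` is the number of sites represented, ``R`` the number of
    Monte-Carlo genealogies, ``mode`` either ``"expected"`` (real-valued
    expected counts) or ``"multinomial"`` (integer sampled counts).
    """

    N1: float
    N2: float
    NA: float
    t_split: float
    bottleneck: Bottleneck | None = None
    admixture: AdmixturePulse | None = None
    outgroup: OutgroupConfig | None = None
    mu: float = DEFAULT_MU
    m_tot: float = 1e9
    R: int = 200_000
    seed: int | None = None
    mode: str = "expected"

    def __post_init__(self):
        if min(self.N1, self.N2, self.NA) <= 0:
            raise ModelError("population sizes must be positive")
        if self.t_split < 0:
            raise ModelError("t_split must be nonnegative")
        if self.admixture is not None:
            if self.admixture.delta > self.t_split:
                raise ModelError("admixture pulse must occur no earlier than the split "
                                 "(delta <= t_split)")
            if self.admixture.donor == "outgroup" and self.outgroup is None:
                raise ModelError("admixture donor 'outgroup' requires an outgroup config")
        if self.outgroup is not None and self.outgroup.t_out <= self.t_split:
            raise ModelError("outgroup split t_out must predate t_split")
        if self.mode not in ("expected", "multinomial"):
            raise ModelError(f"unknown mode {self.mode!r}")
        if self.mu < 0:
            raise ModelError("mu must be nonnegative")
        if self.m_tot <= 0:
            raise ModelError("m_tot must be positive")

    def ancestral_epochs(self) -> list[tuple[float, float, float]]:
        """Ancestral diploid size as ``(start, end, N)`` epochs, times
        measured in generations since the split (backwards)."""
        if self.bottleneck is None or self.bottleneck.tau_b == 0:
            return [(0.0, math.inf, self.NA)]
        b = self.bottleneck
        epochs = []
        if b.phi > 0:
            epochs.append((0.0, b.phi, self.NA))
        epochs.append((b.phi, b.phi + b.tau_b, b.lam * self.NA))
        epochs.append((b.phi + b.tau_b, math.inf, self.NA))
        return epochs


@dataclass
class Genealogy4:
    """A simulated genealogy with branch lengths keyed by subtended leaves.

    ``branches`` maps a configuration ``(i, j, k)`` — the number of
    population-1, population-2 and outgroup leaves a branch subtends — to
    the total length (generations) of such branches.  ``merges`` records
    ``(time, config_a, config_b)`` coalescence events; ``H1``/``H2``
    indicate whether the two lineages sampled in population 1/2 found
    their common ancestor before the split.
    """

    branches: dict[tuple[int, int, int], float]
    merges: list[tuple[float, tuple[int, int, int], tuple[int, int, int]]]
    H1: bool
    H2: bool
    tmrca: float

    @property
    def total_length(self) -> float:
        return sum(self.branches.values())


def _pop_size(cfg: DemographyConfig, pop, t: float) -> float:
    if pop == 1:
        return cfg.N1
    if pop == 2:
        return cfg.N2
    if pop == "out":
        return cfg.outgroup.N_out
    # ancestral (and root) population
    for start, end, n in cfg.ancestral_epochs():
        if cfg.t_split + start <= t < cfg.t_split + end:
            return n
    return cfg.NA


def simulate_genealogy(cfg: DemographyConfig, rng: np.random.Generator) -> Genealogy4:
    """Simulate one labeled genealogy under the configured demography.

    Event-driven: between demographic events, each population with ``k``
    lineages coalesces at rate ``k(k-1)/2 / (2N)`` per generation.
    """
    # (config, pop) per lineage; configs are (i, j, k) leaf counts
    lineages: list[tuple[tuple[int, int, int], object]] = [
        ((1, 0, 0), 1), ((1, 0, 0), 1), ((0, 1, 0), 2), ((0, 1, 0), 2),
    ]
    events: list[tuple[float, str]] = [(cfg.t_split, "split")]
    if cfg.admixture is not None:
        events.append((cfg.admixture.delta, "pulse"))
    for start, end, _ in cfg.ancestral_epochs()[1:]:
        events.append((cfg.t_split + start, "resize"))
    if cfg.outgroup is not None:
        lineages += [((0, 0, 1), "out"), ((0, 0, 1), "out")]
        events.append((cfg.outgroup.t_out, "join_outgroup"))
    events.sort()
    events.append((math.inf, "end"))

    branches: dict[tuple[int, int, int], float] = {}
    merges: list[tuple[float, tuple, tuple]] = []
    t = 0.0
    h1_time = math.inf
    h2_time = math.inf
    ev = 0

    def apply_event(tag):
        nonlocal lineages
        if tag == "split":
            lineages = [(c, "anc" if p in (1, 2) else p) for c, p in lineages]
        elif tag == "join_outgroup":
            lineages = [(c, "anc") for c, _ in lineages]
        elif tag == "pulse":
            adm = cfg.admixture
            donor = adm.donor_pop()
            if donor == "outgroup":
                donor = "out"
            lineages = [
                (c, donor) if p == adm.recipient and rng.random() < adm.gamma else (c, p)
                for c, p in lineages
            ]
        # "resize": nothing to relabel; sizes are read per-interval

    while ev < len(events) and events[ev][0] <= t:
        apply_event(events[ev][1])
        ev += 1

    while len(lineages) > 1:
        t_next = events[ev][0] if ev < len(events) else math.inf
        # per-population coalescence rates (sizes constant until t_next)
        pops: dict[object, list[int]] = {}
        for idx, (_, p) in enumerate(lineages):
            pops.setdefault(p, []).append(idx)
        rates = []
        for p, members in pops.items():
            k = len(members)
            if k >= 2:
                rates.append((p, members, k * (k - 1) / 2.0 / (2.0 * _pop_size(cfg, p, t))))
        total_rate = sum(r for _, _, r in rates)
        wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
        if t + wait < t_next:
            dt = wait
            for c, _ in lineages:
                branches[c] = branches.get(c, 0.0) + dt
            t += dt
            # choose population proportional to its rate, then a uniform pair
            u = rng.random() * total_rate
            acc = 0.0
            for p, members, r in rates:
                acc += r
                if u <= acc:
                    break
            i1, i2 = rng.choice(len(members), size=2, replace=False)
            a, b = members[i1], members[i2]
            ca, cb = lineages[a][0], lineages[b][0]
            merged = (ca[0] + cb[0], ca[1] + cb[1], ca[2] + cb[2])
            merges.append((t, ca, cb))
            if merged[0] == 2 and t < h1_time:
                h1_time = t
            if merged[1] == 2 and t < h2_time:
                h2_time = t
            lineages = [l for idx, l in enumerate(lineages) if idx not in (a, b)]
            lineages.append((merged, p))
        else:
            dt = t_next - t
            if dt > 0:
                for c, _ in lineages:
                    branches[c] = branches.get(c, 0.0) + dt
            t = t_next
            apply_event(events[ev][1])
            ev += 1

    return Genealogy4(
        branches=branches, merges=merges,
        H1=h1_time < cfg.t_split, H2=h2_time < cfg.t_split, tmrca=t,
    )


def genealogy_config_probs(g: Genealogy4, mu: float) -> ConfigProbs:
    """Per-site configuration probabilities implied by one genealogy.

    A mutation on a branch subtending leaf subset ``S`` produces the
    configuration with derived counts ``(|S ∩ pop1|, |S ∩ pop2|)``; under
    the linear-in-mu regime the probability is ``mu`` times the total
    branch length for that configuration.  Rejects genealogies with
    ``mu * total_length > 0.1`` (linearity would be violated).
    """
    if mu * g.total_length > 0.1:
        raise ModelError(
            f"mu * total branch length = {mu * g.total_length:g} > 0.1; "
            "the linear-in-mu approximation does not hold"
        )
    p = np.zeros((3, 3))
    for (i, j, _k), length in g.branches.items():
        p[i, j] += mu * length
    p[0, 0] = 1.0 - (p.sum() - p[0, 0])
    return ConfigProbs(p=p)


@dataclass(frozen=True)
class TruthRecord:
    """Generative ground truth attached to a simulated data set.

    ``alpha1/alpha2`` are closed-form no-coalescence probabilities,
    ``alpha*_mc`` their Monte-Carlo counterparts (fractions of genealogies
    without a within-pair coalescence before the split); ``tau2/3/4`` are
    MC estimates of ``mu * E[T4_i]`` in the ancestral demography; ``theta``
    and ``T1/T2`` are the constant-model parameter values implied by the
    configuration (exact only when the ancestral size is constant).
    """

    config: DemographyConfig
    alpha1: float
    alpha2: float
    alpha1_mc: float
    alpha2_mc: float
    tau2: float
    tau3: float
    tau4: float
    theta: float
    T1: float
    T2: float
    V1: float
    V2: float


@dataclass(frozen=True)
class SimulationResult:
    """Counts (total and optionally blocked / outgroup-ascertained) plus truth."""

    counts: ConfigCounts
    truth: TruthRecord
    counts_star: ConfigCounts | None = None
    blocked: BlockedCounts | None = None

    def __iter__(self):
        return iter((self.counts, self.truth))


def _conditional_nu(N: float, t: float) -> float:
    """E[pair coalescence time | coalescence before t] in a constant
    population of N diploids (exponential with mean 2N truncated at t)."""
    if t == 0:
        return 0.0
    r = 1.0 / (2.0 * N)
    return 1.0 / r - t * math.exp(-r * t) / (1.0 - math.exp(-r * t))


def true_alpha(cfg: DemographyConfig) -> tuple[float, float]:
    """Closed-form probability that each sampled pair does not coalesce
    before the split.

    For a constant daughter of ``N`` diploids this is
    ``exp(-t_split / (2N))``; the marginal pairwise coalescence time is
    unaffected by other lineages, so the same form holds for the admixture
    donor.  For the recipient, the pair survives ``[0, delta]`` in the
    recipient and then either both stay, both jump to the donor, or are
    separated (in which case they cannot coalesce before the split).
    """
    def plain(N):
        return math.exp(-cfg.t_split / (2.0 * N))

    a = [plain(cfg.N1), plain(cfg.N2)]
    adm = cfg.admixture
    if adm is not None and adm.gamma > 0:
        rec = adm.recipient
        N_r = cfg.N1 if rec == 1 else cfg.N2
        donor = adm.donor_pop()
        N_d = cfg.outgroup.N_out if donor == "outgroup" else (cfg.N1 if donor == 1 else cfg.N2)
        rest = cfg.t_split - adm.delta
        g = adm.gamma
        a[rec - 1] = math.exp(-adm.delta / (2.0 * N_r)) * (
            (1 - g) ** 2 * math.exp(-rest / (2.0 * N_r))
            + g ** 2 * math.exp(-rest / (2.0 * N_d))
            + 2 * g * (1 - g)
        )
    return a[0], a[1]


def ancestral_t4(
    cfg: DemographyConfig, R: int = 100_000, rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Monte-Carlo mean durations ``E[T4_k]`` of a 4-lineage coalescent
    started at the split in the (piecewise-constant) ancestral population.

    Vectorized over replicates; returns means (generations) and the
    mutation-scaled ``tau2/3/4``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    epochs = cfg.ancestral_epochs()
    pos = np.zeros(R)  # elapsed time since the split, per replicate
    means: dict[int, float] = {}
    for k in (4, 3, 2):
        pairs = k * (k - 1) / 2.0
        E = rng.exponential(size=R)  # unit-rate hazard targets
        wait = np.zeros(R)
        remaining = E.copy()
        cur = pos.copy()
        done = np.zeros(R, dtype=bool)
        for start, end, n in epochs:
            rate = pairs / (2.0 * n)
            lo = np.maximum(cur, start)
            span = end - lo  # inf in last epoch
            hazard = np.where(span > 0, rate * span, 0.0)
            finish = ~done & (remaining <= hazard)
            wait[finish] = lo[finish] + remaining[finish] / rate - pos[finish]
            done |= finish
            cont = ~done & (span > 0)
            remaining[cont] -= hazard[cont]
            cur[cont] = end
        means[k] = float(np.mean(wait))
        pos = pos + wait
    return {
        "T44": means[4], "T43": means[3], "T42": means[2],
        "tau4": cfg.mu * means[4], "tau3": cfg.mu * means[3], "tau2": cfg.mu * means[2],
    }


def _piecewise_wait(rng, pos: np.ndarray, pairs: float, epochs) -> np.ndarray:
    """Vectorized waiting time to the next coalescence for ``pairs``
    lineage pairs, starting ``pos`` generations after the split, under
    piecewise-constant ancestral epochs ``(start, end, N)``."""
    n = pos.shape[0]
    E = rng.exponential(size=n)
    wait = np.zeros(n)
    remaining = E
    cur = pos.copy()
    done = np.zeros(n, dtype=bool)
    for start, end, size in epochs:
        rate = pairs / (2.0 * size)
        lo = np.maximum(cur, start)
        span = end - lo
        hazard = np.where(span > 0, rate * span, 0.0)
        finish = ~done & (remaining <= hazard)
        wait[finish] = lo[finish] + remaining[finish] / rate - pos[finish]
        done |= finish
        cont = ~done & (span > 0)
        remaining = np.where(cont, remaining - hazard, remaining)
        cur = np.where(cont, end, cur)
    return wait


# Alive-lineage states of the ancestral-phase coalescent for the plain
# two-population sample (no admixture, no outgroup).  Configurations are
# (i, j) leaf counts; states are multisets of configurations.
_S4 = ((1, 0), (1, 0), (0, 1), (0, 1))
_S3_A = ((2, 0), (0, 1), (0, 1))   # pop-1 pair coalesced
_S3_B = ((1, 0), (1, 0), (0, 2))   # pop-2 pair coalesced
_S3_C = ((1, 1), (1, 0), (0, 1))   # one cross coalescence
_S2 = {
    0: ((2, 0), (0, 2)),
    1: ((2, 1), (0, 1)),
    2: ((1, 2), (1, 0)),
    3: ((1, 1), (1, 1)),
}
# transition tables: state -> list of (probability, next_state_id)
_T3 = {  # from 3 lineages (3 equally likely pairs)
    "A": [(2 / 3, 1), (1 / 3, 0)],
    "B": [(2 / 3, 2), (1 / 3, 0)],
    "C": [(1 / 3, 1), (1 / 3, 2), (1 / 3, 3)],
}


def _simulate_lengths_fast(cfg: DemographyConfig, R: int, rng: np.random.Generator):
    """Vectorized expected-branch-length accumulation for the plain
    two-population split (no admixture, no outgroup).

    Returns ``(sum_len, sumsq_len, n_h1, n_h2)`` matching the generic
    per-genealogy loop: per-replicate total branch length by configuration,
    summed and sum-squared over replicates.
    """
    epochs = cfg.ancestral_epochs()
    t = cfg.t_split
    sum_len = np.zeros((3, 3))
    sumsq_len = np.zeros((3, 3))
    n_h1 = 0
    n_h2 = 0
    chunk = 200_000
    for lo in range(0, R, chunk):
        n = min(chunk, R - lo)
        lengths = np.zeros((n, 3, 3))

        # daughter phase: each pair coalesces at an exponential time,
        # truncated at the split
        x1 = rng.exponential(2.0 * cfg.N1, size=n)
        x2 = rng.exponential(2.0 * cfg.N2, size=n)
        h1 = x1 < t
        h2 = x2 < t
        n_h1 += int(h1.sum())
        n_h2 += int(h2.sum())
        lengths[:, 1, 0] += 2.0 * np.minimum(x1, t)
        lengths[:, 2, 0] += np.maximum(t - x1, 0.0)
        lengths[:, 0, 1] += 2.0 * np.minimum(x2, t)
        lengths[:, 0, 2] += np.maximum(t - x2, 0.0)

        pos = np.zeros(n)  # elapsed time since the split

        # four lineages entering: one coalescence takes the state to
        # 3 lineages (state A, B or C depending on which pair merged)
        four = ~h1 & ~h2
        state3 = np.full(n, "", dtype="U1")
        state3[h1 & ~h2] = "A"
        state3[~h1 & h2] = "B"
        if four.any():
            w = _piecewise_wait(rng, pos[four], 6.0, epochs)
            for c in _S4:
                lengths[four, c[0], c[1]] += w
            pos[four] += w
            u = rng.random(four.sum())
            s = np.where(u < 1 / 6, "A", np.where(u < 2 / 6, "B", "C"))
            state3[four] = s

        # three lineages: one coalescence leaves one of four 2-lineage states
        state2 = np.full(n, -1, dtype=np.int8)
        state2[h1 & h2] = 0
        three = state3 != ""
        if three.any():
            w = _piecewise_wait(rng, pos[three], 3.0, epochs)
            widx = np.zeros(n)
            widx[three] = w
            for tag, alive in (("A", _S3_A), ("B", _S3_B), ("C", _S3_C)):
                mask = state3 == tag
                for c in alive:
                    lengths[mask, c[0], c[1]] += widx[mask]
            pos[three] += widx[three]
            u = rng.random(n)
            for tag, trans in _T3.items():
                mask = state3 == tag
                acc = 0.0
                assigned = np.zeros(n, dtype=bool)
                for prob, nxt in trans:
                    acc += prob
                    pick = mask & ~assigned & (u < acc)
                    state2[pick] = nxt
                    assigned |= pick
                state2[mask & ~assigned] = trans[-1][1]

        # two lineages: final coalescence to the root
        w = _piecewise_wait(rng, pos, 1.0, epochs)
        for sid, alive in _S2.items():
            mask = state2 == sid
            for c in alive:
                lengths[mask, c[0], c[1]] += w[mask]

        sum_len += lengths.sum(axis=0)
        sumsq_len += (lengths ** 2).sum(axis=0)
    return sum_len, sumsq_len, n_h1, n_h2


def simulate_counts(cfg: DemographyConfig, n_blocks: int | None = None) -> SimulationResult:
    """Simulate configuration counts under ``cfg``.

    Averages per-genealogy branch lengths over ``cfg.R`` genealogies,
    converts to expected configuration probabilities, and returns expected
    (``mode="expected"``) or multinomially sampled integer
    (``mode="multinomial"``) counts at ``cfg.m_tot`` sites, together with
    the generative :class:`TruthRecord`.  With an outgroup, the
    outgroup-ascertained counts (sites with at least one derived copy in
    the outgroup) are returned as ``counts_star``.  ``n_blocks`` splits
    the sites into equally sized blocks for jackknifing.
    """
    if cfg.R < 1000:
        raise ModelError(f"R = {cfg.R} Monte-Carlo genealogies is too few (need >= 1000)")
    rng = np.random.default_rng(cfg.seed)

    sum_len_star = np.zeros((3, 3))
    plain = (cfg.outgroup is None
             and (cfg.admixture is None or cfg.admixture.gamma == 0))
    if plain:
        # vectorized path: identical process, enumerated ancestral states
        sum_len, sumsq_len, n_h1, n_h2 = _simulate_lengths_fast(cfg, cfg.R, rng)
    else:
        sum_len = np.zeros((3, 3))
        sumsq_len = np.zeros((3, 3))
        n_h1 = 0
        n_h2 = 0
        for _ in range(cfg.R):
            g = simulate_genealogy(cfg, rng)
            n_h1 += g.H1
            n_h2 += g.H2
            per = np.zeros((3, 3))
            per_star = np.zeros((3, 3))
            for (i, j, k), length in g.branches.items():
                per[i, j] += length
                if k >= 1:
                    per_star[i, j] += length
            sum_len += per
            sumsq_len += per ** 2
            sum_len_star += per_star

    mean_len = sum_len / cfg.R
    # MC standard error of each polymorphic probability, relative to its value
    var_len = sumsq_len / cfg.R - mean_len ** 2
    se_len = np.sqrt(np.maximum(var_len, 0.0) / cfg.R)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean_len > 0, se_len / mean_len, 0.0)
    rel[0, 0] = 0.0
    if np.any(rel > 0.01):
        worst = np.unravel_index(np.argmax(rel), rel.shape)
        warnings.warn(
            f"Monte-Carlo SE of p{worst[0]},{worst[1]} is {rel[worst]:.1%} of its "
            f"value at R={cfg.R}; consider increasing R",
            RuntimeWarning, stacklevel=2,
        )

    p = cfg.mu * mean_len
    p[0, 0] = 1.0 - (p.sum() - p[0, 0])

    counts_star = None
    if cfg.outgroup is None:
        counts = _draw_counts(p, cfg.m_tot, cfg.mode, rng)
    else:
        # joint draw over (configuration, ascertained?) so that the
        # ascertained table is an exact cellwise subset of the full table
        p_star = cfg.mu * sum_len_star / cfg.R
        if cfg.mode == "expected":
            counts = ConfigCounts(m=p * cfg.m_tot, m_tot=cfg.m_tot)
            m_star = p_star * cfg.m_tot
        else:
            n = int(round(cfg.m_tot))
            joint = np.concatenate([(p - p_star).ravel(), p_star.ravel()])
            draw = rng.multinomial(n, joint / joint.sum())
            m_star = draw[9:].reshape(3, 3).astype(float)
            counts = ConfigCounts(m=(draw[:9].reshape(3, 3) + m_star), m_tot=float(n))
        counts_star = ConfigCounts(m=m_star, m_tot=float(m_star.sum()))

    blocked = None
    if n_blocks is not None:
        if n_blocks < 2:
            raise ModelError("n_blocks must be at least 2")
        per_block = cfg.m_tot / n_blocks
        blocks = []
        for b in range(n_blocks):
            blocks.append((f"block{b}", _draw_counts(p, per_block, cfg.mode, rng)))
        total = blocks[0][1]
        for _, c in blocks[1:]:
            total = total + c
        blocked = BlockedCounts(blocks=blocks, total=total)

    t4 = ancestral_t4(cfg, R=min(cfg.R, 200_000), rng=rng)
    a1, a2 = true_alpha(cfg)
    adm = cfg.admixture
    truth = TruthRecord(
        config=cfg,
        alpha1=a1, alpha2=a2,
        alpha1_mc=1.0 - n_h1 / cfg.R, alpha2_mc=1.0 - n_h2 / cfg.R,
        tau2=t4["tau2"], tau3=t4["tau3"], tau4=t4["tau4"],
        theta=cfg.mu * 2.0 * cfg.NA,
        T1=cfg.mu * cfg.t_split, T2=cfg.mu * cfg.t_split,
        V1=cfg.mu * _conditional_nu(cfg.N1, cfg.t_split)
        if not (adm and adm.gamma > 0 and adm.recipient == 1) else math.nan,
        V2=cfg.mu * _conditional_nu(cfg.N2, cfg.t_split)
        if not (adm and adm.gamma > 0 and adm.recipient == 2) else math.nan,
    )
    return SimulationResult(counts=counts, truth=truth, counts_star=counts_star, blocked=blocked)


def _draw_counts(p: np.ndarray, m_tot: float, mode: str, rng: np.random.Generator) -> ConfigCounts:
    if mode == "expected":
        return ConfigCounts(m=p * m_tot, m_tot=m_tot)
    n = int(round(m_tot))
    m = rng.multinomial(n, p.ravel() / p.sum()).reshape(3, 3).astype(float)
    return ConfigCounts(m=m, m_tot=float(n))


def write_site_table(
    path,
    counts: ConfigCounts,
    counts_star: ConfigCounts | None = None,
    chrom: str = "sim1",
    ancestral: str = "A",
    rng: np.random.Generator | None = None,
) -> None:
    """Write integer configuration counts as a per-site TSV table.

    Emits one row per site (``chrom  pos  ancestral  d1  d2[  d_out]``)
    with consecutive positions in shuffled configuration order.  When
    ``counts_star`` (a cellwise subset of ``counts``) is given, that many
    sites per cell carry ``d_out = 1`` and the rest ``d_out = 0``.
    Intended for end-to-end tests at small ``m_tot``.
    """
    if rng is None:
        rng = np.random.default_rng()
    m = np.round(counts.m).astype(int)
    rows = []
    for i in range(3):
        for j in range(3):
            n_star = 0
            if counts_star is not None:
                n_star = int(round(counts_star.m[i, j]))
                if n_star > m[i, j]:
                    raise ModelError("counts_star must be a cellwise subset of counts")
            if counts_star is not None:
                rows += [(i, j, 1)] * n_star + [(i, j, 0)] * (m[i, j] - n_star)
            else:
                rows += [(i, j, None)] * m[i, j]
    order = rng.permutation(len(rows))
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ancestral", "d1", "d2"]
        if counts_star is not None:
            header.append("d_out")
        fh.write("\t".join(header) + "\n")
        for pos, idx in enumerate(order, start=1):
            i, j, k = rows[idx]
            fields = [chrom, str(pos), ancestral, str(i), str(j)]
            if counts_star is not None:
                fields.append(str(k))
            fh.write("\t".join(fields) + "\n")
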