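"""Population growth, genotype fitness, and selection--mutation dynamics.

Each species carries two genotypes: the reaction-performing genotype ``p``
and the wild type ``q`` (p + q = 1).  Fitness of the performer increases
linearly with the level of its substrate nutrient; mutation occurs at
reproduction, with loss of function (p -> q) an order of magnitude more
probable than gain of function (q -> p).  Mutation is realized by sampling
individual reproductive events, so the frequency dynamics are stochastic
even before any diffusion term is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "SpeciesState",
    "MutationDraw",
    "performer_count",
    "growth_rate",
    "fitnesses",
    "mutation_rates",
    "sample_mutations",
    "expected_mutations",
    "frequency_derivatives",
    "round_half_away",
]


@dataclass
class SpeciesState:
    """Population size and genotype frequencies for one species."""

    id: str          # one of "A", "B", "C", "D"
    M: float         # population size (continuous, >= 0)
    p: float         # frequency of the reaction-performing genotype

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass
class MutationDraw:
    """Outcome of sampling one timestep's reproductive events.

    ``m_p``/``m_q`` are the realized fractions of events in which the
    offspring genotype differed from the parent; they are 0 whenever the
    corresponding event count is 0 (division-by-zero guard).
    """

    RE_p: int
    RE_q: int
    same_p: int
    same_q: int
    m_p: float
    m_q: float


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def performer_count(p: float, M: float) -> int:
    """Number of reaction-performing individuals: round(p * M)."""
    return round_half_away(p * M)


def growth_rate(
    M: float,
    g0: float,
    K: float,
    alpha: float = 0.0,
    is_C: bool = False,
    square_outside: bool = False,
) -> float:
    """dM/dt for one species.

    Two readings of the density regulation are supported (both vanish at
    M = K).  With ``square_outside=False``: ``g0*M*(1 - (M/K)**2)``.  With
    ``square_outside=True``: the square-outside form, implemented with a
    restoring sign above carrying capacity,
    ``g0*M*(1 - M/K)*|1 - M/K|`` -- the literal square would make any
    noise-driven overshoot of K self-amplifying, whereas below K the two
    coincide.  Species C additionally loses ``M * alpha`` individuals per
    unit time once the suppression function is active.
    """
    r = M / K
    if square_outside:
        d = 1.0 - r
        base = g0 * M * d * abs(d)
    else:
        base = g0 * M * (1.0 - r * r)
    if is_C:
        base -= M * alpha
    return base


def fitnesses(
    p: float, M: float, J_substrate: float, params: ModelParams
) -> tuple[float, float, float]:
    """Absolute fitnesses (W_p, W_q) and the count-weighted mean fitness.

    W_p = W0*(1 + s*J_substrate), W_q = W0; the mean weights each genotype's
    fitness by its individual count (performers from :func:`performer_count`,
    the remainder wild type).  An empty population returns W_mean = W0.
    """
    W_p = params.W0 * (1.0 + params.s * J_substrate)
    W_q = params.W0
    if M <= 0.0:
        return W_p, W_q, params.W0
    n_p = performer_count(p, M)
    n_q = M - n_p
    W_mean = (W_p * n_p + W_q * n_q) / M
    return W_p, W_q, W_mean


def mutation_rates(m0: float) -> tuple[float, float]:
    """Per-event mutation probabilities (loss p->q, gain q->p) = (m0, m0**2)."""
    return m0, m0 * m0


def _reproductive_events(W: float, freq: float, M: float, scale_by_M: bool) -> int:
    x = W * freq * (M if scale_by_M else 1.0)
    return max(round_half_away(x), 0)


def sample_mutations(
    W_p: float,
    W_q: float,
    p: float,
    q: float,
    m0_p: float,
    m0_q: float,
    rng,
    M: float = 1.0,
    scale_by_M: bool = False,
) -> MutationDraw:
    """Sample one timestep's reproductive events and realized mutations.

    The event count per genotype is round(W * frequency) (optionally scaled
    by population size).  Each event draws u ~ U(0,1); the offspring keeps
    the parental genotype when u - m0 > 0, otherwise it mutates.  The
    realized mutation fraction is (events - same)/events.
    """
    RE_p = _reproductive_events(W_p, p, M, scale_by_M)
    RE_q = _reproductive_events(W_q, q, M, scale_by_M)
    same_p = same_q = 0
    if RE_p > 0:
        u = rng.random(RE_p)
        same_p = int((u - m0_p > 0.0).sum())
    if RE_q > 0:
        u = rng.random(RE_q)
        same_q = int((u - m0_q > 0.0).sum())
    m_p = (RE_p - same_p) / RE_p if RE_p > 0 else 0.0
    m_q = (RE_q - same_q) / RE_q if RE_q > 0 else 0.0
    return MutationDraw(RE_p, RE_q, same_p, same_q, m_p, m_q)


def expected_mutations(
    W_p: float,
    W_q: float,
    p: float,
    q: float,
    m0_p: float,
    m0_q: float,
    M: float = 1.0,
    scale_by_M: bool = False,
) -> MutationDraw:
    """Expectation of :func:`sample_mutations` (used in deterministic mode)."""
    RE_p = _reproductive_events(W_p, p, M, scale_by_M)
    RE_q = _reproductive_events(W_q, q, M, scale_by_M)
    m_p = m0_p if RE_p > 0 else 0.0
    m_q = m0_q if RE_q > 0 else 0.0
    return MutationDraw(
        RE_p, RE_q,
        round_half_away(RE_p * (1 - m_p)), round_half_away(RE_q * (1 - m_q)),
        m_p, m_q,
    )


def frequency_derivatives(
    W_p: float, W_q: float, W_mean: float, draw: MutationDraw
) -> tuple[float, float]:
    """(dp/dt, dq/dt): normalized fitness excess plus realized mutation flux.

    dp/dt = (W_p - W_mean)/W_mean - m_p + m_q and symmetrically for q.  The
    mutation contributions cancel between the two derivatives; the selection
    parts are each normalized by the mean fitness.
    """
    if W_mean <= 0.0:
        raise ValueError(f"mean fitness must be positive, got {W_mean}")
    dp = (W_p - W_mean) / W_mean - draw.m_p + draw.m_q
    dq = (W_q - W_mean) / W_mean + draw.m_p - draw.m_q
    return dp, dq


def clamp_frequency(p: float) -> float:
    """Clamp a genotype frequency to [0, 1]."""
    if p < 0.0:
        return 0.0
    if p > 1.0:
        return 1.0
    return p
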