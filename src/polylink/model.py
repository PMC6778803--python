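"""Probability model for bivalent meiosis in autopolyploid full-sib crosses.

Gamete and genotype transition probabilities between adjacent loci, the
uniform initial-state distribution, dosage emission functions, and the
polysomic segregation prior used for missing observations.

Conventions: recombination fractions live in ``[0, 0.5]`` (estimation code
clamps to ``[R_MIN, 0.5]``); dosage priors are length ``m+1`` vectors over
dosage classes ``0..m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .states import (
    _as_subset,
    _check_ploidy,
    gamete_subsets,
    genotype_decompose,
    recomb_count_matrix,
    recombinant_count,
)

__all__ = [
    "R_MIN",
    "MarkerPhase",
    "check_prior",
    "gamete_prob_given_config",
    "gamete_prob",
    "gametic_transition",
    "gametic_transition_matrix",
    "genotypic_transition",
    "initial_state",
    "dosage_profile",
    "delta_dosage",
    "delta_matrix",
    "emission_global_error",
    "error_rate_prior",
    "emission_prior",
    "gamete_dosage_pmf",
    "polysomic_prior",
    "dosage_span",
    "feasible_dosage_classes",
]

#: lower clamp for recombination fractions in estimation paths
R_MIN = 1e-7


@dataclass(frozen=True)
class MarkerPhase:
    """Homolog subsets carrying the counted allele at one marker.

    ``phiP``/``phiQ`` are subsets of ``{1..m}`` whose sizes equal the
    parental dosages ``d_P`` and ``d_Q``.
    """

    phiP: frozenset[int]
    phiQ: frozenset[int]

    @staticmethod
    def from_iterables(phiP, phiQ) -> "MarkerPhase":
        return MarkerPhase(frozenset(int(x) for x in phiP), frozenset(int(x) for x in phiQ))


def check_prior(probs, m: int, tol: float = 1e-9) -> np.ndarray:
    """Validate a dosage prior: length ``m+1``, nonnegative, sums to 1."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (m + 1,):
        raise ValueError(f"prior must have length {m + 1}, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("prior entries must be nonnegative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"prior must sum to 1 (got {p.sum()!r})")
    return p


def _check_r(r: float) -> float:
    r = float(r)
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    return r


def gamete_prob_given_config(S_k, S_k1, psi, r: float, m: int) -> float:
    """Probability of the gamete ``{S_k, S_k1}`` given a bivalent
    configuration ``psi`` (an iterable of homolog pairs).

    The gamete is producible from ``psi`` iff each bivalent contributes
    exactly one homolog at each locus; with ``l`` bivalents switching
    partner between the loci the probability is
    ``(1-r)^(m/2-l) * r^l / 2^(m/2)``; otherwise 0.
    """
    m = _check_ploidy(m)
    r = _check_r(r)
    a = set(_as_subset(S_k, m))
    b = set(_as_subset(S_k1, m))
    half = m // 2
    l = 0
    for pair in psi:
        pair = set(pair)
        at_k = a & pair
        at_k1 = b & pair
        if len(at_k) != 1 or len(at_k1) != 1:
            return 0.0
        if at_k != at_k1:
            l += 1
    return (1.0 - r) ** (half - l) * r**l / 2.0**half


def gamete_prob(S_k, S_k1, r: float, m: int) -> float:
    """Unconditional probability of the gamete ``{S_k, S_k1}``:
    ``l!(m/2-l)!/w_m * (1-r)^(m/2-l) r^l / 2^(m/2)``."""
    m = _check_ploidy(m)
    r = _check_r(r)
    from .states import count_bivalent_configs

    half = m // 2
    l = recombinant_count(S_k, S_k1, m)
    n_consistent = math.factorial(l) * math.factorial(half - l)
    return (
        n_consistent
        / count_bivalent_configs(m)
        * (1.0 - r) ** (half - l)
        * r**l
        / 2.0**half
    )


def gametic_transition(i: int, i1: int, r: float, m: int) -> float:
    """Conditional probability of gamete rank ``i1`` at locus k+1 given
    rank ``i`` at locus k: ``(1-r)^(m/2-l) r^l / C(m/2, l)``."""
    m = _check_ploidy(m)
    r = _check_r(r)
    L = recomb_count_matrix(m)
    n = L.shape[0]
    if not (1 <= i <= n and 1 <= i1 <= n):
        raise ValueError(f"gamete ranks must be in 1..{n}, got ({i}, {i1})")
    l = int(L[i - 1, i1 - 1])
    return (1.0 - r) ** (m // 2 - l) * r**l / math.comb(m // 2, l)


def gametic_transition_matrix(r: float, m: int) -> np.ndarray:
    """Full gamete-space transition matrix (symmetric, doubly stochastic)."""
    m = _check_ploidy(m)
    r = _check_r(r)
    L = recomb_count_matrix(m)
    half = m // 2
    denom = np.array([math.comb(half, l) for l in range(half + 1)], dtype=float)
    return (1.0 - r) ** (half - L) * r**L / denom[L]


def genotypic_transition(j: int, j1: int, r: float, m: int) -> float:
    """Genotype-space transition probability, the product of the two
    parental gametic transitions (via the ``(lP, lQ)`` class)."""
    from .states import genotype_pair_counts

    m = _check_ploidy(m)
    r = _check_r(r)
    lP, lQ = genotype_pair_counts(j, j1, m)
    half = m // 2
    return (
        (1.0 - r) ** (m - lP - lQ)
        * r ** (lP + lQ)
        / (math.comb(half, lP) * math.comb(half, lQ))
    )


def initial_state(j: int, m: int) -> float:
    """Uniform initial-state probability ``1/g_m``."""
    m = _check_ploidy(m)
    g = math.comb(m, m // 2) ** 2
    genotype_decompose(j, m)  # validates j
    return 1.0 / g


@lru_cache(maxsize=None)
def _dosage_profile_cached(phi: frozenset, m: int) -> np.ndarray:
    prof = np.array([len(phi & set(s)) for s in gamete_subsets(m)], dtype=np.int64)
    prof.setflags(write=False)
    return prof


def dosage_profile(phi, m: int) -> np.ndarray:
    """For each gamete rank, the allele count contributed by that gamete
    under the phase subset ``phi``: ``|phi & S_i|``, shape ``(C(m,m/2),)``."""
    m = _check_ploidy(m)
    phi = frozenset(int(x) for x in phi)
    if any(x < 1 or x > m for x in phi):
        raise ValueError(f"phase subset labels must be in 1..{m}, got {sorted(phi)}")
    return _dosage_profile_cached(phi, m)


def delta_dosage(j: int, phase: MarkerPhase, m: int) -> int:
    """Dosage implied by genotype state ``j`` under ``phase``:
    ``|phiP & S_P(j)| + |phiQ & S_Q(j)|`` (parental origins distinct)."""
    i, h = genotype_decompose(j, m)
    pP = dosage_profile(phase.phiP, m)
    pQ = dosage_profile(phase.phiQ, m)
    return int(pP[i - 1] + pQ[h - 1])


def delta_matrix(phase: MarkerPhase, m: int) -> np.ndarray:
    """Implied dosage for every genotype state, arranged as an
    ``(n_gametes, n_gametes)`` array over (P-gamete rank, Q-gamete rank)."""
    pP = dosage_profile(phase.phiP, m)
    pQ = dosage_profile(phase.phiQ, m)
    return pP[:, None] + pQ[None, :]


def emission_global_error(O: int, delta: int, epsilon: float, m: int) -> float:
    """Global-error emission: ``1-eps`` if the observed dosage matches the
    implied dosage, else ``eps/m``."""
    m = _check_ploidy(m)
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"error rate must be in [0, 1), got {epsilon}")
    return 1.0 - epsilon if int(O) == int(delta) else epsilon / m


def error_rate_prior(O: int, epsilon: float, m: int) -> np.ndarray:
    """The dosage prior equivalent to the global-error emission for an
    observed dosage ``O``: ``1-eps`` at class ``O``, ``eps/m`` elsewhere."""
    m = _check_ploidy(m)
    if not 0 <= int(O) <= m:
        raise ValueError(f"observed dosage must be in 0..{m}, got {O}")
    p = np.full(m + 1, epsilon / m)
    p[int(O)] = 1.0 - epsilon
    return p


def emission_prior(delta: int, prior) -> float:
    """Prior-based emission: the prior mass on the implied dosage class."""
    prior = np.asarray(prior, dtype=float)
    delta = int(delta)
    if not 0 <= delta < prior.shape[0]:
        raise ValueError(f"implied dosage {delta} outside prior support 0..{prior.shape[0] - 1}")
    return float(prior[delta])


@lru_cache(maxsize=None)
def gamete_dosage_pmf(d: int, m: int) -> np.ndarray:
    """Distribution of the allele count in one gamete from a parent with
    dosage ``d``: hypergeometric, ``P(a) = C(d,a) C(m-d, m/2-a) / C(m, m/2)``.
    Length ``m/2 + 1``."""
    m = _check_ploidy(m)
    if not 0 <= d <= m:
        raise ValueError(f"dosage must be in 0..{m}, got {d}")
    half = m // 2
    pmf = hypergeom.pmf(np.arange(half + 1), m, d, half)
    pmf.setflags(write=False)
    return pmf


def polysomic_prior(dP: int, dQ: int, m: int) -> np.ndarray:
    """Offspring dosage distribution under polysomic segregation for
    parental dosages ``(dP, dQ)``: the convolution of the two parental
    gamete-dosage distributions.  Length ``m+1``."""
    p = np.convolve(gamete_dosage_pmf(dP, m), gamete_dosage_pmf(dQ, m))
    # numerical floor: exact zeros for infeasible classes
    p[p < 1e-15] = 0.0
    return p / p.sum()


def dosage_span(x: int, m: int) -> int:
    """The operator ``u(x) = ||x - m/2| - m/2| = min(x, m-x)``."""
    m = _check_ploidy(m)
    if not 0 <= x <= m:
        raise ValueError(f"dosage must be in 0..{m}, got {x}")
    return abs(abs(x - m // 2) - m // 2)


def feasible_dosage_classes(dP: int, dQ: int, m: int) -> frozenset[int]:
    """Offspring dosage classes with nonzero polysomic probability: a
    contiguous range of cardinality ``u(dP) + u(dQ) + 1``."""
    m = _check_ploidy(m)
    half = m // 2
    lo = max(0, dP - half) + max(0, dQ - half)
    hi = min(half, dP) + min(half, dQ)
    return frozenset(range(lo, hi + 1))
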