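"""Combinatorial machinery for bivalent meiosis state spaces.

A homology group of even ploidy ``m`` forms ``m/2`` bivalents during
meiosis I.  A gamete carries one homolog per bivalent, i.e. a size-``m/2``
subset of the homolog labels ``1..m``.  Offspring genotype states are
ordered pairs of parental gamete states.  This module enumerates and ranks
those objects and provides the recombinant-bivalent count that indexes
transition probabilities without materializing the full transition space.

All public interfaces use 1-based homolog labels and 1-based ranks; gamete
states are ordered lexicographically on their sorted label tuples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "InvalidPloidyError",
    "PloidyContext",
    "count_bivalent_configs",
    "enumerate_bivalent_configs",
    "gamete_subsets",
    "gamete_rank",
    "gamete_unrank",
    "recombinant_count",
    "genotype_index",
    "genotype_decompose",
    "genotype_pair_counts",
    "recomb_count_matrix",
]


class InvalidPloidyError(ValueError):
    """Raised when a ploidy is not an even integer >= 2."""


def _check_ploidy(m: int) -> int:
    if not isinstance(m, (int, np.integer)):
        raise InvalidPloidyError(f"ploidy must be an integer, got {m!r}")
    m = int(m)
    if m < 2 or m % 2:
        raise InvalidPloidyError(f"ploidy must be an even integer >= 2, got {m}")
    return m


@dataclass(frozen=True)
class PloidyContext:
    """Derived state-space sizes for an even ploidy level.

    Attributes
    ----------
    m : int
        Ploidy (number of homologs per homology group), even, >= 2.
    """

    m: int

    def __post_init__(self) -> None:
        _check_ploidy(self.m)

    @property
    def n_gametes(self) -> int:
        """Number of gamete states, C(m, m/2)."""
        return math.comb(self.m, self.m // 2)

    @property
    def g(self) -> int:
        """Number of genotype states, C(m, m/2)**2."""
        return self.n_gametes**2

    @property
    def w(self) -> int:
        """Number of bivalent pairing configurations."""
        return count_bivalent_configs(self.m)


def count_bivalent_configs(m: int) -> int:
    """Number of distinct bivalent configurations (perfect matchings) of
    ``m`` homologs: ``(1/(m/2)!) * prod_{i=1}^{m/2} C(2i, 2)``.
    """
    m = _check_ploidy(m)
    half = m // 2
    prod = math.prod(math.comb(2 * i, 2) for i in range(1, half + 1))
    return prod // math.factorial(half)


def enumerate_bivalent_configs(m: int, cap: int = 8):
    """All perfect matchings of homologs ``1..m`` in a deterministic order.

    Each configuration is a ``frozenset`` of ``frozenset`` pairs.  The
    enumeration always pairs the smallest unpaired label first, giving a
    canonical order.  Refuses ploidies above ``cap`` (the count grows as
    the double factorial; enumeration is only needed for oracle tests and
    the simulator).
    """
    m = _check_ploidy(m)
    if m > cap:
        raise ValueError(
            f"refusing to enumerate bivalent configurations for m={m} > cap={cap}; "
            "raise `cap` explicitly if you really need this"
        )

    def _rec(remaining: tuple[int, ...]):
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for idx, partner in enumerate(rest):
            pair = frozenset((first, partner))
            sub = rest[:idx] + rest[idx + 1 :]
            for tail in _rec(sub):
                yield (pair,) + tail

    return [frozenset(cfg) for cfg in _rec(tuple(range(1, m + 1)))]


@lru_cache(maxsize=None)
def gamete_subsets(m: int) -> tuple[tuple[int, ...], ...]:
    """All size-``m/2`` subsets of ``1..m`` in lexicographic order."""
    m = _check_ploidy(m)
    return tuple(itertools.combinations(range(1, m + 1), m // 2))


@lru_cache(maxsize=None)
def _rank_lookup(m: int) -> dict[tuple[int, ...], int]:
    return {s: i + 1 for i, s in enumerate(gamete_subsets(m))}


def _as_subset(S, m: int) -> tuple[int, ...]:
    tup = tuple(sorted(int(x) for x in S))
    if len(tup) != m // 2 or len(set(tup)) != len(tup):
        raise ValueError(f"expected a set of {m // 2} distinct homolog labels, got {S!r}")
    if tup[0] < 1 or tup[-1] > m:
        raise ValueError(f"homolog labels must be in 1..{m}, got {S!r}")
    return tup


def gamete_rank(S, m: int) -> int:
    """1-based lexicographic rank of a gamete subset."""
    return _rank_lookup(m)[_as_subset(S, m)]


def gamete_unrank(rank: int, m: int) -> frozenset[int]:
    """Inverse of :func:`gamete_rank`."""
    subsets = gamete_subsets(m)
    if not 1 <= rank <= len(subsets):
        raise ValueError(f"rank must be in 1..{len(subsets)}, got {rank}")
    return frozenset(subsets[rank - 1])


def recombinant_count(S_k, S_k1, m: int) -> int:
    """Recombinant-bivalent count ``l = m/2 - |S_k & S_k1|`` between the
    homolog subsets carried by one gamete at two adjacent loci."""
    a = _as_subset(S_k, m)
    b = _as_subset(S_k1, m)
    return m // 2 - len(set(a) & set(b))


def genotype_index(i: int, h: int, m: int) -> int:
    """Genotype state index ``j = (i-1)*C(m, m/2) + h`` from the two
    parental gamete ranks (P-gamete ``i``, Q-gamete ``h``)."""
    n = math.comb(m, m // 2)
    if not (1 <= i <= n and 1 <= h <= n):
        raise ValueError(f"gamete ranks must be in 1..{n}, got ({i}, {h})")
    return (i - 1) * n + h


def genotype_decompose(j: int, m: int) -> tuple[int, int]:
    """Inverse of :func:`genotype_index`: returns ``(i, h)``."""
    n = math.comb(m, m // 2)
    if not 1 <= j <= n * n:
        raise ValueError(f"genotype index must be in 1..{n * n}, got {j}")
    i, h = divmod(j - 1, n)
    return i + 1, h + 1


def genotype_pair_counts(j: int, j1: int, m: int) -> tuple[int, int]:
    """Recombinant-bivalent counts ``(lP, lQ)`` for a transition between
    genotype states ``j`` and ``j1``, computed from the parental gamete
    ranks without materializing the full transition space."""
    i, h = genotype_decompose(j, m)
    i1, h1 = genotype_decompose(j1, m)
    L = recomb_count_matrix(m)
    return int(L[i - 1, i1 - 1]), int(L[h - 1, h1 - 1])


@lru_cache(maxsize=None)
def recomb_count_matrix(m: int) -> np.ndarray:
    """Matrix of recombinant-bivalent counts over all ordered pairs of
    gamete ranks; read-only, shape ``(C(m,m/2), C(m,m/2))``."""
    subsets = [frozenset(s) for s in gamete_subsets(m)]
    n = len(subsets)
    half = m // 2
    L = np.empty((n, n), dtype=np.int64)
    for a, sa in enumerate(subsets):
        for b, sb in enumerate(subsets):
            L[a, b] = half - len(sa & sb)
    L.setflags(write=False)
    return L
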