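"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from polylink import model, states
from polylink.model import MarkerPhase


def brute_matchings(items):
    """Independent perfect-matching enumerator (pair-the-first recursion is
    NOT reused here; this one filters all set partitions of pairs from
    permutations)."""
    items = tuple(items)
    if not items:
        return [frozenset()]
    out = set()
    for perm in itertools.permutations(items):
        pairs = frozenset(
            frozenset(perm[i : i + 2]) for i in range(0, len(perm), 2)
        )
        out.add(pairs)
    return sorted(out, key=lambda cfg: sorted(sorted(p) for p in cfg))


def brute_collapsed(phiPk, phiPk1, phiQk, phiQk1, r, m):
    """Aggregate the full g_m x g_m genotypic transition space into the
    joint dosage table (uniform initial states)."""
    nG = math.comb(m, m // 2)
    g = nG * nG
    A = np.zeros((m + 1, m + 1))
    for j in range(1, g + 1):
        i, h = states.genotype_decompose(j, m)
        dk = len(phiPk & states.gamete_unrank(i, m)) + len(phiQk & states.gamete_unrank(h, m))
        for j1 in range(1, g + 1):
            i1, h1 = states.genotype_decompose(j1, m)
            dk1 = len(phiPk1 & states.gamete_unrank(i1, m)) + len(
                phiQk1 & states.gamete_unrank(h1, m)
            )
            A[dk, dk1] += model.genotypic_transition(j, j1, r, m) / g
    return A


def brute_chain_loglik(chain):
    """Path-enumeration chain likelihood (small m and z only)."""
    g = math.comb(chain.m, chain.m // 2) ** 2
    total = 0.0
    for i in range(chain.n):
        acc = 0.0
        for path in itertools.product(range(1, g + 1), repeat=chain.z):
            p = 1.0 / g
            for k in range(chain.z):
                d = model.delta_dosage(path[k], chain.phases[k], chain.m)
                p *= chain.priors[i, k, d]
                if k < chain.z - 1:
                    p *= model.genotypic_transition(path[k], path[k + 1], chain.r[k], chain.m)
            acc += p
        total += np.log(acc)
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tetra_phase():
    return MarkerPhase(frozenset({1, 2}), frozenset({1}))
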