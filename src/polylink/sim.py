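"""Synthetic full-sib populations under bivalent meiosis.

Parental haplotypes are binary homolog x marker matrices; each offspring
is the union of one gamete per parent.  Meiosis samples a bivalent pairing
(uniform over all perfect matchings, optionally biased toward a fixed
partner matching), transmits one homolog per bivalent, and switches to the
partner across interval k with probability r_k, independently per bivalent
(no interference, no obligate chiasma — exactly the process the mapping
model assumes).  Includes the Haldane mapping function and map-comparison
metrics, plus a replicated phasing study driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phasing import PhasingConfig, compare_phase, homolog_matrix, phase_chain
from .states import _check_ploidy, enumerate_bivalent_configs

__all__ = ["SimConfig", "TruthRecord", "SimResult", "make_parent_haplotypes",
           "sample_bivalent_config", "simulate_meiosis", "simulate_population",
           "haldane", "haldane_inverse", "map_rms_distance", "indicator_priors",
           "run_simulation_study"]

SCENARIOS = ("A", "B", "C")


@dataclass
class SimConfig:
    """Design of one simulated full-sib population."""

    m: int
    n: int
    z: int
    distances_cm: np.ndarray = None  # type: ignore[assignment]  # z-1 interval lengths
    scenario: str = "A"
    preferential: float = 0.0
    error_rate: float = 0.0
    seed: int | None = None
    dosage_range: tuple[int, int] | None = None  # inclusive; default (1, m-1)

    def __post_init__(self):
        _check_ploidy(self.m)
        if self.n < 1 or self.z < 2:
            raise ValueError("need n >= 1 offspring and z >= 2 markers")
        if self.distances_cm is None:
            self.distances_cm = np.ones(self.z - 1)
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        if self.distances_cm.shape != (self.z - 1,) or np.any(self.distances_cm <= 0):
            raise ValueError("distances_cm must be z-1 positive interval lengths")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not 0.0 <= self.preferential <= 1.0:
            raise ValueError("preferential pairing weight must be in [0, 1]")
        if self.dosage_range is None:
            self.dosage_range = (1, self.m - 1)

    @property
    def r(self) -> np.ndarray:
        return haldane_inverse(self.distances_cm)


@dataclass
class TruthRecord:
    """Ground truth for evaluation: parental homolog matrices, the homolog
    tracks transmitted to each offspring, and the noise-free dosages."""

    HP: np.ndarray  # (m, z)
    HQ: np.ndarray  # (m, z)
    tracks_P: np.ndarray  # (n, m/2, z) homolog labels 1..m
    tracks_Q: np.ndarray
    dosages: np.ndarray  # (z, n)


@dataclass
class SimResult:
    config: SimConfig
    dP: np.ndarray
    dQ: np.ndarray
    dosages: np.ndarray  # (z, n) observed (possibly corrupted)
    truth: TruthRecord


def make_parent_haplotypes(m: int, z: int, dosages, scenario: str, rng) -> np.ndarray:
    """Binary (m, z) homolog matrix with the requested per-marker column
    sums, placed by scenario:

    - ``A``: alleles on homologs 1..d (concentrated);
    - ``B``: a contiguous block starting at a random row within the first
      m/2 homologs;
    - ``C``: a uniformly random subset of homologs.
    """
    m = _check_ploidy(m)
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    dosages = np.asarray(dosages, dtype=int)
    if dosages.shape != (z,) or np.any(dosages < 0) or np.any(dosages > m):
        raise ValueError(f"need {z} dosages in 0..{m}")
    H = np.zeros((m, z), dtype=np.int8)
    for k, d in enumerate(dosages):
        if d == 0:
            continue
        if scenario == "A":
            rows = np.arange(d)
        elif scenario == "B":
            start = rng.integers(0, min(m // 2, m - d + 1))
            rows = np.arange(start, start + d)
        else:
            rows = rng.choice(m, size=d, replace=False)
        H[rows, k] = 1
    return H


FIXED_MATCHING_CHOICES = None  # computed lazily per ploidy


def sample_bivalent_config(m: int, preferential: float, rng) -> np.ndarray:
    """Sample a pairing as an (m/2, 2) array of homolog labels.  With
    probability ``preferential`` the fixed partner matching
    {(1,2),(3,4),...}; otherwise uniform over all perfect matchings."""
    if preferential > 0 and rng.random() < preferential:
        return np.arange(1, m + 1).reshape(-1, 2)
    perm = rng.permutation(m) + 1
    pairs = perm.reshape(-1, 2)
    return pairs


def simulate_meiosis(H: np.ndarray, r, preferential: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: returns ``(track, alleles)`` where ``track[b, k]`` is
    the homolog label transmitted by bivalent ``b`` at marker ``k`` and
    ``alleles[k]`` is the gamete's allele count at marker ``k``."""
    m, z = H.shape
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fractions must be in [0, 0.5]")
    half = m // 2
    pairs = sample_bivalent_config(m, preferential, rng)
    choice = rng.integers(0, 2, size=half)
    track = np.empty((half, z), dtype=np.int64)
    track[:, 0] = pairs[np.arange(half), choice]
    for k in range(z - 1):
        switch = rng.random(half) < r[k]
        choice = np.where(switch, 1 - choice, choice)
        track[:, k + 1] = pairs[np.arange(half), choice]
    alleles = H[track - 1, np.arange(z)[None, :]].sum(axis=0)
    return track, alleles


def simulate_population(config: SimConfig, parents: tuple[np.ndarray, np.ndarray] | None = None,
                        rng=None) -> SimResult:
    """Simulate a full-sib population; returns observed dosages plus the
    truth record.  Observed dosage equals the true dosage unless
    ``config.error_rate`` > 0, in which case each observation is replaced
    by a uniformly chosen *other* class with that probability."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m, n, z = config.m, config.n, config.z
    if parents is None:
        lo, hi = config.dosage_range
        dP = rng.integers(lo, hi + 1, size=z)
        dQ = rng.integers(lo, hi + 1, size=z)
        HP = make_parent_haplotypes(m, z, dP, config.scenario, rng)
        HQ = make_parent_haplotypes(m, z, dQ, config.scenario, rng)
    else:
        HP, HQ = parents
    dP = HP.sum(axis=0).astype(int)
    dQ = HQ.sum(axis=0).astype(int)
    r = config.r
    half = m // 2
    tracks_P = np.empty((n, half, z), dtype=np.int64)
    tracks_Q = np.empty((n, half, z), dtype=np.int64)
    dosages = np.empty((z, n), dtype=float)
    for i in range(n):
        tP, aP = simulate_meiosis(HP, r, config.preferential, rng)
        tQ, aQ = simulate_meiosis(HQ, r, config.preferential, rng)
        tracks_P[i], tracks_Q[i] = tP, tQ
        dosages[:, i] = aP + aQ
    truth = TruthRecord(HP=HP, HQ=HQ, tracks_P=tracks_P, tracks_Q=tracks_Q,
                        dosages=dosages.copy())
    observed = dosages
    if config.error_rate > 0:
        flip = rng.random((z, n)) < config.error_rate
        shift = rng.integers(1, m + 1, size=(z, n))
        observed = np.where(flip, (dosages + shift) % (m + 1), dosages)
    return SimResult(config=config, dP=dP, dQ=dQ, dosages=observed, truth=truth)


def haldane(r) -> np.ndarray | float:
    """Haldane map distance in cM: ``d = -50 ln(1 - 2r)``; r = 0.5 is
    infinitely distant."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("Haldane distance requires 0 <= r < 0.5")
    d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inverse(d_cm) -> np.ndarray | float:
    """Inverse Haldane: ``r = (1 - exp(-d/50)) / 2``."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distances must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


def map_rms_distance(d_hat, d_true) -> float:
    """Root mean squared difference between two interval-length vectors
    (cM); 1 cM means the maps differ by 1 cM on average."""
    d_hat = np.asarray(d_hat, dtype=float)
    d_true = np.asarray(d_true, dtype=float)
    if d_hat.shape != d_true.shape:
        raise ValueError(f"length mismatch: {d_hat.shape} vs {d_true.shape}")
    return float(np.sqrt(np.mean((d_hat - d_true) ** 2)))


def indicator_priors(dosages: np.ndarray, dP, dQ, m: int,
                     error_rate: float = 0.0) -> np.ndarray:
    """Per-individual dosage priors from hard calls: mass ``1-eps`` on the
    observed class (``eps/m`` elsewhere); missing values (NaN) get the
    polysomic prior for the marker's parental dosages.  Shape (n, z, m+1)."""
    from .model import error_rate_prior, polysomic_prior

    z, n = dosages.shape
    priors = np.empty((n, z, m + 1))
    for k in range(z):
        poly = polysomic_prior(int(dP[k]), int(dQ[k]), m)
        for i in range(n):
            o = dosages[k, i]
            if np.isnan(o):
                priors[i, k] = poly
            else:
                priors[i, k] = error_rate_prior(int(o), error_rate, m)
    return priors


def run_simulation_study(m: int, n_replicates: int, n: int = 200, z: int = 10,
                         spacing_cm: float = 1.0, scenario: str = "A",
                         eta: float = 3.0, multipoint_lod: float = 10.0,
                         window: int = 50, preferential: float = 0.0,
                         error_rate: float = 0.0, seed: int | None = None,
                         parents: tuple[np.ndarray, np.ndarray] | None = None,
                         config_kwargs: dict | None = None):
    """Replicated phasing study: simulate, phase, evaluate.

    Returns a pandas DataFrame with one row per replicate: whether each
    parent's phase was recovered (up to homolog permutation) and, when both
    were, the RMS distance between the estimated and true maps (cM).
    """
    import pandas as pd

    root = np.random.SeedSequence(seed)
    streams = root.spawn(max(n_replicates, 1))
    pconfig = PhasingConfig(eta=eta, multipoint_lod=multipoint_lod, window=window,
                            **(config_kwargs or {}))
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(streams[rep])
        cfg = SimConfig(m=m, n=n, z=z, distances_cm=np.full(z - 1, spacing_cm),
                        scenario=scenario, preferential=preferential,
                        error_rate=error_rate)
        sim = simulate_population(cfg, parents=parents, rng=rng)
        priors = indicator_priors(sim.dosages, sim.dP, sim.dQ, m,
                                  error_rate=error_rate)
        res = phase_chain(sim.dP, sim.dQ, priors, m, config=pconfig)
        if res.skipped or len(res.included) != z:
            okP = okQ = False
            rms = np.nan
        else:
            HP_est = homolog_matrix(res.best.phiP, m)
            HQ_est = homolog_matrix(res.best.phiQ, m)
            okP = compare_phase(HP_est, sim.truth.HP)
            okQ = compare_phase(HQ_est, sim.truth.HQ)
            rms = (map_rms_distance(haldane(np.minimum(res.r, 0.49999)), cfg.distances_cm)
                   if okP and okQ else np.nan)
        rows.append({"replicate": rep, "correct_P": okP, "correct_Q": okQ,
                     "rms_cm": rms, "n_skipped": len(res.skipped),
                     "loglik": res.loglik})
    cols = ["replicate", "correct_P", "correct_Q", "rms_cm", "n_skipped", "loglik"]
    return pd.DataFrame(rows, columns=cols)
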