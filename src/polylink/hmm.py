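"""Multipoint hidden Markov engine over the genotype state space.

For an ordered, phased marker chain the genotype state at marker k is the
pair of parental gamete states; the transition kernel factorizes into the
two parental gametic transition matrices.  All recursions therefore run on
``(n, n_gametes, n_gametes)`` tensors (individual, P-gamete, Q-gamete)
instead of the flattened ``g_m = n_gametes**2`` space, and per-interval
transition matrices are never materialized beyond the gamete space.

Numerical underflow is handled with standard per-marker scaling constants;
public outputs are log-domain or normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import warnings

import numpy as np

from .model import (
    R_MIN,
    MarkerPhase,
    delta_matrix,
    gametic_transition_matrix,
    polysomic_prior,
)
from .states import _check_ploidy, recomb_count_matrix

__all__ = ["ChainModel", "ForwardBackward", "FitResult", "forward", "backward",
           "forward_backward", "state_pair_posterior", "em_update", "fit",
           "genotype_posterior"]


@dataclass
class ChainModel:
    """An ordered, phased marker chain with per-individual dosage priors.

    Parameters
    ----------
    m : int
        Ploidy.
    phases : sequence of MarkerPhase, length z
    r : array, length z-1
        Recombination fractions per interval, clamped to [R_MIN, 0.5].
    priors : array, shape (n, z, m+1)
        Per-individual, per-marker dosage priors.  All-zero columns are
        replaced by the polysomic prior (with a warning).
    dP, dQ : arrays of length z, optional
        Parental dosages; inferred from the phases when omitted.
    """

    m: int
    phases: list[MarkerPhase]
    r: np.ndarray
    priors: np.ndarray
    dP: np.ndarray = field(default=None)  # type: ignore[assignment]
    dQ: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.m = _check_ploidy(self.m)
        z = len(self.phases)
        if z < 2:
            raise ValueError("a chain needs at least 2 markers")
        self.r = np.clip(np.asarray(self.r, dtype=float), R_MIN, 0.5)
        if self.r.shape != (z - 1,):
            raise ValueError(f"r must have length z-1={z - 1}, got {self.r.shape}")
        self.priors = np.asarray(self.priors, dtype=float)
        if self.priors.ndim != 3 or self.priors.shape[1:] != (z, self.m + 1):
            raise ValueError(
                f"priors must have shape (n, {z}, {self.m + 1}), got {self.priors.shape}"
            )
        if self.dP is None:
            self.dP = np.array([len(ph.phiP) for ph in self.phases])
        if self.dQ is None:
            self.dQ = np.array([len(ph.phiQ) for ph in self.phases])
        zero = np.where(self.priors.sum(axis=2) <= 0)
        if zero[0].size:
            warnings.warn(
                f"{zero[0].size} all-zero prior column(s) replaced by the polysomic prior",
                stacklevel=2,
            )
            for i, k in zip(*zero):
                self.priors[i, k] = polysomic_prior(int(self.dP[k]), int(self.dQ[k]), self.m)
        self._deltas = [delta_matrix(ph, self.m) for ph in self.phases]

    @property
    def z(self) -> int:
        return len(self.phases)

    @property
    def n(self) -> int:
        return self.priors.shape[0]

    def emissions(self) -> np.ndarray:
        """Per-individual emission tensors, shape (n, z, nG, nG)."""
        n, z = self.n, self.z
        nG = math.comb(self.m, self.m // 2)
        B = np.empty((n, z, nG, nG))
        rows = np.arange(n)[:, None, None]
        for k in range(z):
            B[:, k] = self.priors[:, k, :][rows, self._deltas[k][None, :, :]]
        return B


@dataclass
class ForwardBackward:
    """Scaled forward/backward quantities.

    ``alpha`` and ``beta`` are scaled so that ``sum_j alpha_k(j) beta_k(j)
    == 1`` at every marker; ``log_scale[i, k]`` are the per-marker log
    scaling constants; ``loglik`` is the total chain log-likelihood.
    """

    alpha: np.ndarray  # (n, z, nG, nG)
    beta: np.ndarray | None
    log_scale: np.ndarray  # (n, z)
    loglik: float
    B: np.ndarray  # (n, z, nG, nG) emissions


def _step(x: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Apply the factored transition kernel T (x) T to (n, nG, nG) tensors."""
    t = np.tensordot(x, T, axes=([1], [0]))  # (n, h, i') — sums the P axis
    return np.tensordot(t, T, axes=([1], [0]))  # (n, i', h')


def forward(chain: ChainModel) -> ForwardBackward:
    """Scaled forward recursion; fills ``alpha`` and the log-likelihood."""
    m, n, z = chain.m, chain.n, chain.z
    nG = math.comb(m, m // 2)
    B = chain.emissions()
    alpha = np.empty((n, z, nG, nG))
    log_scale = np.empty((n, z))
    g = nG * nG
    a = B[:, 0] / g
    _rescale(a, alpha, log_scale, chain, 0)
    for k in range(z - 1):
        T = gametic_transition_matrix(chain.r[k], m)
        a = _step(alpha[:, k], T) * B[:, k + 1]
        _rescale(a, alpha, log_scale, chain, k + 1)
    loglik = float(log_scale.sum())
    return ForwardBackward(alpha=alpha, beta=None, log_scale=log_scale, loglik=loglik, B=B)


def _rescale(a, alpha, log_scale, chain, k):
    c = a.sum(axis=(1, 2))
    dead = np.where(c <= 0)[0]
    if dead.size:
        raise ValueError(
            f"zero chain probability for individual {int(dead[0])} at marker {k}: "
            "observations contradict the phase (check error rate / priors)"
        )
    alpha[:, k] = a / c[:, None, None]
    log_scale[:, k] = np.log(c)


def backward(chain: ChainModel, fb: ForwardBackward) -> ForwardBackward:
    """Scaled backward recursion sharing the forward scaling constants."""
    m, n, z = chain.m, chain.n, chain.z
    nG = fb.alpha.shape[2]
    beta = np.empty_like(fb.alpha)
    beta[:, z - 1] = 1.0
    for k in range(z - 2, -1, -1):
        T = gametic_transition_matrix(chain.r[k], m)
        b = _step(fb.B[:, k + 1] * beta[:, k + 1], T)
        beta[:, k] = b / np.exp(fb.log_scale[:, k + 1])[:, None, None]
    fb.beta = beta
    return fb


def forward_backward(chain: ChainModel) -> ForwardBackward:
    return backward(chain, forward(chain))


def state_pair_posterior(chain: ChainModel, fb: ForwardBackward, k: int) -> np.ndarray:
    """Posterior over genotype-state pairs across interval ``k`` (0-based),
    shape ``(n, g, g)`` with ``j = (i-1)*nG + h`` flattening.  Normalized
    per individual.  Materializes the pair space — intended for small m.
    """
    if fb.beta is None:
        raise ValueError("run backward() first")
    m = chain.m
    nG = fb.alpha.shape[2]
    g = nG * nG
    T = gametic_transition_matrix(chain.r[k], m)
    Tfull = np.kron(T, T)
    a = fb.alpha[:, k].reshape(-1, g)
    mseg = (fb.B[:, k + 1] * fb.beta[:, k + 1]).reshape(-1, g)
    xi = a[:, :, None] * Tfull[None, :, :] * mseg[:, None, :]
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    return xi


def _quad(a, T1, T2, M):
    """sum_{i,h,i',h'} a(i,h) T1(i,i') T2(h,h') M(i',h') per individual."""
    t = np.tensordot(a, T1, axes=([1], [0]))  # (n, h, i')
    t = np.tensordot(t, T2, axes=([1], [0]))  # (n, i', h')
    return (t * M).sum(axis=(1, 2))


def em_update(chain: ChainModel, fb: ForwardBackward) -> np.ndarray:
    """One EM sweep for the recombination-fraction vector: each r_k is
    replaced by the posterior-expected proportion of recombinant bivalents
    across both parents, averaged over individuals."""
    if fb.beta is None:
        raise ValueError("run backward() first")
    m = chain.m
    Lmat = recomb_count_matrix(m).astype(float)
    r_new = np.empty_like(chain.r)
    for k in range(chain.z - 1):
        T = gametic_transition_matrix(chain.r[k], m)
        TL = T * Lmat
        M = fb.B[:, k + 1] * fb.beta[:, k + 1]
        a = fb.alpha[:, k]
        denom = _quad(a, T, T, M)
        EL = (_quad(a, TL, T, M) + _quad(a, T, TL, M)) / denom
        r_new[k] = np.clip(EL.mean() / m, R_MIN, 0.5)
    return r_new


@dataclass
class FitResult:
    r: np.ndarray
    loglik: float
    n_iter: int
    trace: list[float]


def fit(chain: ChainModel, tol: float = 1e-4, max_iter: int = 1000) -> FitResult:
    """Alternate forward-backward and the EM update until the largest
    change in any r_k drops below ``tol`` (or ``max_iter`` sweeps)."""
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fb = forward_backward(chain)
        if not np.isfinite(fb.loglik):
            raise ValueError(f"non-finite chain log-likelihood at sweep {n_iter}")
        trace.append(fb.loglik)
        r_new = em_update(chain, fb)
        delta = np.max(np.abs(r_new - chain.r))
        chain.r = r_new
        if delta < tol:
            break
    fb = forward(chain)
    trace.append(fb.loglik)
    return FitResult(r=chain.r.copy(), loglik=fb.loglik, n_iter=n_iter, trace=trace)


def genotype_posterior(chain: ChainModel, fb: ForwardBackward) -> np.ndarray:
    """Per-individual, per-marker posterior over genotype states,
    shape ``(n, z, nG, nG)``; sums to 1 over the state axes."""
    if fb.beta is None:
        raise ValueError("run backward() first")
    post = fb.alpha * fb.beta
    post /= post.sum(axis=(2, 3), keepdims=True)
    return post
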