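"""Sequential linkage-phase search.

Markers are inserted one at a time into a growing chain.  For each new
marker, two-point LOD scores against a window of already-phased markers
restrict which homolog assignments are worth considering; assignments that
are row permutations of one another (per parent) are collapsed to a single
canonical representative; the survivors are scored with the multipoint HMM
likelihood and pruned by a LOD threshold.  After the last insertion the
best configuration is kept and its recombination fractions refit by full
EM.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import hmm
from .model import MarkerPhase
from .states import _check_ploidy
from .twopoint import retained_sharing_values, scan_phases

__all__ = ["PhasingConfig", "PhaseCandidate", "PhasingResult", "canonical_form",
           "candidate_key", "extend_candidates", "score_and_prune", "phase_chain",
           "compare_phase", "homolog_matrix"]

log = logging.getLogger(__name__)

NEW_INTERVAL_R = 0.01  # map-scale starting value for a freshly added interval


@dataclass(frozen=True)
class PhasingConfig:
    """Thresholds for the sequential search.

    eta : two-point LOD threshold for retaining a sharing partition
    multipoint_lod : LOD pruning threshold between insertion rounds
    window : number of terminal phased markers used for two-point checks
    refresh_sweeps : EM sweeps applied to each candidate at insertion time
    max_candidates : hard cap on the candidate list (safety valve)
    """

    eta: float = 5.0
    multipoint_lod: float = 10.0
    window: int = 50
    refresh_sweeps: int = 5
    max_candidates: int = 200

    def __post_init__(self):
        if self.eta <= 0 or self.multipoint_lod <= 0 or self.window < 1:
            raise ValueError("eta and multipoint_lod must be > 0 and window >= 1")


@dataclass
class PhaseCandidate:
    """One linkage-phase configuration for the markers inserted so far."""

    phiP: tuple[frozenset, ...]
    phiQ: tuple[frozenset, ...]
    r: np.ndarray
    loglik: float = -np.inf
    lod: float = np.nan


@dataclass
class PhasingResult:
    best: PhaseCandidate
    candidates: list[PhaseCandidate]
    included: list[int]
    skipped: list[int]
    loglik: float
    r: np.ndarray
    n_iter: int = 0


def homolog_matrix(phis, m: int) -> np.ndarray:
    """Binary homolog x marker matrix from a sequence of phase subsets."""
    H = np.zeros((m, len(phis)), dtype=np.int8)
    for k, phi in enumerate(phis):
        for i in phi:
            H[i - 1, k] = 1
    return H


def canonical_form(H: np.ndarray) -> np.ndarray:
    """Row-permutation canonical form: rows sorted as binary words,
    descending.  Two matrices are permutation-equivalent iff their
    canonical forms are equal."""
    H = np.asarray(H)
    if H.ndim != 2 or not np.isin(H, (0, 1)).all():
        raise ValueError("expected a binary homolog matrix")
    rows = sorted((tuple(int(x) for x in row) for row in H), reverse=True)
    return np.array(rows, dtype=H.dtype)


def candidate_key(phiP, phiQ, m: int) -> tuple:
    """Hashable redundancy-elimination key: the pair of per-parent
    canonical forms (parents permute independently)."""
    kP = tuple(map(tuple, canonical_form(homolog_matrix(phiP, m))))
    kQ = tuple(map(tuple, canonical_form(homolog_matrix(phiQ, m))))
    return kP, kQ


def _allowed_subsets(phis, d_new: int, allowed_w: dict[int, set[int]], m: int):
    """Subsets of size d_new whose sharing value against each constrained
    chain position lies in the allowed set for that position."""
    out = []
    for comb in itertools.combinations(range(1, m + 1), d_new):
        phi = frozenset(comb)
        if all(len(phi & phis[pos]) in ws for pos, ws in allowed_w.items()):
            out.append(phi)
    return out


def extend_candidates(candidates: list[PhaseCandidate], allowedP: dict[int, set[int]],
                      allowedQ: dict[int, set[int]], d_new: tuple[int, int],
                      m: int) -> list[PhaseCandidate]:
    """Append every two-point-compatible assignment of the new marker to
    each candidate; remove permutation-redundant expansions.

    ``allowedP[pos]`` is the set of sharing values retained (LOD < eta)
    between the new marker and the candidate subset at chain position
    ``pos``; likewise for Q.  The two parents expand independently and are
    crossed.
    """
    m = _check_ploidy(m)
    dP_new, dQ_new = d_new
    seen: set[tuple] = set()
    out: list[PhaseCandidate] = []
    for cand in candidates:
        for phiP_new in _allowed_subsets(cand.phiP, dP_new, allowedP, m):
            for phiQ_new in _allowed_subsets(cand.phiQ, dQ_new, allowedQ, m):
                phiP = cand.phiP + (phiP_new,)
                phiQ = cand.phiQ + (phiQ_new,)
                key = candidate_key(phiP, phiQ, m)
                if key in seen:
                    continue
                seen.add(key)
                out.append(PhaseCandidate(
                    phiP=phiP, phiQ=phiQ,
                    r=np.append(cand.r, NEW_INTERVAL_R),
                    loglik=cand.loglik,
                ))
    return out


def _score(cand: PhaseCandidate, priors: np.ndarray, m: int,
           sweeps: int, tol: float = 1e-4) -> PhaseCandidate:
    phases = [MarkerPhase(p, q) for p, q in zip(cand.phiP, cand.phiQ)]
    chain = hmm.ChainModel(m=m, phases=phases, r=cand.r.copy(), priors=priors)
    res = hmm.fit(chain, tol=tol, max_iter=sweeps)
    cand.r = res.r
    cand.loglik = res.loglik
    return cand


PRESCREEN_THRESHOLD = 8
PRESCREEN_MARGIN = 5.0  # extra LOD slack for the refresh-free first pass


def _forward_loglik(cand: PhaseCandidate, priors: np.ndarray, m: int) -> float:
    phases = [MarkerPhase(p, q) for p, q in zip(cand.phiP, cand.phiQ)]
    chain = hmm.ChainModel(m=m, phases=phases, r=cand.r.copy(), priors=priors)
    return hmm.forward(chain).loglik


def score_and_prune(candidates: list[PhaseCandidate], priors: np.ndarray,
                    m: int, config: PhasingConfig, sweeps: int | None = None) -> list[PhaseCandidate]:
    """Refresh each candidate's multipoint likelihood (a few EM sweeps on
    its r vector) and keep those within ``multipoint_lod`` of the best.

    Large expansions are first screened with a refresh-free forward pass
    (all candidates share the same r history, so the ranking is already
    meaningful); only candidates within ``multipoint_lod`` plus a safety
    margin of the screened best receive the EM refresh.
    """
    if not candidates:
        raise ValueError("no candidates to score")
    sweeps = config.refresh_sweeps if sweeps is None else sweeps
    if len(candidates) > PRESCREEN_THRESHOLD and np.isfinite(config.multipoint_lod):
        lls = [_forward_loglik(c, priors, m) for c in candidates]
        best0 = max(lls)
        cutoff = (config.multipoint_lod + PRESCREEN_MARGIN) * math.log(10)
        candidates = [c for c, ll in zip(candidates, lls) if best0 - ll < cutoff]
    for cand in candidates:
        _score(cand, priors, m, sweeps)
    best = max(c.loglik for c in candidates)
    for c in candidates:
        c.lod = (best - c.loglik) / math.log(10)
    kept = [c for c in candidates if c.lod < config.multipoint_lod]
    kept.sort(key=lambda c: c.lod)
    if len(kept) > config.max_candidates:
        log.warning("candidate explosion: keeping top %d of %d", config.max_candidates, len(kept))
        kept = kept[: config.max_candidates]
    return kept


def phase_chain(dP, dQ, priors, m: int, config: PhasingConfig | None = None,
                marker_order=None) -> PhasingResult:
    """Sequential phasing of an ordered marker chain.

    Parameters
    ----------
    dP, dQ : arrays of length z — parental dosages per marker
    priors : array (n, z, m+1) — per-individual dosage priors
    marker_order : optional sequence of marker indices (default 0..z-1)

    Returns the best candidate with fully refit recombination fractions.
    Markers for which no assignment survives the two-point restriction are
    skipped and reported.
    """
    m = _check_ploidy(m)
    config = config or PhasingConfig()
    priors = np.asarray(priors, dtype=float)
    z = priors.shape[1]
    order = list(marker_order) if marker_order is not None else list(range(z))
    if len(order) < 2:
        raise ValueError("need at least 2 markers to phase")

    first = order[0]
    cand0 = PhaseCandidate(
        phiP=(frozenset(range(1, int(dP[first]) + 1)),),
        phiQ=(frozenset(range(1, int(dQ[first]) + 1)),),
        r=np.empty(0),
    )
    candidates = [cand0]
    included = [first]
    skipped: list[int] = []

    for new in order[1:]:
        window_pos = range(max(0, len(included) - config.window), len(included))
        allowedP: dict[int, set[int]] = {}
        allowedQ: dict[int, set[int]] = {}
        feasible = True
        for pos in window_pos:
            prev = included[pos]
            results = scan_phases(
                priors[:, prev, :], priors[:, new, :],
                (int(dP[prev]), int(dP[new])), (int(dQ[prev]), int(dQ[new])), m,
            )
            wsP, wsQ = retained_sharing_values(results, config.eta)
            if not wsP or not wsQ:
                feasible = False
                break
            allowedP[pos] = wsP
            allowedQ[pos] = wsQ
        expanded = (
            extend_candidates(candidates, allowedP, allowedQ,
                              (int(dP[new]), int(dQ[new])), m)
            if feasible else []
        )
        if not expanded:
            log.warning("marker %s: no linkage phase assignment survives eta=%s; skipped",
                        new, config.eta)
            skipped.append(new)
            continue
        trial = included + [new]
        candidates = score_and_prune(expanded, priors[:, trial, :], m, config)
        included = trial
        log.info("inserted marker %s: %d candidate(s) retained", new, len(candidates))

    # final choice by the multipoint likelihood of the whole chain, then a
    # full EM refit of the winner's recombination fractions
    best = max(candidates, key=lambda c: c.loglik)
    phases = [MarkerPhase(p, q) for p, q in zip(best.phiP, best.phiQ)]
    chain = hmm.ChainModel(m=m, phases=phases, r=best.r.copy(),
                           priors=priors[:, included, :])
    res = hmm.fit(chain, tol=1e-5, max_iter=1000)
    best.r = res.r
    best.loglik = res.loglik
    lbest = max(c.loglik for c in candidates)
    for c in candidates:
        c.lod = (lbest - c.loglik) / math.log(10)
    return PhasingResult(best=best, candidates=candidates, included=included,
                         skipped=skipped, loglik=res.loglik, r=res.r,
                         n_iter=res.n_iter)


def compare_phase(H_est: np.ndarray, H_true: np.ndarray) -> bool:
    """True iff the two homolog matrices are equal up to row permutation."""
    H_est = np.asarray(H_est)
    H_true = np.asarray(H_true)
    if H_est.shape != H_true.shape:
        raise ValueError(f"shape mismatch: {H_est.shape} vs {H_true.shape}")
    return bool(np.array_equal(canonical_form(H_est), canonical_form(H_true)))
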