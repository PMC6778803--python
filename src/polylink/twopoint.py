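"""Two-marker engine: collapsed dosage-class model, recombination-fraction
estimation per linkage-phase partition, and LOD scores.

The ``g_m`` genotype states at two loci collapse into an ``(m+1) x (m+1)``
joint dosage table ``A(r)`` that depends on the linkage phase only through
the sharing pair ``(wP, wQ)`` — the number of homologs on which the counted
allele co-occurs at both loci, per parent.  ``A(r)`` is a polynomial in
``(1-r)^(m-L) r^L`` with coefficients indexed by the total recombinant
count ``L = lP + lQ``; the coefficient tensors are cached so that repeated
likelihood evaluation across a pairwise scan is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .model import R_MIN, dosage_profile, dosage_span
from .states import _check_ploidy, recomb_count_matrix

__all__ = [
    "TwoPointResult",
    "enumerate_sharing_values",
    "representative_phase",
    "collapsed_coeffs",
    "coeffs_from_subsets",
    "collapsed_joint",
    "twopoint_loglik",
    "twopoint_estimate",
    "scan_phases",
    "retained_sharing_values",
    "pairwise_rf_matrix",
    "fisher_information",
]


@dataclass(frozen=True)
class TwoPointResult:
    """Outcome of a two-point estimation for one sharing pair."""

    r_hat: float
    loglik: float
    wP: int
    wQ: int
    lod_linkage: float
    lod_phase: float = float("nan")
    uninformative: bool = False
    n_iter: int = 0


def enumerate_sharing_values(dk: int, dk1: int, m: int) -> tuple[int, ...]:
    """Possible sharing values ``w`` for one parent with dosages
    ``(dk, dk1)``: the contiguous range ``max(0, dk+dk1-m) .. min(dk, dk1)``,
    of cardinality ``min(u(dk), u(dk1)) + 1``."""
    m = _check_ploidy(m)
    for d in (dk, dk1):
        if not 0 <= d <= m:
            raise ValueError(f"dosage must be in 0..{m}, got {d}")
    lo = max(0, dk + dk1 - m)
    hi = min(dk, dk1)
    vals = tuple(range(lo, hi + 1))
    assert len(vals) == min(dosage_span(dk, m), dosage_span(dk1, m)) + 1
    return vals


def representative_phase(d: int, d1: int, w: int, m: int) -> tuple[frozenset, frozenset]:
    """A canonical pair of homolog subsets ``(phi_k, phi_k1)`` with sizes
    ``(d, d1)`` sharing exactly ``w`` homologs."""
    if w not in enumerate_sharing_values(d, d1, m):
        raise ValueError(f"sharing value {w} impossible for dosages ({d}, {d1}) at m={m}")
    phi_k = frozenset(range(1, d + 1))
    start = d - w  # first homolog (0-based) of the second subset
    phi_k1 = frozenset(range(start + 1, start + d1 + 1))
    assert len(phi_k & phi_k1) == w and max(phi_k1, default=1) <= m
    return phi_k, phi_k1


def _parent_tensor(phi_k: frozenset, phi_k1: frozenset, m: int) -> np.ndarray:
    """``F[l, a, a1]``: number of ordered gamete-rank pairs with ``l``
    recombinant bivalents contributing allele counts ``(a, a1)`` at the
    two loci, for one parent."""
    half = m // 2
    L = recomb_count_matrix(m)
    ak = dosage_profile(phi_k, m)
    ak1 = dosage_profile(phi_k1, m)
    F = np.zeros((half + 1, half + 1, half + 1), dtype=np.int64)
    np.add.at(F, (L, ak[:, None] + 0 * L, ak1[None, :] + 0 * L), 1)
    return F


def coeffs_from_subsets(phiPk, phiPk1, phiQk, phiQk1, m: int) -> np.ndarray:
    """Coefficient tensor ``C[L, a, b]`` such that the collapsed joint
    dosage table is ``A(r)[a, b] = sum_L C[L, a, b] (1-r)^(m-L) r^L``.

    Built from explicit phase subsets; any representatives of the same
    sharing pair yield the identical tensor.
    """
    m = _check_ploidy(m)
    half = m // 2
    g = math.comb(m, half) ** 2
    FP = _parent_tensor(frozenset(phiPk), frozenset(phiPk1), m)
    FQ = _parent_tensor(frozenset(phiQk), frozenset(phiQk1), m)
    C = np.zeros((m + 1, m + 1, m + 1), dtype=float)
    for lP in range(half + 1):
        cP = math.comb(half, lP)
        for lQ in range(half + 1):
            cQ = math.comb(half, lQ)
            # 2-D convolution over the per-parent dosage contributions
            block = np.zeros((m + 1, m + 1))
            for aP in range(half + 1):
                for aP1 in range(half + 1):
                    if FP[lP, aP, aP1]:
                        block[aP : aP + half + 1, aP1 : aP1 + half + 1] += (
                            FP[lP, aP, aP1] * FQ[lQ]
                        )
            C[lP + lQ] += block / (cP * cQ * g)
    return C


@lru_cache(maxsize=4096)
def collapsed_coeffs(m: int, dPk: int, dPk1: int, dQk: int, dQk1: int, wP: int, wQ: int) -> np.ndarray:
    """Cached coefficient tensor for a dosage/sharing configuration,
    using canonical representative subsets."""
    phiPk, phiPk1 = representative_phase(dPk, dPk1, wP, m)
    phiQk, phiQk1 = representative_phase(dQk, dQk1, wQ, m)
    C = coeffs_from_subsets(phiPk, phiPk1, phiQk, phiQk1, m)
    C.setflags(write=False)
    return C


def _poly_eval(C: np.ndarray, r: float, m: int) -> np.ndarray:
    L = np.arange(m + 1)
    xL = (1.0 - r) ** (m - L) * r**L
    return np.tensordot(xL, C, axes=1)


def collapsed_joint(dP_pair, dQ_pair, phase, r: float, m: int) -> np.ndarray:
    """Joint ``(m+1) x (m+1)`` offspring dosage table ``A(r)`` for parental
    dosage pairs ``dP_pair=(dPk, dPk1)``, ``dQ_pair=(dQk, dQk1)`` and a
    sharing pair ``phase=(wP, wQ)``."""
    wP, wQ = phase
    if wP not in enumerate_sharing_values(*dP_pair, m):
        raise ValueError(f"wP={wP} not feasible for parental dosages {dP_pair}")
    if wQ not in enumerate_sharing_values(*dQ_pair, m):
        raise ValueError(f"wQ={wQ} not feasible for parental dosages {dQ_pair}")
    C = collapsed_coeffs(m, dP_pair[0], dP_pair[1], dQ_pair[0], dQ_pair[1], wP, wQ)
    return _poly_eval(C, float(r), m)


def _check_priors(priors, m: int, label: str) -> np.ndarray:
    p = np.atleast_2d(np.asarray(priors, dtype=float))
    if p.shape[1] != m + 1:
        raise ValueError(f"{label}: priors must have {m + 1} columns, got {p.shape[1]}")
    bad = np.where(p.sum(axis=1) <= 0)[0]
    if bad.size:
        raise ValueError(f"{label}: individual {bad[0]} has an all-zero prior row")
    return p


def twopoint_loglik(priors_k, priors_k1, A: np.ndarray) -> float:
    """Log-likelihood ``sum_i log(pi_i^k A (pi_i^k')^T)``."""
    m = A.shape[0] - 1
    pk = _check_priors(priors_k, m, "marker k")
    pk1 = _check_priors(priors_k1, m, "marker k'")
    lik = np.einsum("na,ab,nb->n", pk, A, pk1)
    if np.any(lik <= 0):
        i = int(np.where(lik <= 0)[0][0])
        raise ValueError(f"zero two-point likelihood for individual {i}")
    return float(np.log(lik).sum())


def _em_r(pk, pk1, C, m, r0=0.25, tol=1e-6, max_iter=200):
    """EM on the collapsed table: the expected proportion of recombinant
    bivalents given each dosage cell updates r."""
    Lvec = np.arange(m + 1)
    r = r0
    for it in range(1, max_iter + 1):
        xL = (1.0 - r) ** (m - Lvec) * r**Lvec
        A = np.tensordot(xL, C, axes=1)
        AL = np.tensordot(xL * Lvec, C, axes=1)
        lik = np.einsum("na,ab,nb->n", pk, A, pk1)
        EL = np.einsum("na,ab,nb->n", pk, AL, pk1) / lik
        r_new = float(np.clip(EL.mean() / m, R_MIN, 0.5))
        if abs(r_new - r) < tol:
            return r_new, it
        r = r_new
    return r, max_iter


def _newton_r(pk, pk1, C, m):
    def nll(r):
        A = _poly_eval(C, r, m)
        lik = np.einsum("na,ab,nb->n", pk, A, pk1)
        if np.any(lik <= 0):
            return np.inf
        return -np.log(lik).sum()

    res = minimize_scalar(nll, bounds=(R_MIN, 0.5), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x), int(res.nfev)


def twopoint_estimate(priors_k, priors_k1, dP_pair, dQ_pair, phase, m: int,
                      method: str = "em", r0: float = 0.25,
                      tol: float = 1e-6, max_iter: int = 200) -> TwoPointResult:
    """Maximize the two-point likelihood over ``r`` for one sharing pair.

    ``lod_linkage`` compares the fitted model against the no-linkage null
    ``r = 0.5``.  Configurations whose likelihood does not depend on ``r``
    are flagged uninformative with ``r_hat = 0.5``.
    """
    m = _check_ploidy(m)
    pk = _check_priors(priors_k, m, "marker k")
    pk1 = _check_priors(priors_k1, m, "marker k'")
    wP, wQ = phase
    C = collapsed_coeffs(m, dP_pair[0], dP_pair[1], dQ_pair[0], dQ_pair[1], wP, wQ)

    ll_half = twopoint_loglik(pk, pk1, _poly_eval(C, 0.5, m))
    ll_quarter = twopoint_loglik(pk, pk1, _poly_eval(C, 0.25, m))
    if abs(ll_quarter - ll_half) < 1e-10:
        return TwoPointResult(r_hat=0.5, loglik=ll_half, wP=wP, wQ=wQ,
                              lod_linkage=0.0, uninformative=True)

    if method == "em":
        r_hat, n_iter = _em_r(pk, pk1, C, m, r0=r0, tol=tol, max_iter=max_iter)
    elif method == "newton":
        r_hat, n_iter = _newton_r(pk, pk1, C, m)
    else:
        raise ValueError(f"unknown method {method!r}")
    ll = twopoint_loglik(pk, pk1, _poly_eval(C, r_hat, m))
    lod_linkage = max(0.0, (ll - ll_half) / math.log(10))
    return TwoPointResult(r_hat=r_hat, loglik=ll, wP=wP, wQ=wQ,
                          lod_linkage=lod_linkage, n_iter=n_iter)


def scan_phases(priors_k, priors_k1, dP_pair, dQ_pair, m: int, **kwargs) -> list[TwoPointResult]:
    """Estimate ``r`` for every sharing pair ``(wP, wQ)``; results sorted
    by decreasing log-likelihood with ``lod_phase`` relative to the best.
    Ties are broken by the enumeration order of ``(wP, wQ)``, lowest first.
    """
    results = []
    for wP in enumerate_sharing_values(*dP_pair, m):
        for wQ in enumerate_sharing_values(*dQ_pair, m):
            results.append(
                twopoint_estimate(priors_k, priors_k1, dP_pair, dQ_pair, (wP, wQ), m, **kwargs)
            )
    best = max(res.loglik for res in results)
    results = [replace(res, lod_phase=(best - res.loglik) / math.log(10)) for res in results]
    results.sort(key=lambda res: (-res.loglik, res.wP, res.wQ))
    return results


def retained_sharing_values(results: list[TwoPointResult], eta: float) -> tuple[set[int], set[int]]:
    """Per-parent sharing values retained by the two-point LOD threshold.

    A value ``wP`` survives if its best partition over ``wQ`` has a phase
    LOD below ``eta`` (profile LOD), and symmetrically for ``wQ``.
    """
    lodP: dict[int, float] = {}
    lodQ: dict[int, float] = {}
    for res in results:
        lodP[res.wP] = min(lodP.get(res.wP, np.inf), res.lod_phase)
        lodQ[res.wQ] = min(lodQ.get(res.wQ, np.inf), res.lod_phase)
    return (
        {w for w, lod in lodP.items() if lod < eta},
        {w for w, lod in lodQ.items() if lod < eta},
    )


def pairwise_rf_matrix(priors, dP, dQ, m: int, **kwargs):
    """Best-phase two-point results for every unordered marker pair.

    Parameters
    ----------
    priors : array, shape (z, n, m+1)
        Per-marker, per-individual dosage priors.
    dP, dQ : arrays of length z
        Parental dosages.

    Returns
    -------
    table : pandas.DataFrame
        One row per pair: marker1, marker2, r_hat, lod_linkage, wP, wQ,
        lod_phase (of the runner-up partition, i.e. the margin).
    r_mat, lod_mat : (z, z) symmetric arrays (NaN diagonal).
    """
    import pandas as pd

    priors = np.asarray(priors, dtype=float)
    z = priors.shape[0]
    if z < 2:
        raise ValueError("need at least 2 markers")
    r_mat = np.full((z, z), np.nan)
    lod_mat = np.full((z, z), np.nan)
    rows = []
    for k in range(z):
        for k1 in range(k + 1, z):
            res = scan_phases(priors[k], priors[k1], (dP[k], dP[k1]), (dQ[k], dQ[k1]), m, **kwargs)
            best = res[0]
            margin = res[1].lod_phase if len(res) > 1 else np.inf
            rows.append({
                "marker1": k, "marker2": k1, "r_hat": best.r_hat,
                "lod_linkage": best.lod_linkage, "wP": best.wP, "wQ": best.wQ,
                "lod_phase_margin": margin,
            })
            r_mat[k, k1] = r_mat[k1, k] = best.r_hat
            lod_mat[k, k1] = lod_mat[k1, k] = best.lod_linkage
    return pd.DataFrame(rows), r_mat, lod_mat


def fisher_information(r: float, dP_pair, dQ_pair, phase, m: int) -> float:
    """Expected (per-observation) Fisher information of the two-point
    likelihood at ``r``, by exact enumeration over the dosage cells:
    ``I(r) = sum_cells A'(r)^2 / A(r)`` (the ``sum A''`` term vanishes
    because the table sums to 1 identically in ``r``)."""
    m = _check_ploidy(m)
    r = float(r)
    if not 0.0 < r < 0.5:
        raise ValueError(f"r must be in (0, 0.5), got {r}")
    wP, wQ = phase
    C = collapsed_coeffs(m, dP_pair[0], dP_pair[1], dQ_pair[0], dQ_pair[1], wP, wQ)
    L = np.arange(m + 1)
    xL = (1.0 - r) ** (m - L) * r**L
    dxL = np.zeros(m + 1)
    dxL[0] = -(m) * (1.0 - r) ** (m - 1)
    for l in range(1, m + 1):
        dxL[l] = (1.0 - r) ** (m - l - 1) * r ** (l - 1) * (l - m * r) if l < m else m * r ** (m - 1)
    A = np.tensordot(xL, C, axes=1)
    dA = np.tensordot(dxL, C, axes=1)
    mask = A > 1e-300
    return float((dA[mask] ** 2 / A[mask]).sum())
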