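import itertools
import math

import numpy as np
import pytest

from polylink import model, sim, twopoint
from polylink.model import polysomic_prior
from polylink.twopoint import (
    coeffs_from_subsets,
    collapsed_joint,
    enumerate_sharing_values,
    fisher_information,
    pairwise_rf_matrix,
    representative_phase,
    scan_phases,
    twopoint_estimate,
    twopoint_loglik,
)

from conftest import brute_collapsed


class TestSharingValues:
    def test_double_duplex_tetraploid(self):
        assert enumerate_sharing_values(2, 2, 4) == (0, 1, 2)

    def test_nulliplex(self):
        assert enumerate_sharing_values(0, 3, 4) == (0,)

    def test_triplex_pair(self):
        assert enumerate_sharing_values(3, 3, 4) == (2, 3)

    @pytest.mark.parametrize("m", [2, 4, 6, 8])
    def test_cardinality_closed_form(self, m):
        for d, d1 in itertools.product(range(m + 1), repeat=2):
            vals = enumerate_sharing_values(d, d1, m)
            assert len(vals) == min(model.dosage_span(d, m), model.dosage_span(d1, m)) + 1

    def test_representative_has_requested_sharing(self):
        for m in (4, 6):
            for d, d1 in itertools.product(range(m + 1), repeat=2):
                for w in enumerate_sharing_values(d, d1, m):
                    pk, pk1 = representative_phase(d, d1, w, m)
                    assert (len(pk), len(pk1), len(pk & pk1)) == (d, d1, w)

    def test_invalid_sharing_rejected(self):
        with pytest.raises(ValueError):
            representative_phase(2, 2, 3, 4)
        with pytest.raises(ValueError):
            collapsed_joint((2, 2), (0, 0), (3, 0), 0.1, 4)


class TestCollapsedJoint:
    def test_grand_sum_is_one(self, rng):
        for m in (2, 4, 6):
            for _ in range(10):
                dP = tuple(rng.integers(0, m + 1, size=2))
                dQ = tuple(rng.integers(0, m + 1, size=2))
                wP = rng.choice(enumerate_sharing_values(*dP, m))
                wQ = rng.choice(enumerate_sharing_values(*dQ, m))
                A = collapsed_joint(dP, dQ, (int(wP), int(wQ)), rng.uniform(0, 0.5), m)
                assert A.sum() == pytest.approx(1.0)
                assert (A >= 0).all()

    def test_independence_at_r_half(self):
        m = 4
        A = collapsed_joint((2, 1), (1, 3), (1, 1), 0.5, m)
        expected = np.outer(polysomic_prior(2, 1, m), polysomic_prior(1, 3, m))
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_full_space_oracle_every_config_m4(self):
        # collapsed computation == brute-force aggregation of the 36x36
        # genotypic transition space, for every dosage/sharing combination
        m, r = 4, 0.17
        for dPk, dPk1, dQk, dQk1 in itertools.product(range(m + 1), repeat=4):
            for wP in enumerate_sharing_values(dPk, dPk1, m):
                for wQ in enumerate_sharing_values(dQk, dQk1, m):
                    A = collapsed_joint((dPk, dPk1), (dQk, dQk1), (wP, wQ), r, m)
                    pk, pk1 = representative_phase(dPk, dPk1, wP, m)
                    qk, qk1 = representative_phase(dQk, dQk1, wQ, m)
                    B = brute_collapsed(pk, pk1, qk, qk1, r, m)
                    np.testing.assert_allclose(A, B, atol=1e-12)

    def test_any_representative_same_table(self, rng):
        # partition invariance: every (phi, phi') pair with the same sharing
        # value yields the same coefficient tensor
        m = 4
        for dk, dk1 in [(1, 1), (2, 2), (2, 1), (3, 2)]:
            for w in enumerate_sharing_values(dk, dk1, m):
                tables = []
                for phi in itertools.combinations(range(1, m + 1), dk):
                    for phi1 in itertools.combinations(range(1, m + 1), dk1):
                        if len(set(phi) & set(phi1)) == w:
                            tables.append(
                                coeffs_from_subsets(phi, phi1, {1}, {1}, m)
                            )
                assert len(tables) > 1
                for t in tables[1:]:
                    np.testing.assert_allclose(t, tables[0], atol=1e-12)


class TestLoglik:
    def test_single_individual_indicator(self):
        m = 4
        A = collapsed_joint((1, 1), (1, 1), (1, 1), 0.1, m)
        pk = np.zeros((1, m + 1))
        pk1 = np.zeros((1, m + 1))
        pk[0, 1] = 1.0
        pk1[0, 2] = 1.0
        assert twopoint_loglik(pk, pk1, A) == pytest.approx(np.log(A[1, 2]))

    def test_marker_swap_symmetry(self, rng):
        m = 4
        A = collapsed_joint((2, 1), (1, 2), (1, 0), 0.2, m)
        pk = rng.dirichlet(np.ones(m + 1), size=9)
        pk1 = rng.dirichlet(np.ones(m + 1), size=9)
        assert twopoint_loglik(pk, pk1, A) == pytest.approx(
            twopoint_loglik(pk1, pk, A.T)
        )

    def test_zero_prior_row_error(self):
        m = 4
        A = collapsed_joint((1, 1), (1, 1), (1, 1), 0.1, m)
        pk = np.ones((3, m + 1)) / (m + 1)
        pk[1] = 0.0
        with pytest.raises(ValueError, match="individual 1"):
            twopoint_loglik(pk, np.ones((3, m + 1)) / (m + 1), A)

    def test_factorizes_at_independence(self, rng):
        # at r=0.5 the joint loglik equals the sum of the marginal logliks
        m = 4
        dP, dQ = (2, 1), (1, 2)
        A = collapsed_joint(dP, dQ, (1, 1), 0.5, m)
        pk = rng.dirichlet(np.ones(m + 1), size=40)
        pk1 = rng.dirichlet(np.ones(m + 1), size=40)
        margk = polysomic_prior(dP[0], dQ[0], m)
        margk1 = polysomic_prior(dP[1], dQ[1], m)
        expected = np.log(pk @ margk).sum() + np.log(pk1 @ margk1).sum()
        assert twopoint_loglik(pk, pk1, A) == pytest.approx(expected)


def _simulate_pair(m, n, r, HPcols, HQcols, seed):
    HP = np.zeros((m, 2), dtype=np.int8)
    HQ = np.zeros((m, 2), dtype=np.int8)
    for k, rows in enumerate(HPcols):
        HP[list(rows), k] = 1
    for k, rows in enumerate(HQcols):
        HQ[list(rows), k] = 1
    cfg = sim.SimConfig(m=m, n=n, z=2, distances_cm=[sim.haldane(r)])
    s = sim.simulate_population(cfg, parents=(HP, HQ), rng=np.random.default_rng(seed))
    priors = sim.indicator_priors(s.dosages, s.dP, s.dQ, m)
    return s, priors


class TestEstimate:
    def test_recovers_simulated_r(self):
        # informative coupling-phase duplex markers, r = 0.2, n = 500
        s, priors = _simulate_pair(4, 500, 0.2, [(0, 1), (0, 1)], [(0, 1), (0, 1)], 11)
        res = twopoint_estimate(priors[:, 0, :], priors[:, 1, :], (2, 2), (2, 2), (2, 2), 4)
        assert res.r_hat == pytest.approx(0.2, abs=0.05)
        assert res.lod_linkage > 3

    def test_uninformative_flags(self):
        m = 4
        pk = np.tile(polysomic_prior(0, 0, m), (10, 1))
        res = twopoint_estimate(pk, pk, (0, 0), (0, 0), (0, 0), m)
        assert res.uninformative
        assert res.r_hat == 0.5
        assert res.lod_linkage == 0.0

    def test_newton_agrees_with_em(self):
        s, priors = _simulate_pair(4, 200, 0.1, [(0,), (0,)], [(0, 1), (0, 1)], 3)
        em = twopoint_estimate(priors[:, 0, :], priors[:, 1, :], (1, 1), (2, 2), (1, 2), 4)
        nt = twopoint_estimate(priors[:, 0, :], priors[:, 1, :], (1, 1), (2, 2), (1, 2), 4,
                               method="newton")
        assert em.r_hat == pytest.approx(nt.r_hat, abs=1e-3)

    def test_em_fixed_point_is_local_max(self):
        s, priors = _simulate_pair(4, 300, 0.15, [(0, 1), (0, 1)], [(0,), (0,)], 8)
        res = twopoint_estimate(priors[:, 0, :], priors[:, 1, :], (2, 2), (1, 1), (2, 1), 4,
                                tol=1e-9)
        for dr in (-1e-3, 1e-3):
            r_alt = res.r_hat + dr
            if 0 < r_alt <= 0.5:
                A = collapsed_joint((2, 2), (1, 1), (2, 1), r_alt, 4)
                assert twopoint_loglik(priors[:, 0, :], priors[:, 1, :], A) <= res.loglik + 1e-6

    def test_matches_multipoint_for_two_markers(self):
        from polylink import hmm
        from polylink.model import MarkerPhase

        s, priors = _simulate_pair(4, 200, 0.2, [(0, 1), (0,)], [(0,), (0,)], 21)
        res = twopoint_estimate(priors[:, 0, :], priors[:, 1, :], (2, 1), (1, 1), (1, 1), 4,
                                tol=1e-9, max_iter=2000)
        chain = hmm.ChainModel(
            m=4,
            phases=[MarkerPhase(frozenset({1, 2}), frozenset({1})),
                    MarkerPhase(frozenset({1}), frozenset({1}))],
            r=[0.25], priors=priors,
        )
        fit = hmm.fit(chain, tol=1e-9, max_iter=2000)
        assert fit.r[0] == pytest.approx(res.r_hat, abs=1e-4)
        assert fit.loglik == pytest.approx(res.loglik, abs=1e-6)


class TestScanPhases:
    def test_partition_count(self):
        m = 4
        res = scan_phases(np.ones((5, 5)) / 5, np.ones((5, 5)) / 5, (2, 2), (1, 1), m)
        assert len(res) == 3 * 2  # 3 partitions for P, 2 for Q

    def test_best_has_zero_lod_and_sorted(self, rng):
        s, priors = _simulate_pair(4, 200, 0.05, [(0,), (0,)], [(0, 1), (1, 2)], 4)
        res = scan_phases(priors[:, 0, :], priors[:, 1, :], (1, 1), (2, 2), 4)
        assert res[0].lod_phase == 0.0
        assert all(res[i].loglik >= res[i + 1].loglik for i in range(len(res) - 1))
        assert all(r.lod_phase >= 0 for r in res)

    def test_recovers_true_phase(self):
        # truth wP=1 (coupling simplex), wQ=0 (repulsion simplex), r=0.01.
        # with symmetric parental dosages the mirrored phase (0, 1) is an
        # exact two-point tie, so assert the truth is among the tied best.
        s, priors = _simulate_pair(4, 200, 0.01, [(0,), (0,)], [(0,), (1,)], 5)
        res = scan_phases(priors[:, 0, :], priors[:, 1, :], (1, 1), (1, 1), 4)
        best = {(r.wP, r.wQ) for r in res if r.lod_phase < 1e-6}
        assert (1, 0) in best
        assert best <= {(1, 0), (0, 1)}

    def test_identical_uninformative_markers(self):
        m = 4
        pk = np.tile(polysomic_prior(0, 0, m), (6, 1))
        res = scan_phases(pk, pk, (0, 0), (0, 0), m)
        assert len(res) == 1
        assert res[0].uninformative


class TestPairwise:
    def test_matrix_symmetry_and_row_count(self):
        m = 4
        cfg = sim.SimConfig(m=m, n=100, z=4, seed=9)
        s = sim.simulate_population(cfg)
        priors = sim.indicator_priors(s.dosages, s.dP, s.dQ, m)
        table, r_mat, lod_mat = pairwise_rf_matrix(
            np.transpose(priors, (1, 0, 2)), s.dP, s.dQ, m
        )
        assert len(table) == 4 * 3 // 2
        np.testing.assert_allclose(r_mat, r_mat.T, equal_nan=True)
        assert np.isnan(np.diag(r_mat)).all()

    def test_linked_vs_unlinked(self):
        m = 4
        rng = np.random.default_rng(13)
        HP = np.zeros((m, 4), dtype=np.int8)
        HQ = np.zeros((m, 4), dtype=np.int8)
        HP[0] = 1
        HP[1, :2] = 1
        HQ[0] = 1
        # markers 0,1 at 1 cM; markers 2,3 effectively unlinked (200 cM away)
        cfg = sim.SimConfig(m=m, n=300, z=4, distances_cm=[1.0, 200.0, 1.0])
        s = sim.simulate_population(cfg, parents=(HP, HQ), rng=rng)
        priors = sim.indicator_priors(s.dosages, s.dP, s.dQ, m)
        table, r_mat, _ = pairwise_rf_matrix(np.transpose(priors, (1, 0, 2)), s.dP, s.dQ, m)
        assert r_mat[0, 1] < 0.05
        assert r_mat[2, 3] < 0.05
        assert r_mat[0, 2] > 0.35


class TestFisherInformation:
    def test_nonnegative(self, rng):
        for _ in range(10):
            r = rng.uniform(0.01, 0.49)
            assert fisher_information(r, (2, 1), (1, 1), (1, 1), 4) >= 0

    def test_finite_difference_oracle(self):
        # I(r) == -d2/dr2 E_r0[log A(r)] at r = r0
        m, dP, dQ, phase = 4, (2, 2), (1, 1), (2, 1)
        for r0 in (0.1, 0.25, 0.4):
            eps = 1e-5
            A0 = collapsed_joint(dP, dQ, phase, r0, m)

            def ell(r):
                A = collapsed_joint(dP, dQ, phase, r, m)
                mask = A0 > 0
                return (A0[mask] * np.log(A[mask])).sum()

            d2 = (ell(r0 + eps) - 2 * ell(r0) + ell(r0 - eps)) / eps**2
            assert fisher_information(r0, dP, dQ, phase, m) == pytest.approx(-d2, rel=1e-4)

    def test_hexaploid_single_dose_ordering(self):
        # coupling (w=1) beats repulsion (w=0) at small r for simplex pairs
        m = 6
        info1 = fisher_information(0.05, (1, 1), (0, 0), (1, 0), m)
        info0 = fisher_information(0.05, (1, 1), (0, 0), (0, 0), m)
        assert info1 > info0
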