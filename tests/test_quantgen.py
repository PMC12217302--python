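"""Colony-genetics machinery: G construction, gametes, drones, offspring,
worker-group means, and colony phenotypes."""

import numpy as np
import pytest

from apisim.quantgen import (ColonyRecord, GeneticParams, Q1, Q2, W1, W2,
                             build_G, colony_phenotype, draw_founder_bvs,
                             make_drone, make_gamete, make_offspring_queen,
                             worker_group_mean_bv)


def params(**kw):
    defaults = dict(sigma2_AW=1.0, sigma2_AQ=0.5, sigma2_eps=1.5)
    defaults.update(kw)
    return GeneticParams(**defaults)


class TestBuildG:
    def test_uncorrelated_is_diagonal(self):
        G = build_G(params())
        assert np.allclose(G, np.diag([1.0, 0.5, 1.0, 0.5]))

    def test_perfect_trait_correlation_collapses_rank(self):
        with pytest.warns(UserWarning):
            G = build_G(params(r_T1T2=1.0))
        assert np.linalg.matrix_rank(G, tol=1e-10) == 2
        assert np.allclose(G[:2, :2], G[2:, 2:])
        assert np.allclose(G[:2, 2:], G[:2, :2])

    def test_kronecker_entries_and_psd(self):
        G = build_G(params(r_WQ=-0.5, r_T1T2=0.6))
        cov_wq = -0.5 * np.sqrt(1.0 * 0.5)
        assert G[W1, Q1] == pytest.approx(cov_wq)          # -0.3536
        assert G[W1, Q1] == pytest.approx(-0.35355, abs=1e-4)
        assert np.allclose(G[:2, 2:], 0.6 * G[:2, :2])      # cross-trait block
        assert np.linalg.eigvalsh(G).min() >= -1e-12
        assert np.allclose(G, G.T)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_G(params(sigma2_AW=-1.0))
        with pytest.raises(ValueError):
            build_G(params(r_T1T2=1.5))


class TestFounders:
    def test_zero_G_gives_zero_bvs(self, rng):
        bvs = draw_founder_bvs(np.zeros((4, 4)), 5, rng)
        assert np.all(bvs == 0)

    def test_sample_covariance_matches_G(self, rng):
        G = build_G(params())
        n = 100_000
        bvs = draw_founder_bvs(G, n, rng)
        emp = np.cov(bvs.T)
        se = np.sqrt((np.outer(np.diag(G), np.diag(G)) + G ** 2) / n)
        assert np.all(np.abs(emp - G) < 3 * se + 1e-12)

    def test_founder_cohort_reproducible(self):
        G = build_G(params())
        a = draw_founder_bvs(G, 24, np.random.default_rng(7))
        b = draw_founder_bvs(G, 24, np.random.default_rng(7))
        assert np.array_equal(a, b)
        assert len(np.unique(a, axis=0)) == 24


class TestGametes:
    def test_fully_inbred_parent_transmits_deterministically(self, rng):
        G = build_G(params())
        bv = np.array([1.0, -2.0, 0.5, 0.25])
        g = make_gamete(bv, 1.0, G, rng)
        assert np.allclose(g, 0.5 * bv)

    def test_mendelian_sampling_variance(self, rng):
        G = build_G(params())
        bv = np.zeros(4)
        gam = make_gamete(bv, 0.0, G, rng, size=100_000)
        emp = np.cov(gam.T)
        assert np.all(np.abs(emp - 0.25 * G) < 0.01)

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 1.0])
    def test_variance_shrinks_linearly_in_F(self, rng, f):
        G = build_G(params())
        gam = make_gamete(np.zeros(4), f, G, rng, size=60_000)
        assert np.var(gam[:, W1]) == pytest.approx(0.25 * (1 - f), abs=0.01)

    def test_two_gametes_sum_recovers_base_variance(self, rng):
        """Closure: offspring of unrelated non-inbred parents have Var = G."""
        G = build_G(params(r_T1T2=0.3))
        n = 60_000
        p1 = draw_founder_bvs(G, n, rng)
        p2 = draw_founder_bvs(G, n, rng)
        kids = np.empty((n, 4))
        L = np.linalg.cholesky(0.25 * G)
        kids = 0.5 * p1 + rng.standard_normal((n, 4)) @ L.T \
            + 0.5 * p2 + rng.standard_normal((n, 4)) @ L.T
        emp = np.cov(kids.T)
        se = np.sqrt((np.outer(np.diag(G), np.diag(G)) + G ** 2) / n)
        assert np.all(np.abs(emp - G) < 4 * se + 1e-12)

    def test_invalid_F_rejected(self, rng):
        with pytest.raises(ValueError):
            make_gamete(np.zeros(4), -0.1, np.eye(4), rng)
        with pytest.raises(ValueError):
            make_gamete(np.zeros(4), 1.2, np.eye(4), rng)


class TestDronesAndOffspring:
    def test_drones_of_fully_inbred_dpq_identical(self, rng):
        G = build_G(params())
        bv = np.array([2.0, 1.0, 0.0, -1.0])
        drones = make_drone(bv, 1.0, G, rng, size=8)
        assert np.allclose(drones, 0.5 * bv)

    def test_drone_variance(self, rng):
        G = build_G(params())
        drones = make_drone(np.zeros(4), 0.0, G, rng, size=100_000)
        emp = np.cov(drones.T)
        assert np.all(np.abs(emp - 0.25 * G) < 0.01)

    def test_super_sisters_share_paternal_genome(self, rng):
        """A drone fathers every daughter with the same clonal genome."""
        G = build_G(params())
        drone = make_drone(draw_founder_bvs(G, 1, rng)[0], 0.0, G, rng)
        dam = draw_founder_bvs(G, 1, rng)[0]
        k1 = make_offspring_queen(dam, 0.0, drone, G, rng)
        k2 = make_offspring_queen(dam, 0.0, drone, G, rng)
        # identical paternal part: difference is purely maternal sampling
        diff = k1 - k2
        assert diff.shape == (4,)
        # deterministic case: fully inbred dam and drone from inbred DPQ
        dk1 = make_offspring_queen(dam, 1.0, drone, G, rng)
        dk2 = make_offspring_queen(dam, 1.0, drone, G, rng)
        assert np.allclose(dk1, dk2)
        assert np.allclose(dk1, 0.5 * dam + drone)

    def test_offspring_moments(self, rng):
        """Var(offspring) = G and Cov(offspring, dam) = 0.5 G."""
        G = build_G(params())
        n = 60_000
        dams = draw_founder_bvs(G, n, rng)
        dpqs = draw_founder_bvs(G, n, rng)
        L = np.linalg.cholesky(0.25 * G)
        drones = 0.5 * dpqs + rng.standard_normal((n, 4)) @ L.T
        kids = 0.5 * dams + rng.standard_normal((n, 4)) @ L.T + drones
        se = np.sqrt(2.0 / n) * 3
        assert np.all(np.abs(np.cov(kids.T) - G) < 4 * np.sqrt(2 / n) + 0.02)
        cross = (kids - kids.mean(0)).T @ (dams - dams.mean(0)) / (n - 1)
        assert np.all(np.abs(cross - 0.5 * G) < 0.02 + se)

    def test_super_sister_correlation_three_quarters(self, rng):
        """Same dam, same father drone: additive correlation 0.75."""
        G = np.eye(4)
        n = 80_000
        dams = draw_founder_bvs(G, n, rng)
        drones = make_drone(np.zeros(4), 0.0, G, rng, size=n) \
            + 0.5 * draw_founder_bvs(G, n, rng)
        L = np.linalg.cholesky(0.25 * G)
        k1 = 0.5 * dams + rng.standard_normal((n, 4)) @ L.T + drones
        k2 = 0.5 * dams + rng.standard_normal((n, 4)) @ L.T + drones
        corr = np.corrcoef(k1[:, 0], k2[:, 0])[0, 1]
        assert corr == pytest.approx(0.75, abs=0.02)


class TestWorkerGroup:
    def test_identical_drones_reduce_to_midparent(self):
        d = np.array([0.5, 0.1, -0.3, 0.2])
        q = np.array([1.0, 2.0, 3.0, 4.0])
        wm = worker_group_mean_bv(q, 0.0, np.tile(d, (8, 1)))
        assert np.allclose(wm, 0.5 * q + d)

    def test_paternal_variance_is_drone_variance_over_eight(self, rng):
        G = build_G(params())
        n = 30_000
        means = np.empty((n, 4))
        for i in range(n):
            drones = make_drone(np.zeros(4), 0.0, G, rng, size=8)
            means[i] = worker_group_mean_bv(np.zeros(4), 0.0, drones)
        emp = np.var(means[:, W1])
        assert emp == pytest.approx(0.25 / 8, rel=0.1)

    def test_open_mated_expectation_is_half_queen(self, rng):
        """Base drones average zero, so E[worker mean] = 0.5 * queen BV."""
        G = build_G(params())
        q = np.array([2.0, -1.0, 0.5, 0.0])
        n = 20_000
        acc = np.zeros(4)
        for _ in range(n):
            dummies = draw_founder_bvs(G, 8, rng)
            drones = 0.5 * dummies + make_drone(np.zeros(4), 0.0, G, rng, size=8)
            acc += worker_group_mean_bv(q, 0.0, drones)
        assert np.allclose(acc / n, 0.5 * q, atol=0.02)

    def test_wrong_drone_count_rejected(self):
        with pytest.raises(ValueError):
            worker_group_mean_bv(np.zeros(4), 0.0, np.zeros((7, 4)))


class TestColonyPhenotype:
    def _record(self, qbv, wbv):
        return ColonyRecord("q", "w", 1, 3, true_queen_bv=np.asarray(qbv),
                            true_worker_mean_bv=np.asarray(wbv))

    def test_zero_noise_recovers_true_effects(self, rng):
        p = GeneticParams(sigma2_eps=1e-30)
        rec = self._record([9., 1., 9., 2.], [3., 9., 4., 9.])
        colony_phenotype(rec, np.zeros(2), p, rng)
        assert rec.y_T1 == pytest.approx(1.0 + 3.0, abs=1e-6)
        assert rec.y_T2 == pytest.approx(2.0 + 4.0, abs=1e-6)

    def test_variance_decomposition(self, rng):
        """Var(y) = queen + worker + apiary + residual variance."""
        p = params()
        G = build_G(p)
        n = 40_000
        ys = np.empty(n)
        for i in range(n):
            qbv = draw_founder_bvs(G, 1, rng)[0]
            dummies = draw_founder_bvs(G, 8, rng)
            L = np.linalg.cholesky(0.25 * G)
            drones = 0.5 * dummies + rng.standard_normal((8, 4)) @ L.T
            wbv = worker_group_mean_bv(qbv, 0.0, drones)
            rec = self._record(qbv, wbv)
            E = rng.normal(0, [np.sqrt(p.sigma2_apiary_T1),
                               np.sqrt(p.sigma2_apiary_T2)])
            colony_phenotype(rec, E, p, rng)
            ys[i] = rec.y_T1
        # queen 0.5 + worker mean (0.25 maternal + 0.5/8 drones) + apiary 1
        # + residual 1.5; worker-queen cross term is zero at r_WQ = 0
        expected = 0.5 + (0.25 + 0.5 / 8) + 1.0 + 1.5
        assert np.var(ys) == pytest.approx(expected, rel=0.05)

    def test_early_only_mode_leaves_late_trait_missing(self, rng):
        rec = self._record(np.ones(4), np.ones(4))
        colony_phenotype(rec, np.zeros(2), params(), rng,
                         traits_to_record=(True, False))
        assert np.isfinite(rec.y_T1)
        assert np.isnan(rec.y_T2)
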