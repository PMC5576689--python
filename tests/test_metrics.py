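"""Overlap, variance, collectivity, subspace and ensemble metrics."""

import math

import numpy as np
import pytest

from lmcenm import metrics
from lmcenm.enm import ModeSet, UniformCutoff, build_network, normal_modes
from lmcenm.synthetic import make_globule


def random_modeset(n_res, rng, n_zero=0):
    """Orthonormal basis with random positive eigenvalues (test helper)."""
    dim = 3 * n_res
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    evals = np.sort(rng.uniform(0.5, 5.0, size=dim))
    evals[:n_zero] = 0.0
    return ModeSet(eigenvalues=evals, eigenvectors=q, n_zero=n_zero,
                   zero_tol=1e-8)


class TestModeOverlap:
    def test_parallel_is_one(self, rng):
        v = rng.normal(size=30)
        assert metrics.mode_overlap(v, 2.5 * v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        a = np.zeros(6); a[0] = 1.0
        b = np.zeros(6); b[3] = 1.0
        assert metrics.mode_overlap(a, b) == pytest.approx(0.0)

    def test_sixty_degrees_is_half(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
        assert metrics.mode_overlap(a, b) == pytest.approx(0.5)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError, match="undefined overlap"):
            metrics.mode_overlap(np.ones(6), np.zeros(6))


class TestCumulativeOverlap:
    def test_pythagorean(self, rng):
        ms = random_modeset(4, rng)
        # displacement built from two modes with overlaps 0.6 and 0.8
        d = 0.6 * ms.mode(0) + 0.8 * ms.mode(1)
        assert metrics.cumulative_overlap(ms, d, 2) == pytest.approx(1.0)
        assert metrics.cumulative_overlap(ms, d, 1) == pytest.approx(0.6)

    def test_monotone_in_k(self, rng):
        ms = random_modeset(5, rng)
        d = rng.normal(size=15)
        co = [metrics.cumulative_overlap(ms, d, k) for k in range(1, 16)]
        assert all(b >= a - 1e-12 for a, b in zip(co, co[1:]))

    def test_complete_basis_reaches_one(self):
        """CO over all nonzero modes is 1 for displacements orthogonal to
        the rigid-body motions."""
        net = build_network(make_globule(20, seed=2), UniformCutoff())
        ms = normal_modes(net)
        rng = np.random.default_rng(5)
        d = rng.normal(size=60)
        rigid = ms.eigenvectors[:, : ms.n_zero]
        d -= rigid @ (rigid.T @ d)  # project off rigid modes
        co = metrics.cumulative_overlap(ms, d, ms.n_nonzero)
        assert co == pytest.approx(1.0, abs=1e-8)


class TestVarianceFractions:
    def test_equal_eigenvalues_split_evenly(self, rng):
        ms = random_modeset(2, rng)
        ms.eigenvalues[:] = 1.0
        frac, cfv = metrics.variance_fractions(ms, 3)
        np.testing.assert_allclose(frac, 1 / 6)
        assert cfv == pytest.approx(0.5)

    def test_inverse_eigenvalue_weighting(self):
        ms = ModeSet(eigenvalues=np.array([1.0, 3.0]),
                     eigenvectors=np.eye(2), n_zero=0, zero_tol=1e-8)
        frac, _ = metrics.variance_fractions(ms)
        np.testing.assert_allclose(frac, [0.75, 0.25])

    def test_cfv_all_is_one(self, rng):
        ms = random_modeset(4, rng)
        _, cfv = metrics.variance_fractions(ms)
        assert cfv == pytest.approx(1.0)


class TestCollectivity:
    def test_uniform_amplitude_is_one(self):
        n = 30
        mode = np.tile([1.0, 0.0, 0.0], n)
        assert metrics.collectivity(mode) == pytest.approx(1.0)

    def test_single_residue_is_one_over_n(self):
        n = 25
        mode = np.zeros(3 * n)
        mode[0] = 1.0
        assert metrics.collectivity(mode) == pytest.approx(1 / n)

    def test_half_support(self):
        # N = 4, squared amplitudes (0.5, 0.5, 0, 0) → exp(log 2)/4 = 0.5
        mode = np.zeros(12)
        mode[0] = mode[3] = math.sqrt(0.5)
        assert metrics.collectivity(mode) == pytest.approx(0.5)

    def test_zero_mode_rejected(self):
        with pytest.raises(ValueError, match="zero mode"):
            metrics.collectivity(np.zeros(9))


class TestBestMode:
    def test_exact_mode_hit(self, rng):
        ms = random_modeset(6, rng)
        rec = metrics.best_mode(ms, ms.mode(3))
        assert rec.rank == 3
        assert rec.max_overlap == pytest.approx(1.0)

    def test_rank_zero_is_first_nonzero_mode(self, rng):
        ms = random_modeset(6, rng, n_zero=6)
        rec = metrics.best_mode(ms, ms.mode(0))
        assert rec.rank == 0

    def test_matches_exhaustive_scan(self, rng):
        ms = random_modeset(20, rng)
        d = rng.normal(size=60)
        rec = metrics.best_mode(ms, d)
        brute = [metrics.mode_overlap(ms.mode(k), d) for k in range(ms.n_nonzero)]
        assert rec.rank == int(np.argmax(brute))
        assert rec.max_overlap == pytest.approx(max(brute))


class TestModesToReach:
    def test_single_mode_displacement(self, rng):
        ms = random_modeset(4, rng)
        out = metrics.modes_to_reach(ms, ms.mode(0))
        assert out == {0.7: 1, 0.8: 1, 0.9: 1}

    def test_two_overlaps_of_point_six(self, rng):
        """Overlaps (0.6, 0.6) give CO(2) ≈ 0.849: enough for 70% and 80%,
        never 90% within the two-mode set."""
        ms = random_modeset(4, rng)
        two = ModeSet(eigenvalues=ms.eigenvalues[:2],
                      eigenvectors=ms.eigenvectors[:, :2], n_zero=0,
                      zero_tol=1e-8)
        rest = math.sqrt(1 - 2 * 0.6**2)
        d = 0.6 * ms.mode(0) + 0.6 * ms.mode(1) + rest * ms.mode(2)
        out = metrics.modes_to_reach(two, d)
        assert out[0.7] == 2
        assert out[0.8] == 2
        assert out[0.9] == math.inf

    def test_threshold_monotonicity(self, rng):
        ms = random_modeset(8, rng)
        d = rng.normal(size=24)
        out = metrics.modes_to_reach(ms, d)
        assert out[0.9] >= out[0.8] >= out[0.7]


class TestFluctuationCorrelation:
    def test_self_correlation(self, rng):
        ms = random_modeset(10, rng)
        prof = metrics.fluctuation_profile(ms, 5)
        assert metrics.correlate(prof, prof) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        ms = random_modeset(10, rng)
        prof = metrics.fluctuation_profile(ms, 5)
        assert metrics.correlate(prof, 2 * prof + 5) == pytest.approx(1.0)

    def test_hand_computed_coefficient(self):
        p = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        expected = np.corrcoef(p, r)[0, 1]
        assert metrics.correlate(p, r) == pytest.approx(expected)


class TestSubspaceSimilarity:
    def test_rmsip_identity(self, rng):
        ms = random_modeset(10, rng)
        u = ms.nonzero_modes
        assert metrics.rmsip(u, u, k=10) == pytest.approx(1.0)

    def test_rmsip_swap_invariance(self, rng):
        ms = random_modeset(10, rng)
        u = ms.nonzero_modes[:, :10]
        v = u[:, [1, 0, 2, 3, 4, 5, 6, 7, 8, 9]]
        assert metrics.rmsip(u, v, k=10) == pytest.approx(1.0)

    def test_rmsip_orthogonal(self):
        u = np.eye(6)[:, :2]
        v = np.eye(6)[:, 2:4]
        assert metrics.rmsip(u, v, k=2) == pytest.approx(0.0)

    def test_rwsip_identity(self):
        u = np.eye(4)
        w = np.array([4.0, 3.0, 2.0, 1.0])
        assert metrics.rwsip(u, w, u, w) == pytest.approx(1.0)

    def test_rwsip_mismatched_weights_below_one(self):
        u = np.eye(2)
        assert metrics.rwsip(u, [2.0, 1.0], u[:, [1, 0]], [2.0, 1.0]) < 1.0

    def test_rwsip_orthogonal(self):
        u = np.eye(6)[:, :3]
        v = np.eye(6)[:, 3:]
        w = np.array([3.0, 2.0, 1.0])
        assert metrics.rwsip(u, w, v, w) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        a = random_modeset(5, rng).nonzero_modes[:, :5]
        b = random_modeset(5, np.random.default_rng(77)).nonzero_modes[:, :5]
        wa = np.sort(rng.uniform(1, 5, 5))[::-1]
        wb = np.sort(rng.uniform(1, 5, 5))[::-1]
        assert metrics.rwsip(a, wa, b, wb) == pytest.approx(
            metrics.rwsip(b, wb, a, wa))
        assert metrics.rmsip(a, b, 5) == pytest.approx(metrics.rmsip(b, a, 5))


class TestEnsemblePCA:
    def test_single_axis_variation(self, rng):
        base = rng.normal(size=(10, 3))
        # vary only the x coordinate of the first atom
        ensemble = []
        for t in (-1.0, 0.0, 1.0, 2.0, -2.0):
            c = base.copy()
            c[0, 0] += t
            ensemble.append(c)
        dirs, var = metrics.ensemble_pca(ensemble)
        assert var[0] > 1e-10
        np.testing.assert_allclose(var[1:], 0.0, atol=1e-20)
        assert abs(dirs[0, 0]) == pytest.approx(1.0)

    def test_recovers_generator_variances(self, rng):
        """Two-mode Gaussian sampler: PCA variances match within 10% at 500."""
        n_res = 15
        q, _ = np.linalg.qr(rng.normal(size=(3 * n_res, 2)))
        sd = np.array([3.0, 1.0])
        base = rng.normal(size=3 * n_res)
        samples = [
            (base + q @ (sd * rng.normal(size=2))).reshape(n_res, 3)
            for _ in range(500)
        ]
        mean = np.mean([s.reshape(-1) for s in samples], axis=0)
        centered = [s - mean.reshape(n_res, 3) for s in samples]
        _, var = metrics.ensemble_pca(centered)
        np.testing.assert_allclose(var[:2], sd**2, rtol=0.1)

    def test_total_variance_trace_identity(self, rng):
        samples = [rng.normal(size=(8, 3)) for _ in range(20)]
        flat = np.array([s.reshape(-1) for s in samples])
        msd = np.mean(np.sum((flat - flat.mean(axis=0)) ** 2, axis=1))
        _, var = metrics.ensemble_pca(samples)
        assert var.sum() == pytest.approx(msd)

    def test_too_few_conformers(self):
        with pytest.raises(ValueError, match="three conformers"):
            metrics.ensemble_pca([np.zeros((4, 3))] * 2)


class TestBoundedRanges:
    def test_metric_ranges_on_random_fixtures(self, rng):
        """All bounded metrics stay in their documented ranges (1000 draws)."""
        ms = random_modeset(6, rng)
        u = ms.nonzero_modes
        for _ in range(1000):
            d = rng.normal(size=18)
            o = metrics.mode_overlap(u[:, 0], d)
            co = metrics.cumulative_overlap(ms, d, 5)
            kap = metrics.collectivity(d)
            assert 0.0 <= o <= 1.0
            assert 0.0 <= co <= 1.0 + 1e-12
            assert 1 / 6 - 1e-12 <= kap <= 1.0 + 1e-12
        for _ in range(100):
            a, _ = np.linalg.qr(rng.normal(size=(18, 5)))
            b, _ = np.linalg.qr(rng.normal(size=(18, 5)))
            wa = np.sort(rng.uniform(0.5, 5, 5))[::-1]
            wb = np.sort(rng.uniform(0.5, 5, 5))[::-1]
            assert 0.0 <= metrics.rmsip(a, b, 5) <= 1.0 + 1e-12
            assert 0.0 <= metrics.rwsip(a, wa, b, wb) <= 1.0 + 1e-12
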