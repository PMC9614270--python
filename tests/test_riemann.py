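"""SPD geometry: OAS estimation, the affine-invariant metric, Karcher
means, tangent maps, the potato, and the multi-band stack."""

import numpy as np
import pytest

from conftest import random_spd
from podeeg.config import DEFAULT_BANDS
from podeeg.errors import ContractError
from podeeg.riemann import (
    airm_distance,
    balanced_reference,
    expm_sym,
    geodesic_step,
    invsqrtm_spd,
    is_spd,
    logm_spd,
    multiband_stack,
    oas_covariance,
    riemannian_mean,
    riemannian_potato,
    sqrtm_spd,
    tangent_project,
    tangent_unproject,
)


def oas_reference(block):
    """Independent implementation of the published shrinkage formula,
    written with explicit loops over the definition."""
    block = np.asarray(block, float)
    p, n = block.shape
    xc = block - block.mean(axis=1, keepdims=True)
    s = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            s[i, j] = np.dot(xc[i], xc[j]) / n
    tr_s = sum(s[i, i] for i in range(p))
    tr_s2 = sum(s[i, j] * s[j, i] for i in range(p) for j in range(p))
    mu = tr_s / p
    num = (1 - 2.0 / p) * tr_s2 + tr_s**2
    den = (n + 1 - 2.0 / p) * (tr_s2 - tr_s**2 / p)
    rho = min(1.0, num / den) if den > 0 else 1.0
    return (1 - rho) * s + rho * mu * np.eye(p)


class TestOAS:
    def test_matches_published_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.choice([5, 25])
            n = int(rng.integers(2, 400))
            block = rng.normal(size=(p, n)) * rng.uniform(0.5, 3.0)
            got = oas_covariance(block)
            np.testing.assert_allclose(got, oas_reference(block), atol=1e-10)
            assert np.linalg.eigvalsh(got).min() > 0

    def test_identity_covariance_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        got = oas_covariance(rng.normal(size=(5, 200_000)))
        np.testing.assert_allclose(got, np.eye(5), atol=0.05)

    def test_tiny_n_shrinks_toward_scaled_identity(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(25, 2))
        got = oas_covariance(block)
        xc = block - block.mean(axis=1, keepdims=True)
        emp = xc @ xc.T / 2
        mu_eye = np.trace(emp) / 25 * np.eye(25)
        # strong shrinkage: much closer to the scaled identity than the
        # (singular) empirical covariance is
        assert np.linalg.norm(got - mu_eye) < 0.4 * np.linalg.norm(emp - mu_eye)
        assert np.linalg.eigvalsh(got).min() > 0

    def test_approximates_sklearn_at_large_n(self):
        # sklearn drops the 2/p terms of the published formula; at large n
        # the two agree closely
        from sklearn.covariance import oas as sk_oas

        rng = np.random.default_rng(3)
        block = rng.normal(size=(10, 5000))
        got = oas_covariance(block)
        ref, _ = sk_oas(block.T)
        np.testing.assert_allclose(got, ref, atol=1e-4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ContractError):
            oas_covariance(np.ones((4, 1)))


class TestMetric:
    def test_identity_of_indiscernibles_and_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        assert airm_distance(a, a) == pytest.approx(0.0, abs=1e-9)
        assert airm_distance(a, b) == pytest.approx(airm_distance(b, a), abs=1e-10)
        assert airm_distance(a, b) > 0

    def test_scalar_matrices_closed_form(self):
        # d(I, e^2 I_2) = ||diag(2, 2)||_F = 2 sqrt(2)
        assert airm_distance(np.eye(2), np.exp(2) * np.eye(2)) == pytest.approx(
            2 * np.sqrt(2), abs=1e-10
        )

    def test_congruence_invariance(self):
        rng = np.random.default_rng(5)
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        w = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        assert airm_distance(w @ a @ w.T, w @ b @ w.T) == pytest.approx(
            airm_distance(a, b), abs=1e-8
        )

    def test_non_spd_rejected(self):
        with pytest.raises(ContractError):
            airm_distance(np.eye(3), np.diag([1.0, -1.0, 1.0]))


class TestKarcherMean:
    def test_mean_of_identical_matrices(self):
        a = random_spd(np.random.default_rng(6), 4)
        np.testing.assert_allclose(riemannian_mean([a, a]), a, atol=1e-8)

    def test_commuting_matrices_geometric_mean(self):
        m = riemannian_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        np.testing.assert_allclose(m, np.diag([2.0, 2.0]), atol=1e-8)

    def test_two_point_closed_form(self):
        rng = np.random.default_rng(7)
        a, b = random_spd(rng, 6), random_spd(rng, 6)
        w, wi = sqrtm_spd(a), invsqrtm_spd(a)
        expected = w @ sqrtm_spd(wi @ b @ wi) @ w
        np.testing.assert_allclose(riemannian_mean([a, b]), expected, atol=1e-8)

    def test_weighted_mean_fixed_point(self):
        rng = np.random.default_rng(8)
        mats = [random_spd(rng, 4) for _ in range(6)]
        weights = rng.uniform(0.5, 2.0, size=6)
        m = riemannian_mean(mats, weights)
        wi = invsqrtm_spd(m)
        tangent = sum(
            wgt / weights.sum() * logm_spd(wi @ c @ wi) for wgt, c in zip(weights, mats)
        )
        assert np.linalg.norm(tangent, "fro") < 1e-8


class TestTangentSpace:
    def test_reference_maps_to_zero(self):
        r = random_spd(np.random.default_rng(9), 5)
        assert np.linalg.norm(tangent_project(r, r)) == pytest.approx(0.0, abs=1e-9)

    def test_norm_equals_distance_and_round_trip(self):
        rng = np.random.default_rng(10)
        r = random_spd(rng, 6)
        for _ in range(10):
            c = random_spd(rng, 6)
            v = tangent_project(c, r)
            assert np.linalg.norm(v) == pytest.approx(airm_distance(r, c), abs=1e-8)
            np.testing.assert_allclose(tangent_unproject(v, r), c, atol=1e-8)

    def test_vector_dimension(self):
        rng = np.random.default_rng(11)
        r = random_spd(rng, 25)
        v = tangent_project(random_spd(rng, 25), r)
        assert v.shape == (25 * 26 // 2,)


class TestBalancedReference:
    def test_equal_class_means(self):
        m = random_spd(np.random.default_rng(12), 4)
        out = balanced_reference([m, m, m], [0, 0, 1])
        np.testing.assert_allclose(out, m, atol=1e-8)

    def test_invariant_to_duplicating_a_class(self):
        rng = np.random.default_rng(13)
        mats = [random_spd(rng, 4) for _ in range(4)]
        labels = [0, 0, 1, 1]
        base = balanced_reference(mats, labels)
        dup = balanced_reference(mats + mats[:2], labels + [0, 0])
        np.testing.assert_allclose(base, dup, atol=1e-7)

    def test_commuting_class_means_closed_form(self):
        out = balanced_reference(
            [np.diag([1.0, 1.0]), np.diag([4.0, 4.0])], [0, 1]
        )
        np.testing.assert_allclose(out, np.diag([2.0, 2.0]), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            balanced_reference([np.eye(2), np.eye(2)], [1, 1])


class TestPotato:
    def test_identical_frames_none_flagged(self):
        a = random_spd(np.random.default_rng(14), 4)
        mask = riemannian_potato([a] * 30)
        assert mask.all()

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(15)
        base = random_spd(rng, 4)
        mats = [base + 0.01 * random_spd(rng, 4) for _ in range(50)]
        mats[25] = 10.0 * mats[25]
        mask = riemannian_potato(mats)
        assert not mask[25]
        assert mask.sum() >= 48

    def test_planted_outlier_recovery(self):
        rng = np.random.default_rng(16)
        base = random_spd(rng, 8)
        mats, outliers = [], []
        for i in range(200):
            c = base + 0.05 * random_spd(rng, 8)
            if rng.random() < 0.05:
                c = 10.0 * c
                outliers.append(i)
            mats.append(c)
        mask = riemannian_potato(mats)
        outliers = np.asarray(outliers)
        inliers = np.setdiff1d(np.arange(200), outliers)
        assert (~mask[outliers]).mean() >= 0.90
        assert (~mask[inliers]).mean() <= 0.05

    def test_affine_invariance_of_flagging(self):
        rng = np.random.default_rng(17)
        base = random_spd(rng, 4)
        mats = [base + 0.05 * random_spd(rng, 4) for _ in range(60)]
        mats[30] = 8.0 * mats[30]
        mask1 = riemannian_potato(mats)
        mask2 = riemannian_potato([37.5 * m for m in mats])
        np.testing.assert_array_equal(mask1, mask2)


class TestMultibandStack:
    def test_row_count_and_alpha_energy(self):
        fs = 128.0
        t = np.arange(0, 20, 1 / fs)
        block = np.tile(np.sin(2 * np.pi * 10 * t), (4, 1))
        tl = np.zeros(block.shape[1])
        out = multiband_stack([block], [tl], fs)[0]
        assert out.data.shape[0] == 4 * len(DEFAULT_BANDS) + 1
        band_energy = [
            out.data[4 * k : 4 * k + 4].var() for k in range(len(DEFAULT_BANDS))
        ]
        assert np.argmax(band_energy) == 2          # lower alpha rows
        assert band_energy[0] < 0.01 * band_energy[2]   # delta rows ~ 0
        assert np.abs(out.data[-1]).max() == 0.0    # zero timeline row

    def test_filterbank_roughly_reconstructs_broadband(self):
        fs = 128.0
        rng = np.random.default_rng(18)
        from scipy.signal import butter, sosfiltfilt

        block = rng.normal(size=(4, int(30 * fs)))
        tl = np.zeros(block.shape[1])
        out = multiband_stack([block], [tl], fs)[0]
        summed = sum(out.data[4 * k : 4 * k + 4] for k in range(len(DEFAULT_BANDS)))
        sos = butter(4, [0.3, 30.0], btype="band", fs=fs, output="sos")
        broadband = sosfiltfilt(sos, block, axis=1)
        resid = summed - broadband
        assert resid.var() < 0.25 * broadband.var()

    def test_misaligned_timeline_rejected(self):
        with pytest.raises(ContractError):
            multiband_stack([np.zeros((4, 256))], [np.zeros(100)], 128.0)


def test_matrix_functions_are_mutual_inverses():
    rng = np.random.default_rng(19)
    a = random_spd(rng, 5)
    np.testing.assert_allclose(expm_sym(logm_spd(a)), a, atol=1e-9)
    np.testing.assert_allclose(sqrtm_spd(a) @ sqrtm_spd(a), a, atol=1e-9)
    assert is_spd(geodesic_step(a, random_spd(rng, 5), 0.3))
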