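"""Degradation model, patches, PCA, OMP, K-SVD and the SR pipelines."""

import dataclasses

import numpy as np
import pytest

from mesr.sparse_model import (
    DegradationSpec,
    DictionaryPair,
    PatchConfig,
    aggregate_patches,
    build_mesr_detail_image,
    degrade,
    extract_feature_patches,
    extract_lr_features,
    extract_patches,
    fit_pca_projection,
    high_pass_filters,
    ksvd_train,
    mesr_train,
    omp_batch,
    omp_code,
    solve_hr_dictionary,
    sr_reconstruct,
    train_dictionary_variants,
    upscale,
)


def _smooth_test_image(size, seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.random((size, size)), 3.0)
    img[size // 4 : -size // 4, size // 4 : -size // 4] += 0.5
    return img


class TestDegradation:
    def test_identity_spec(self, rng):
        img = rng.random((16, 16))
        spec = DegradationSpec(scale=1, blur_sigma=0.0, noise_sigma=0.0)
        np.testing.assert_array_equal(degrade(img, spec), img)

    def test_scale_two_halves_sides(self, rng):
        z = degrade(rng.random((256, 256)), DegradationSpec())
        assert z.shape == (128, 128)

    def test_noise_magnitude_half_normal(self):
        # E|v| = sigma sqrt(2/pi) for centered Gaussian noise
        spec = DegradationSpec(scale=2, blur_sigma=0.0, noise_sigma=0.1)
        clean = np.zeros((512, 512))
        z = degrade(clean, spec, rng=7)
        assert np.isclose(np.abs(z).mean(), 0.1 * np.sqrt(2 / np.pi), rtol=0.05)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            degrade(np.zeros((15, 16)), DegradationSpec(scale=2))

    def test_upscale_constant_and_shape(self):
        out = upscale(np.full((128, 128), 2.5), DegradationSpec(scale=2))
        assert out.shape == (256, 256)
        np.testing.assert_allclose(out, 2.5)

    def test_upscale_degrade_roundtrip_on_ramp(self):
        # bicubic interpolation reproduces a linear ramp away from borders
        x = np.linspace(0.0, 1.0, 64)
        img = np.add.outer(x, 0.5 * x)
        spec = DegradationSpec(scale=2, blur_sigma=0.0)
        rec = upscale(degrade(img, spec), spec)
        assert np.abs(rec - img)[8:-8, 8:-8].max() < 0.02

    def test_unknown_upscaler(self):
        with pytest.raises(ValueError):
            upscale(np.zeros((4, 4)), DegradationSpec(upscaler="lanczos"))


class TestFeaturesAndPatches:
    def test_constant_image_has_zero_features(self):
        feats = extract_lr_features(np.full((16, 16), 3.0))
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_ramp_derivative_and_laplacian(self):
        img = np.tile(np.arange(32.0), (32, 1))  # slope 1 along x
        feats = extract_lr_features(img)
        # [1, 0, -1] correlation: f(x-1) - f(x+1) = -2 * slope
        np.testing.assert_allclose(feats[0][2:-2, 2:-2], -2.0, atol=1e-12)
        np.testing.assert_allclose(feats[1][2:-2, 2:-2], 0.0, atol=1e-12)
        np.testing.assert_allclose(feats[2][2:-2, 2:-2], 0.0, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        feats = extract_lr_features(img)
        k = high_pass_filters()[0]  # [1, 0, -1] horizontal, correlation
        assert feats[0][4, 3] == -1.0 and feats[0][4, 5] == 1.0
        assert k.shape == (1, 3)

    def test_patch_counts(self):
        p1, _ = extract_patches(np.zeros((9, 9)), 9, 1)
        assert p1.shape == (1, 81)
        p9, locs = extract_patches(np.zeros((11, 11)), 9, 1)
        assert p9.shape == (9, 81)
        assert locs.shape == (9, 2)

    def test_block_larger_than_image(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((8, 8)), 9, 1)

    def test_overlap_average_reassembly_identity(self, rng):
        img = rng.random((20, 20))
        patches, locs = extract_patches(img, 5, 1)
        rec = aggregate_patches(patches, locs, img.shape, 5)
        np.testing.assert_allclose(rec, img, atol=1e-12)

    def test_feature_patch_concatenation(self, rng):
        stack = rng.random((4, 12, 12))
        fp, locs = extract_feature_patches(stack, 5, 2)
        assert fp.shape[1] == 4 * 25
        single = [extract_patches(f, 5, 2)[0] for f in stack]
        np.testing.assert_array_equal(fp, np.concatenate(single, axis=1))


class TestPCA:
    def test_exact_subspace_dimension(self, rng):
        basis = rng.standard_normal((3, 20))
        coeffs = rng.standard_normal((500, 3))
        X = coeffs @ basis
        proj = fit_pca_projection(X, retained_variance=0.999)
        assert proj.dim == 3
        # orthonormal rows
        np.testing.assert_allclose(proj.components @ proj.components.T, np.eye(3), atol=1e-10)

    def test_full_variance_keeps_rank(self, rng):
        X = rng.standard_normal((50, 8))
        proj = fit_pca_projection(X, retained_variance=1.0)
        assert proj.dim == 8

    def test_reconstruction_loss_bounded(self, rng):
        X = rng.standard_normal((300, 30)) * np.linspace(3, 0.1, 30)
        rv = 0.95
        proj = fit_pca_projection(X, retained_variance=rv)
        back = proj.backproject(proj.project(X))
        total = ((X - X.mean(0)) ** 2).sum()
        lost = ((X - back) ** 2).sum()
        assert lost <= (1 - rv) * total + 1e-9

    def test_degenerate_input_warns_identity(self):
        X = np.full((10, 6), 2.0)
        with pytest.warns(UserWarning):
            proj = fit_pca_projection(X)
        assert proj.dim == 6

    def test_too_few_patches(self):
        with pytest.raises(ValueError):
            fit_pca_projection(np.zeros((1, 5)))


class TestOMP:
    def test_single_scaled_atom(self, rng):
        D = rng.standard_normal((8, 12))
        D /= np.linalg.norm(D, axis=0)
        code = omp_code(2.0 * D[:, 3], D, sparsity=3)
        assert code.support[0] == 3
        assert np.isclose(code.coefficients[3], 2.0)
        assert code.residual_norm < 1e-6

    def test_orthonormal_dictionary_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        x = rng.standard_normal(10)
        code = omp_code(x, Q, sparsity=4)
        inner = Q.T @ x
        order = np.argsort(-np.abs(inner))[:4]
        np.testing.assert_array_equal(code.support, order)
        np.testing.assert_allclose(code.coefficients[order], inner[order], atol=1e-12)

    def test_full_sparsity_equals_least_squares(self, rng):
        D = rng.standard_normal((6, 10))
        D /= np.linalg.norm(D, axis=0)
        x = rng.standard_normal(6)
        code = omp_code(x, D, sparsity=6)
        ls_resid = np.linalg.norm(x - D @ np.linalg.lstsq(D, x, rcond=None)[0])
        assert np.isclose(code.residual_norm, ls_resid, atol=1e-9)

    def test_sparsity_one_matches_exhaustive_search(self, rng):
        D = rng.standard_normal((7, 25))
        D /= np.linalg.norm(D, axis=0)
        for _ in range(10):
            x = rng.standard_normal(7)
            code = omp_code(x, D, sparsity=1)
            # brute force over atoms: best single-atom approximation
            resids = [
                np.linalg.norm(x - D[:, j] * (D[:, j] @ x)) for j in range(25)
            ]
            assert code.support[0] == int(np.argmin(resids))

    def test_zero_vector_empty_support(self, rng):
        D = rng.standard_normal((5, 8))
        D /= np.linalg.norm(D, axis=0)
        code = omp_code(np.zeros(5), D, sparsity=3)
        assert code.support.size == 0
        assert code.residual_norm == 0.0

    def test_epsilon_stopping(self, rng):
        D = rng.standard_normal((8, 20))
        D /= np.linalg.norm(D, axis=0)
        x = D[:, 4] * 3.0
        code = omp_code(x, D, sparsity=8, epsilon=1e-6)
        assert code.support.size == 1
        assert code.residual_norm <= 1e-6

    def test_agrees_with_sklearn(self, rng):
        from sklearn.linear_model import orthogonal_mp

        D = rng.standard_normal((20, 60))
        D /= np.linalg.norm(D, axis=0)
        X = rng.standard_normal((20, 40))
        S, C, _ = omp_batch(D, X, sparsity=3)
        Q = orthogonal_mp(D, X, n_nonzero_coefs=3)
        Qm = np.zeros_like(Q)
        for i in range(X.shape[1]):
            for s in range(3):
                if S[i, s] >= 0:
                    Qm[S[i, s], i] = C[i, s]
        np.testing.assert_allclose(Qm, Q, atol=1e-10)


class TestKSVD:
    def test_recovery_and_monotonicity(self):
        # standard synthetic recovery: 3-sparse data on a random dictionary
        rng = np.random.default_rng(0)
        m, dim, N, k = 32, 20, 2000, 3
        A0 = rng.standard_normal((dim, m))
        A0 /= np.linalg.norm(A0, axis=0)
        idx = np.stack([rng.choice(m, k, replace=False) for _ in range(N)])
        coef = rng.standard_normal((N, k)) + np.sign(rng.standard_normal((N, k)))
        X = np.zeros((dim, N))
        for s in range(k):
            X += A0[:, idx[:, s]] * coef[:, s]
        A, Q, info = ksvd_train(X, m, sparsity=3, iterations=60, seed=1)
        errs = np.array(info["errors"])
        assert np.all(np.diff(errs) <= 1e-9 * errs[0])
        matches = (np.abs(A.T @ A0).max(axis=0) > 0.99).sum()
        assert matches >= 0.9 * m
        assert errs[-1] < 0.1 * errs[0]
        np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0, atol=1e-9)

    def test_zero_iterations_initializes_from_data(self, rng):
        X = rng.standard_normal((10, 50))
        A, Q, info = ksvd_train(X, 8, sparsity=2, iterations=0, seed=3)
        assert info["errors"] == []
        # every atom is a normalized training vector
        Xn = X / np.linalg.norm(X, axis=0)
        for j in range(8):
            assert np.min(np.linalg.norm(Xn - A[:, [j]], axis=0)) < 1e-12

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((10, 80))
        A1, _, _ = ksvd_train(X, 12, iterations=3, seed=9)
        A2, _, _ = ksvd_train(X, 12, iterations=3, seed=9)
        np.testing.assert_array_equal(A1, A2)

    def test_dictionary_larger_than_data_rejected(self, rng):
        with pytest.raises(ValueError):
            ksvd_train(rng.standard_normal((5, 10)), m=20)


class TestHRDictionarySolve:
    def test_exact_consistency(self, rng):
        A = rng.standard_normal((15, 8))
        Q = rng.standard_normal((8, 40))
        np.testing.assert_allclose(solve_hr_dictionary(A @ Q, Q), A, atol=1e-9)

    def test_normal_equation_orthogonality(self, rng):
        P = rng.standard_normal((20, 30))
        Q = rng.standard_normal((8, 30))
        Ah = solve_hr_dictionary(P, Q)
        np.testing.assert_allclose((P - Ah @ Q) @ Q.T, 0.0, atol=1e-9)

    def test_matches_brute_force_least_squares(self, rng):
        # independent oracle: row-by-row lstsq on a random 20 x 30 instance
        P = rng.standard_normal((20, 30))
        Q = rng.standard_normal((8, 30))
        Ah = solve_hr_dictionary(P, Q)
        oracle = np.stack(
            [np.linalg.lstsq(Q.T, P[r], rcond=None)[0] for r in range(20)]
        )
        np.testing.assert_allclose(Ah, oracle, atol=1e-8)

    def test_rank_deficient_ridge_warns(self, rng, caplog):
        Q = np.zeros((6, 30))
        Q[:2] = rng.standard_normal((2, 30))  # rank 2
        P = rng.standard_normal((4, 30))
        import logging

        with caplog.at_level(logging.WARNING, logger="mesr.sparse_model"):
            Ah = solve_hr_dictionary(P, Q)
        assert Ah.shape == (4, 6)
        assert any("ridge" in r.message for r in caplog.records)


class TestDetailChainAndTraining:
    def test_zero_detail_propagates(self):
        img = np.full((32, 32), 5.0)
        det = build_mesr_detail_image(img, img)
        np.testing.assert_allclose(det.guided_detail, 0.0, atol=1e-9)
        np.testing.assert_allclose(det.raw_detail, 0.0, atol=1e-12)

    def test_stage_composition_matches_operators(self):
        from mesr.enhancement import bilateral_filter, bpdhe

        y_h = _smooth_test_image(48, seed=1)
        y_l = _smooth_test_image(48, seed=2)
        det = build_mesr_detail_image(y_h, y_l)
        span = y_h.max() - y_h.min()
        y_he = bpdhe(bilateral_filter(y_h, 3.0, 0.1 * span))
        np.testing.assert_allclose(det.y_h_enhanced, y_he, atol=1e-12)
        np.testing.assert_allclose(det.enhanced_detail, y_he - y_l, atol=1e-12)
        np.testing.assert_allclose(det.raw_detail, y_h - y_l, atol=1e-12)

    def test_guided_detail_keeps_edge_position(self):
        # a clean step edge in the raw detail stays put through the chain
        y_l = np.zeros((40, 40))
        y_h = np.zeros((40, 40))
        y_h[:, 20:] = 1.0
        det = build_mesr_detail_image(y_h, y_l)
        g = det.guided_detail
        left = g[:, :12].mean()
        right = g[:, -12:].mean()
        assert right - left > 0.25 * (y_h.max() - y_h.min())

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_mesr_detail_image(np.zeros((8, 8)), np.zeros((10, 10)))

    def test_training_is_deterministic_and_variant_consistent(self):
        y_h = _smooth_test_image(64)
        spec = DegradationSpec()
        z_l = degrade(y_h, spec)
        cfg = PatchConfig(block_size=9, max_train_patches=2000, seed=0)
        kw = dict(patch_cfg=cfg, m=48, ksvd_iterations=3, seed=0, degradation=spec)
        raw1, enh1 = train_dictionary_variants(y_h, z_l, **kw)
        raw2 = mesr_train(y_h, z_l, use_detail_chain=False, **kw)
        enh2 = mesr_train(y_h, z_l, use_detail_chain=True, **kw)
        np.testing.assert_array_equal(raw1.A_h, raw2.A_h)
        np.testing.assert_array_equal(enh1.A_h, enh2.A_h)
        np.testing.assert_array_equal(raw1.A_l, enh1.A_l)
        assert raw1.n_atoms == 48
        np.testing.assert_allclose(np.linalg.norm(raw1.A_l, axis=0), 1.0, atol=1e-9)

    def test_too_few_patches_for_dictionary(self):
        y_h = _smooth_test_image(32)
        z_l = degrade(y_h, DegradationSpec())
        with pytest.raises(ValueError):
            mesr_train(y_h, z_l, m=5000)


class TestSRReconstruct:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_pair():
        y_h = _smooth_test_image(64)
        spec = DegradationSpec()
        z_l = degrade(y_h, spec)
        cfg = PatchConfig(block_size=9, max_train_patches=2000, seed=0)
        return train_dictionary_variants(
            y_h, z_l, cfg, m=48, ksvd_iterations=3, seed=0, degradation=spec
        )[1], y_h, z_l, spec

    def test_zero_dictionary_returns_upscaled_input(self, small_pair):
        pair, _, z_l, spec = small_pair
        zero = dataclasses.replace(pair, A_h=np.zeros_like(pair.A_h))
        out = sr_reconstruct(z_l, zero, degradation=spec)
        np.testing.assert_array_equal(out, upscale(z_l, spec))

    def test_self_reconstruction_beats_plain_upscale(self, small_pair):
        from mesr.metrics import psnr
        from mesr.phantoms import to_display_range

        pair, y_h, z_l, spec = small_pair
        out = sr_reconstruct(z_l, pair, degradation=spec)
        up = upscale(z_l, spec)
        ref = to_display_range(y_h)
        lo, hi = y_h.min(), y_h.max()
        assert psnr(ref, to_display_range(out, lo, hi)) >= psnr(
            ref, to_display_range(up, lo, hi)
        )

    def test_output_side_is_input_times_scale(self, small_pair):
        pair, *_ = small_pair
        test = _smooth_test_image(255, seed=5)
        out = sr_reconstruct(test, pair)
        assert out.shape == (510, 510)

    def test_dictionary_pair_roundtrips_through_npz(self, small_pair, tmp_path):
        pair, _, z_l, spec = small_pair
        path = tmp_path / "pair.npz"
        pair.save_npz(path)
        loaded = DictionaryPair.load_npz(path)
        np.testing.assert_array_equal(loaded.A_h, pair.A_h)
        out1 = sr_reconstruct(z_l, pair, degradation=spec)
        out2 = sr_reconstruct(z_l, loaded, degradation=spec)
        np.testing.assert_allclose(out1, out2, atol=1e-12)
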