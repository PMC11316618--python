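"""Spectral model: dissimilarity matrix, double centering, eigenpairs,
trigonometric eigenfunction fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import archdiag as ad
from archdiag.errors import DimensionError, FitFailureError, ParameterError


class TestDissimilarityMatrix:
    def test_diagonal_is_zero_and_matrix_symmetric(self):
        m = ad.dissimilarity_matrix(17)
        np.testing.assert_array_equal(np.diag(m.X), 0.0)
        np.testing.assert_array_equal(m.X, m.X.T)

    def test_corner_entry_matches_closed_form(self):
        n = 23
        m = ad.dissimilarity_matrix(n)
        assert m.X[0, n - 1] == pytest.approx(1.0 - np.exp(-(n - 1) / n))

    def test_entries_increase_with_separation_and_stay_in_range(self):
        m = ad.dissimilarity_matrix(40)
        row = m.X[0]
        assert np.all(np.diff(row) > 0)
        assert row.max() <= 1.0 - np.exp(-(40 - 1) / 40) + 1e-15

    def test_n_below_two_rejected(self):
        with pytest.raises(ParameterError):
            ad.dissimilarity_matrix(1)


class TestCenteredKernel:
    def test_three_by_three_against_explicit_arithmetic(self):
        # independent oracle: explicit loops for H, X and the product
        n = 3
        X = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                X[i, j] = 1.0 - np.exp(-abs(i - j) / n)
        H = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                H[i, j] = (1.0 if i == j else 0.0) - 1.0 / n
        expected = -0.5 * H.dot(X).dot(H)
        K = ad.centered_kernel(ad.dissimilarity_matrix(n))
        np.testing.assert_allclose(K, expected, atol=1e-15)

    def test_kernel_annihilates_constants_and_is_symmetric(self):
        K = ad.centered_kernel(ad.dissimilarity_matrix(30))
        np.testing.assert_allclose(K @ np.ones(30), 0.0, atol=1e-12)
        np.testing.assert_allclose(K, K.T, atol=1e-15)


class TestOperatorSpectrum:
    def test_eigenvectors_orthonormal_and_eigenvalues_descending(self):
        K = ad.centered_kernel(ad.dissimilarity_matrix(60))
        spec = ad.operator_spectrum(K, k=5)
        V = spec.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(5), atol=1e-10)
        assert np.all(np.diff(spec.eigenvalues) <= 1e-12)

    def test_sign_canonicalization_first_nonzero_positive(self):
        K = ad.centered_kernel(ad.dissimilarity_matrix(60))
        V = ad.operator_spectrum(K, k=4).eigenvectors
        for j in range(4):
            nz = np.nonzero(np.abs(V[:, j]) > 1e-12)[0]
            assert V[nz[0], j] > 0

    def test_first_eigenvector_antisymmetric_second_symmetric(self):
        K = ad.centered_kernel(ad.dissimilarity_matrix(200))
        V = ad.operator_spectrum(K, k=2).eigenvectors
        np.testing.assert_allclose(V[:, 0], -V[::-1, 0], atol=1e-8)
        np.testing.assert_allclose(V[:, 1], V[::-1, 1], atol=1e-8)

    def test_normalized_eigenvalues_converge_with_grid_size(self):
        lam = ad.eigenvalue_convergence(sizes=(100, 200, 400, 800), k=2)
        diffs = np.abs(np.diff(lam, axis=0))
        assert np.all(np.diff(diffs, axis=0) < 0)


class TestTrigEigenfunction:
    def test_midpoint_values(self):
        assert ad.trig_eigenfunction(0.5, 1) == pytest.approx(0.0)
        assert ad.trig_eigenfunction(0.5, 2) == pytest.approx(1.0)

    def test_left_endpoint_of_sine_form(self):
        assert ad.trig_eigenfunction(0.0, 1) == pytest.approx(-np.sin(ad.SIN_FREQUENCY / 2))

    def test_invalid_branch_rejected(self):
        with pytest.raises(ParameterError):
            ad.trig_eigenfunction(0.5, 3)

    def test_domain_checked(self):
        with pytest.raises(ParameterError):
            ad.trig_eigenfunction(1.5, 1)


class TestModelEmbedding:
    def test_midpoint_maps_to_zero_lambda2(self):
        emb = ad.model_embedding(101)  # x = 50/101 is not exactly 1/2
        x = np.arange(101) / 101
        mid = int(np.argmin(np.abs(x - 0.5)))
        assert emb.points[mid, 0] == pytest.approx(0.0, abs=2e-3)
        assert emb.points[mid, 1] == pytest.approx(ad.LAMBDA_2, abs=2e-3)

    def test_first_coordinate_antisymmetric_on_the_grid(self):
        emb = ad.model_embedding(60)
        f1 = emb.points[:, 0]
        # grid x_i = i/n is asymmetric about 1/2 by 1/n; pairing i with
        # n-1-i leaves a residual bounded by lambda1 * a1 / n
        pair_sums = f1 + f1[::-1]
        bound = ad.LAMBDA_1 * ad.SIN_FREQUENCY / 60 * 1.5
        assert np.max(np.abs(pair_sums)) < bound

    def test_traces_a_u_shape(self):
        emb = ad.model_embedding(200)
        second = emb.points[:, 1]
        assert abs(second[0] - second[-1]) < 0.005
        assert abs(second[100] - second[0]) > 0.02  # midpoint differs


class TestFitFrequency:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(min_value=0.7, max_value=12.0),
           c=st.floats(min_value=0.2, max_value=5.0),
           form=st.sampled_from(["sin", "cos"]))
    def test_recovers_its_own_generating_family(self, a, c, form):
        x = np.arange(200) / 199
        trig = np.sin if form == "sin" else np.cos
        v = c * trig(a * (x - 0.5))
        if np.ptp(v) < 1e-6:
            return  # near-constant sample of the family: frequency unidentifiable
        fit = ad.fit_frequency(v, form)
        assert fit.r2 > 1.0 - 1e-6
        assert fit.a == pytest.approx(a, abs=0.01)

    def test_exact_model_frequency_recovered(self):
        x = np.arange(500) / 499
        v = np.sin(ad.SIN_FREQUENCY * (x - 0.5))
        fit = ad.fit_frequency(v, "sin")
        assert fit.a == pytest.approx(ad.SIN_FREQUENCY, abs=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_vector_fails(self):
        with pytest.raises(FitFailureError):
            ad.fit_frequency(np.ones(50), "sin")

    def test_too_short_vector_rejected(self):
        with pytest.raises(DimensionError):
            ad.fit_frequency(np.arange(5.0), "sin")


class TestSpectralConsistency:
    def test_eigenvalue_frequency_relation_at_moderate_n(self):
        # for the exponential kernel the integral operator satisfies
        # lambda = 1/(1 + a^2); both top eigenpairs must respect it
        spec = ad.fit_spectral_model(500)
        assert spec.lambda1 == pytest.approx(1.0 / (1.0 + spec.a1 ** 2), rel=0.01)
        assert spec.lambda2 == pytest.approx(1.0 / (1.0 + spec.a2 ** 2), rel=0.01)

    def test_model_embedding_passes_the_horseshoe_test(self):
        # the closed-form arch is its own generating family; the only
        # slack is the x=i/n vs x=i/(n-1) grid mismatch
        emb = ad.model_embedding(100)
        e = ad.Embedding(scores=emb.points,
                         component_variances=np.array([ad.LAMBDA_1, ad.LAMBDA_2]))
        hs = ad.horseshoe_score(e, np.arange(100))
        assert hs.is_horseshoe
        assert hs.r2_pc1_sin > 0.99
        assert hs.r2_pc2_cos > 0.99

    def test_exact_trig_scores_fit_perfectly_on_the_rank_grid(self):
        # same family evaluated on the fitter's own x = i/(n-1) grid
        x = np.arange(100) / 99
        scores = np.column_stack([
            ad.LAMBDA_1 * np.sin(ad.SIN_FREQUENCY * (x - 0.5)),
            ad.LAMBDA_2 * np.cos(ad.COS_FREQUENCY * (x - 0.5)),
        ])
        e = ad.Embedding(scores=scores,
                         component_variances=np.array([ad.LAMBDA_1, ad.LAMBDA_2]))
        hs = ad.horseshoe_score(e, np.arange(100))
        assert hs.is_horseshoe
        assert hs.r2_pc1_sin == pytest.approx(1.0, abs=1e-9)
        assert hs.r2_pc2_cos == pytest.approx(1.0, abs=1e-9)
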