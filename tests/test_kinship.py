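import numpy as np
import pytest

import shrinkgrm as sg
from shrinkgrm.kinship import shrinkage_intensity_raw

from conftest import random_genotypes


def _panel(X):
    X = np.asarray(X, dtype=float)
    return sg.GenotypeMatrix(X, [f"l{i}" for i in range(X.shape[0])],
                             [f"m{j}" for j in range(X.shape[1])])


class TestCentering:
    def test_symmetric_two_line_case(self):
        C = sg.center_genotypes(_panel([[0, 2], [2, 0]]))
        assert C.p == pytest.approx([0.5, 0.5])
        assert C.W == pytest.approx(np.array([[-1.0, 1.0], [1.0, -1.0]]))
        assert C.denom == pytest.approx(1.0)

    def test_constant_columns_centered_away(self):
        C = sg.center_genotypes(_panel([[1, 1], [1, 1]]))
        assert C.p == pytest.approx([0.5, 0.5])
        assert np.all(C.W == 0)

    def test_monomorphic_column_contributes_nothing(self):
        C = sg.center_genotypes(_panel([[2, 0], [2, 2]]))
        assert C.p[0] == 1.0
        assert np.all(C.W[:, 0] == 0)
        assert C.denom == pytest.approx(2 * 0.5 * 0.5)

    def test_columns_sum_to_zero(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 15, 40))
        assert np.abs(C.W.sum(axis=0)).max() < 1e-9 * 15

    def test_missing_data_rejected(self):
        X = np.array([[0.0, np.nan], [2.0, 1.0]])
        G = sg.GenotypeMatrix(X, ["a", "b"], ["m1", "m2"])
        with pytest.raises(ValueError, match="impute"):
            sg.center_genotypes(G)


class TestSampleCovariance:
    def test_zero_row_means_case(self):
        C = sg.center_genotypes(_panel([[0, 2], [2, 0]]))
        assert sg.sample_covariance(C) == pytest.approx(np.array([[1.0, -1.0], [-1.0, 1.0]]))

    def test_duplicate_rows_duplicate_entries(self, rng):
        X = rng.integers(0, 3, size=(4, 30)).astype(float)
        X[3] = X[0]
        S = sg.sample_covariance(sg.center_genotypes(_panel(X)))
        assert S[3] == pytest.approx(S[0])
        assert S[:, 3] == pytest.approx(S[:, 0])

    def test_null_case(self):
        S = sg.sample_covariance(sg.center_genotypes(_panel([[1, 1], [1, 1]])))
        assert np.all(S == 0)


class TestShrinkageIntensity:
    def test_no_noise_across_columns_gives_zero(self):
        d = shrinkage_intensity_raw(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert d.numerator == pytest.approx(0.0, abs=1e-15)
        assert d.delta == 0.0

    def test_hand_computed_example(self):
        # n=2, m=3: S = [[2/3,1/3],[1/3,2/3]], denominator 2/9,
        # direct-loop numerator sum 8/3 -> delta_raw = 4/3 -> clamped to 1
        d = shrinkage_intensity_raw(np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]]))
        assert d.S == pytest.approx(np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]]))
        assert d.denominator == pytest.approx(2 / 9)
        assert d.delta_raw == pytest.approx(4 / 3)
        assert d.delta == 1.0

    def test_spherical_covariance_gives_zero_by_convention(self):
        # orthogonal rows with equal norms: S proportional to I
        Z = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        d = shrinkage_intensity_raw(Z)
        assert d.denominator == pytest.approx(0.0, abs=1e-15)
        assert d.delta == 0.0

    def test_direct_loop_oracle_matches_gamma_shortcut(self, rng):
        # sum_k ||Z.k Z.k' - S||^2  computed naively vs m*sum(Gamma - S^2)
        for _ in range(10):
            n = int(rng.integers(2, 21))
            m = int(rng.integers(2, 51))
            Z = rng.standard_normal((n, m))
            S = Z @ Z.T / m
            direct = sum(np.sum((np.outer(Z[:, k], Z[:, k]) - S) ** 2)
                         for k in range(m))
            d = shrinkage_intensity_raw(Z)
            assert d.numerator * m * m == pytest.approx(direct, rel=1e-10)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            shrinkage_intensity_raw(np.ones((3, 1)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            shrinkage_intensity_raw(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestKinshipPlain:
    def test_two_diverged_inbred_lines(self):
        K = sg.kinship_plain(sg.center_genotypes(_panel([[2, 2], [0, 0]])))
        assert K.A == pytest.approx(np.array([[2.0, -2.0], [-2.0, 2.0]]))
        assert K.f == pytest.approx(1.0)

    def test_universal_heterozygosity(self):
        K = sg.kinship_plain(sg.center_genotypes(_panel([[1, 1], [1, 1]])))
        assert np.all(K.A == 0)
        assert K.f == pytest.approx(-1.0)

    def test_row_sums_vanish(self, rng):
        K = sg.kinship_plain(sg.center_genotypes(random_genotypes(rng, 12, 25)))
        assert np.abs(K.A.sum(axis=1)).max() < 1e-10
        # centering also forces a ~0 eigenvalue
        lam = np.linalg.eigvalsh(K.A)
        assert np.min(np.abs(lam)) < 1e-8 * lam.max()

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            sg.kinship_plain(sg.center_genotypes(_panel([[2, 2], [2, 2]])))


class TestKinshipShrunk:
    def test_zero_delta_equals_plain(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 10, 30))
        A0 = sg.kinship_shrunk(C, delta=0.0).A
        Ap = sg.kinship_plain(C).A
        assert A0 == pytest.approx(Ap, rel=1e-12, abs=1e-12)

    def test_full_shrinkage_kills_off_diagonal_covariance(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 8, 40))
        S = sg.sample_covariance(C)
        A1 = sg.kinship_shrunk(C, delta=1.0).A
        expected = (np.mean(np.diag(S)) * np.eye(8)
                    + np.outer(C.row_means, C.row_means))
        expected /= 2 * C.denom / (2 * C.n_markers)
        assert A1 == pytest.approx(expected, rel=1e-10)

    def test_trace_invariant_in_delta(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 10, 30))
        traces = [np.trace(sg.kinship_shrunk(C, delta=d).A)
                  for d in (0, 0.25, 0.5, 0.75, 1.0)]
        assert np.ptp(traces) < 1e-12 * abs(traces[0])

    def test_positive_semidefinite_for_all_delta(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 10, 30))
        for d in (0, 0.25, 0.5, 0.75, 1.0):
            lam = np.linalg.eigvalsh(sg.kinship_shrunk(C, delta=d).A)
            assert lam.min() >= -1e-8 * lam.max()

    def test_auto_records_intensity(self, unstructured_panel):
        C = sg.center_genotypes(unstructured_panel)
        K = sg.kinship_shrunk(C, delta="auto")
        assert K.method == "shrunk"
        assert K.delta == pytest.approx(sg.shrinkage_intensity(C).delta)

    def test_invalid_delta_rejected(self, rng):
        C = sg.center_genotypes(random_genotypes(rng, 5, 10))
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            sg.kinship_shrunk(C, delta=1.5)


class TestHeuristicAndCV:
    def test_heuristic_values(self):
        assert sg.heuristic_intensity(100, 100, 1.0) == pytest.approx(1.0)
        assert sg.heuristic_intensity(100, 200, 1.0) == pytest.approx(0.5)
        # maize-like profile: n=274, 384 markers, CV=1.3 -> ~0.42
        assert sg.heuristic_intensity(274, 384, 1.3) == pytest.approx(0.42, abs=0.01)

    def test_heuristic_rejects_zero_cv(self):
        with pytest.raises(ValueError):
            sg.heuristic_intensity(10, 10, 0.0)

    def test_cv_equal_eigenvalues(self):
        assert sg.eigenvalue_cv(3.0 * np.eye(5)) == pytest.approx(0.0)

    def test_cv_two_point_spectrum(self):
        assert sg.eigenvalue_cv(np.diag([1.0, 3.0])) == pytest.approx(0.5)

    def test_cv_rejects_non_positive_mean(self):
        with pytest.raises(ValueError, match="positive"):
            sg.eigenvalue_cv(np.diag([1.0, -3.0]))

    def test_structured_population_has_higher_cv(self, unstructured_panel,
                                                 structured_panel):
        cv_u = sg.eigenvalue_cv(
            sg.sample_covariance(sg.center_genotypes(unstructured_panel)))
        cv_s = sg.eigenvalue_cv(
            sg.sample_covariance(sg.center_genotypes(structured_panel)))
        assert cv_s > cv_u


class TestInbreeding:
    def test_fully_homozygous_locus(self):
        s = sg.inbreeding_summary(_panel([[0, 0], [2, 2]]))
        assert s.f_k == pytest.approx([1.0, 1.0])
        assert s.f == pytest.approx(1.0)

    def test_universal_heterozygosity_locus(self):
        s = sg.inbreeding_summary(_panel([[1, 0], [1, 2]]))
        assert s.f_k[0] == pytest.approx(-1.0)

    def test_half_frequency_reduces_to_homozygous_fraction(self):
        # all p_k = 1/2: phi_i = 2*psi - 1 with psi the homozygous fraction
        X = [[0, 2, 1, 1], [2, 0, 1, 1], [1, 1, 0, 2], [1, 1, 2, 0]]
        s = sg.inbreeding_summary(_panel(X))
        psi = np.mean(np.array(X) != 1, axis=1)
        assert s.phi_i == pytest.approx(2 * psi - 1)

    @pytest.mark.parametrize("impute_fraction", [0.0, 0.25])
    def test_locus_and_individual_averages_agree(self, rng, impute_fraction):
        # f = sum_k beta_k f_k = n^-1 sum_i phi_i = <A_ii> - 1, also for
        # real-valued imputed dosages
        G = random_genotypes(rng, 15, 40, impute_fraction=impute_fraction)
        s = sg.inbreeding_summary(G)
        assert s.beta_k.sum() == pytest.approx(1.0, abs=1e-12)
        assert s.f == pytest.approx(np.mean(s.phi_i), abs=1e-10)
        K = sg.kinship_plain(sg.center_genotypes(G))
        assert s.f == pytest.approx(K.f, abs=1e-10)

    def test_monomorphic_locus_gets_zero_weight(self):
        s = sg.inbreeding_summary(_panel([[2, 0], [2, 2]]))
        assert s.f_k[0] == 0.0 and s.beta_k[0] == 0.0

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            sg.inbreeding_summary(_panel([[2, 2], [2, 2]]))


class TestIBS:
    def test_identical_and_opposite_homozygotes(self):
        B = sg.ibs_matrix(_panel([[2, 0], [2, 0], [0, 2]]))
        assert B[0, 1] == pytest.approx(1.0)
        assert B[0, 2] == pytest.approx(0.0)

    def test_matches_allele_sharing_count_on_homozygous_panels(self, rng):
        X = 2.0 * rng.integers(0, 2, size=(10, 40))
        B = sg.ibs_matrix(_panel(X))
        counts = (X[:, None, :] == X[None, :, :]).mean(axis=2)
        assert B == pytest.approx(counts, abs=1e-12)
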