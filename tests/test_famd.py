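import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from fsindex.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
)
from fsindex.famd import (
    FadmParams,
    FactorModel,
    MixedDesign,
    Retention,
    encode_mixed,
    fadm_weight,
    famd_decompose,
    first_eigenvalue,
    transform_score,
)


def quantitative_design(X: np.ndarray) -> MixedDesign:
    """Wrap a raw numeric matrix as a standardized quantitative-only design."""
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])
    return encode_mixed(df, list(df.columns), [])


def oracle_factor_scores(X: np.ndarray) -> np.ndarray:
    """Independent route: manual standardization, eigendecomposition-based
    first eigenvalue, scipy SVD, explicit mass scaling."""
    n = X.shape[0]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    lam1 = np.max(np.linalg.eigvalsh(Z.T @ Z / n))
    G = Z / lam1
    U, s, Vt = scipy.linalg.svd(G, full_matrices=False)
    return np.sqrt(n) * U * s


def align_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Flip B's column signs to match A (SVD sign indeterminacy)."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1.0
    return B * signs


class TestEncodeMixed:
    def make_frame(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "c1": rng.choice(["a", "b", "c"], size=n),
                "c2": rng.choice(["u", "v"], size=n),
            }
        )

    def test_level_counting(self):
        df = self.make_frame()
        design = encode_mixed(df, ["x1", "x2"], ["c1", "c2"])
        assert design.m == 5  # 3 + 2 observed levels
        assert design.p1 == 2

    def test_onehot_rows_sum_to_variable_count_before_centering(self):
        df = self.make_frame()
        design = encode_mixed(df, [], ["c1", "c2"])
        # undo the centering: add back each column's mean
        means = np.array(
            [
                (df[name.split("=")[0]] == name.split("=")[1]).mean()
                for name in design.indicator_names
            ]
        )
        raw = design.indicator + means
        np.testing.assert_allclose(raw.sum(axis=1), 2.0, atol=1e-12)

    def test_quantitative_standardized(self):
        design = encode_mixed(self.make_frame(), ["x1"], [])
        col = design.quantitative[:, 0]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std() == pytest.approx(1.0)

    def test_constant_column_dropped_and_logged(self):
        df = self.make_frame()
        df["flat"] = 1.0
        design = encode_mixed(df, ["x1", "flat"], [])
        assert design.quantitative_names == ["x1"]
        assert any("flat" in msg for msg in design.dropped)

    def test_single_level_variable_dropped_and_logged(self):
        df = self.make_frame()
        df["onelevel"] = "same"
        design = encode_mixed(df, [], ["c1", "onelevel"])
        assert all(not name.startswith("onelevel") for name in design.indicator_names)
        assert any("onelevel" in msg for msg in design.dropped)

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            encode_mixed(self.make_frame(n=2), ["x1"], [])

    def test_all_constant_degenerate(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": ["x", "x", "x"]})
        with pytest.raises(DegenerateInputError):
            encode_mixed(df, ["a"], ["b"])


class TestFirstEigenvalue:
    def test_single_standardized_column(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        z = (col - col.mean()) / col.std()
        assert first_eigenvalue(z[:, None]) == pytest.approx(1.0)

    def test_orthogonal_equal_norm_columns(self):
        # 4x2 with orthogonal, equal-norm columns: top eigenvalue equals
        # either column's mean square (brute-force eigendecomposition oracle)
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]) * 3.0
        expected = np.max(np.linalg.eigvalsh(X.T @ X / 4))
        assert first_eigenvalue(X) == pytest.approx(expected, rel=1e-12)
        assert first_eigenvalue(X) == pytest.approx(np.mean(X[:, 0] ** 2), rel=1e-12)

    def test_column_permutation_invariant(self, rng):
        X = rng.normal(size=(10, 4))
        assert first_eigenvalue(X[:, ::-1]) == pytest.approx(
            first_eigenvalue(X), rel=1e-12
        )

    def test_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            first_eigenvalue(np.zeros((5, 2)))


class TestFamdDecompose:
    def test_quantitative_only_matches_svd_oracle(self):
        rng = np.random.default_rng(123)
        X = rng.normal(size=(6, 3))
        model = famd_decompose(quantitative_design(X))
        expected = oracle_factor_scores(X)
        aligned = align_columns(model.factor_scores, expected)
        np.testing.assert_allclose(model.factor_scores, aligned, atol=1e-8)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(9, 4))
        design = quantitative_design(X)
        model = famd_decompose(design)
        G = design.quantitative / model.lambda1_quant
        recon = model.left_vectors * model.singular_values @ model.right_vectors.T
        np.testing.assert_allclose(recon, G, atol=1e-8)

    def test_contributions_sum_to_one(self, small_campaign):
        design = encode_mixed(
            small_campaign.records,
            [f"aux_q{j:02d}" for j in range(1, 15)],
            ["city", "channel"] + [f"aux_c{j:02d}" for j in range(1, 10)],
        )
        model = famd_decompose(design)
        assert model.variance_contributions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(model.variance_contributions >= 0)

    def test_orthonormal_vectors_and_sorted_singular_values(self, rng):
        X = rng.normal(size=(12, 5))
        model = famd_decompose(quantitative_design(X))
        U, V, s = model.left_vectors, model.right_vectors, model.singular_values
        np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        assert np.all(np.diff(s) <= 1e-12) and np.all(s >= 0)

    def test_mass_matrix_is_uniform(self, rng):
        X = rng.normal(size=(8, 3))
        model = famd_decompose(quantitative_design(X))
        np.testing.assert_allclose(model.mass, np.full(8, 1 / 8))

    def test_matches_plain_pca_up_to_block_scaling(self, rng):
        # quantitative-only limit: scores equal sqrt(n)/lambda1 times the
        # PCA projection of the standardized matrix
        X = rng.normal(size=(8, 4))
        design = quantitative_design(X)
        model = famd_decompose(design)
        Z = design.quantitative
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        pca_scores = U * s  # PCA projections of Z
        expected = np.sqrt(8) / model.lambda1_quant * pca_scores
        aligned = align_columns(model.factor_scores, expected)
        np.testing.assert_allclose(model.factor_scores, aligned, atol=1e-8)


class TestRetention:
    def make_model(self, contribs, n=10):
        contribs = np.asarray(contribs, dtype=float)
        s = np.sqrt(contribs)
        F = np.zeros((n, len(s)))
        return FactorModel(None, None, np.zeros((n, len(s))), s, np.zeros((len(s), len(s))),
                           F, contribs, 1, n)

    def test_cumulative_variance_smallest_r(self):
        design_contribs = [0.5, 0.25, 0.15, 0.1]
        s = np.sqrt(np.array(design_contribs))
        from fsindex.famd import _retained

        assert _retained(s, np.array(design_contribs), 10, Retention("cumulative_variance", 0.80)) == 3
        assert _retained(s, np.array(design_contribs), 10, Retention("cumulative_variance", 0.75)) == 2
        assert _retained(s, np.array(design_contribs), 10, Retention("cumulative_variance", 1.0)) == 4

    def test_kaiser_rule(self):
        from fsindex.famd import _retained

        s = np.array([4.0, 2.0, 1.0])  # eigenvalues s^2/n with n=4: 4, 1, 0.25
        contribs = s**2 / np.sum(s**2)
        assert _retained(s, contribs, 4, Retention("kaiser", 0.0)) == 1

    def test_fixed_rule_capped(self):
        from fsindex.famd import _retained

        s = np.ones(3)
        contribs = np.full(3, 1 / 3)
        assert _retained(s, contribs, 5, Retention("fixed", 2)) == 2
        assert _retained(s, contribs, 5, Retention("fixed", 9)) == 3

    def test_parse(self):
        assert Retention.parse("cumulative:0.9") == Retention("cumulative_variance", 0.9)
        assert Retention.parse("kaiser").rule == "kaiser"
        assert Retention.parse("fixed:3") == Retention("fixed", 3)
        with pytest.raises(InvalidParameterError):
            Retention.parse("bogus")


class TestTransformScore:
    def test_value_at_zero(self):
        assert transform_score(0.0, 100.0) == pytest.approx(50.5)
        assert transform_score(0.0, 10.0) == pytest.approx(5.5)

    @pytest.mark.parametrize("k", [10.0, 100.0, 1000.0])
    def test_monotone_and_bounded(self, k):
        grid = np.linspace(-20, 20, 2001)
        f = transform_score(grid, k)
        assert np.all(np.diff(f) > 0)
        assert np.all(f > 1.0) and np.all(f < k)

    def test_limits(self):
        assert transform_score(50.0, 100.0) == pytest.approx(100.0, abs=1e-12)
        assert transform_score(-50.0, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_k(self):
        with pytest.raises(InvalidParameterError):
            transform_score(0.0, 1.0)

    def test_decreasing_orientation_mirrors(self):
        grid = np.linspace(-5, 5, 101)
        inc = transform_score(grid, 100.0, "increasing")
        dec = transform_score(grid, 100.0, "decreasing")
        np.testing.assert_allclose(inc, dec[::-1], atol=1e-12)
        assert np.all(np.diff(dec) < 0)

    def test_unknown_orientation(self):
        with pytest.raises(InvalidParameterError):
            transform_score(0.0, 100.0, "sideways")


def model_from_scores(F: np.ndarray, contribs: np.ndarray, r: int) -> FactorModel:
    n, p = F.shape
    return FactorModel(None, None, np.zeros((n, p)), np.zeros(p), np.zeros((p, p)),
                       F, contribs, r, n)


class TestFadmWeight:
    def test_single_factor_equals_transformed_score(self, rng):
        F = rng.normal(size=(7, 3))
        model = model_from_scores(F, np.array([0.7, 0.2, 0.1]), 1)
        w = fadm_weight(model, FadmParams(k=100.0))
        np.testing.assert_allclose(w, transform_score(F[:, 0], 100.0))

    def test_constant_transformed_scores(self):
        # all factor scores zero -> every transformed score is (k+1)/2
        F = np.zeros((5, 4))
        model = model_from_scores(F, np.array([0.4, 0.3, 0.2, 0.1]), 3)
        w = fadm_weight(model, FadmParams(k=100.0))
        np.testing.assert_allclose(w, 50.5)

    def test_hand_weighted_mean(self):
        # transformed scores (60, 40) with contributions (0.6, 0.2):
        # (60*0.6 + 40*0.2) / 0.8 = 55
        k = 100.0
        f_target = np.array([60.0, 40.0])
        F = np.where(
            f_target >= (k + 1) / 2,
            -np.log(2 * (k - f_target) / (k - 1)),
            np.log(2 * (f_target - 1) / (k - 1)),
        )[None, :]
        np.testing.assert_allclose(transform_score(F, k), f_target[None, :])
        model = model_from_scores(F, np.array([0.6, 0.2]), 2)
        w = fadm_weight(model, FadmParams(k=k))
        assert w[0] == pytest.approx(55.0, abs=1e-10)

    def test_range_and_permutation_equivariance(self, rng):
        F = rng.normal(size=(20, 4))
        contribs = np.array([0.5, 0.3, 0.15, 0.05])
        model = model_from_scores(F, contribs, 3)
        w = fadm_weight(model, FadmParams(k=100.0))
        assert np.all(w > 1.0) and np.all(w < 100.0)
        perm = rng.permutation(20)
        model_p = model_from_scores(F[perm], contribs, 3)
        np.testing.assert_allclose(fadm_weight(model_p, FadmParams(k=100.0)), w[perm])

    def test_monotone_in_each_factor_score(self):
        contribs = np.array([0.6, 0.4])
        base = np.array([[0.2, -0.3]])
        model = model_from_scores(base, contribs, 2)
        w0 = fadm_weight(model, FadmParams(k=100.0))[0]
        for j in range(2):
            bumped = base.copy()
            bumped[0, j] += 0.5
            wj = fadm_weight(model_from_scores(bumped, contribs, 2), FadmParams(k=100.0))[0]
            assert wj > w0

    def test_no_retained_factors_rejected(self, rng):
        model = model_from_scores(rng.normal(size=(4, 2)), np.array([0.6, 0.4]), 0)
        from fsindex.errors import RetentionError

        with pytest.raises(RetentionError):
            fadm_weight(model)
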