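"""Composite-index machinery: min-max normalization, KMO, Bartlett, PCA,
varimax, regression scores, variance-ratio weights and the assembled index,
each against closed-form or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from heatrisk.composite import (
    DegenerateColumnError,
    bartlett,
    build_composite_index,
    component_weights,
    composite_index,
    factor_scores,
    kmo,
    kmo_from_correlation,
    minmax_normalize,
    pca,
    varimax,
    varimax_criterion,
)
from heatrisk.synthetic import LatentFactorSpec, make_indicators
from tests.helpers import align_loadings, exact_corr_data


class TestMinMax:
    def test_positive_orientation(self):
        out = minmax_normalize(pd.Series([2.0, 4.0, 6.0]), +1)
        assert list(out) == [0.0, 0.5, 1.0]

    def test_negative_orientation(self):
        out = minmax_normalize(pd.Series([2.0, 4.0, 6.0]), -1)
        assert list(out) == [1.0, 0.5, 0.0]

    def test_orientations_sum_to_one(self, rng):
        col = pd.Series(rng.normal(size=50))
        total = minmax_normalize(col, +1) + minmax_normalize(col, -1)
        assert np.allclose(total, 1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateColumnError):
            minmax_normalize(pd.Series([3.0, 3.0, 3.0], name="flat"), +1)

    def test_dataframe_with_mixed_orientations(self):
        df = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        out = minmax_normalize(df, {"a": +1, "b": -1})
        assert list(out["a"]) == [0.0, 1.0]
        assert list(out["b"]) == [1.0, 0.0]


def equicorrelation(p, r):
    return np.full((p, p), r) + (1 - r) * np.eye(p)


class TestKMO:
    def test_equicorrelated_closed_form(self):
        # p=3, r=0.5: partial correlations are exactly 1/3, so
        # KMO = (3 * 0.25) / (3 * 0.25 + 3 * (1/9)) = 0.75 / (0.75 + 1/3)
        got = kmo_from_correlation(equicorrelation(3, 0.5))
        assert got == pytest.approx(0.75 / (0.75 + 1.0 / 3.0), abs=1e-12)
        assert got == pytest.approx(0.6923, abs=5e-5)

    def test_identity_correlation_is_flagged_nan(self):
        assert np.isnan(kmo_from_correlation(np.eye(4)))

    def test_matches_brute_force_anti_image(self, rng):
        data = rng.standard_normal((200, 4)) @ rng.standard_normal((4, 4))
        df = pd.DataFrame(data)
        r = df.corr().to_numpy()
        rinv = np.linalg.inv(r)
        ssr = ssq = 0.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                ssr += r[i, j] ** 2
                ssq += (-rinv[i, j] / np.sqrt(rinv[i, i] * rinv[j, j])) ** 2
        assert kmo(df) == pytest.approx(ssr / (ssr + ssq), abs=1e-12)


class TestBartlett:
    @pytest.mark.parametrize("p,df_expected", [(3, 3), (6, 15)])
    def test_degrees_of_freedom(self, rng, p, df_expected):
        data = exact_corr_data(rng, 24, equicorrelation(p, 0.4))
        _, dof, _ = bartlett(data)
        assert dof == df_expected

    def test_identity_correlation_gives_zero_statistic(self, rng):
        data = exact_corr_data(rng, 30, np.eye(4))
        chi2, _, p = bartlett(data)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self, rng):
        data = exact_corr_data(rng, 24, equicorrelation(3, 0.5))
        chi2, dof, _ = bartlett(data)
        n, p = 24, 3
        want = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(equicorrelation(3, 0.5)))
        assert chi2 == pytest.approx(want, rel=1e-9)

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(ValueError):
            bartlett(rng.standard_normal((3, 5)))


class TestPCA:
    def test_two_indicator_closed_form(self, rng):
        data = exact_corr_data(rng, 40, equicorrelation(2, 0.6))
        res = pca(data)
        assert np.allclose(res.eigenvalues, [1.6, 0.4], atol=1e-9)
        assert res.n_retained == 1

    def test_identity_correlation_retains_none_under_strict_kaiser(self, rng):
        data = exact_corr_data(rng, 30, np.eye(3))
        res = pca(data)
        assert np.allclose(res.eigenvalues, 1.0, atol=1e-9)
        assert res.n_retained == 0

    def test_eigenvalues_sum_to_indicator_count(self, rng):
        data = rng.standard_normal((50, 5)) @ rng.standard_normal((5, 5))
        res = pca(pd.DataFrame(data))
        assert res.eigenvalues.sum() == pytest.approx(5.0, rel=1e-9)
        assert res.variance_pct.sum() == pytest.approx(100.0, rel=1e-9)

    def test_loadings_reproduce_eigenvalues(self, rng):
        data = exact_corr_data(rng, 40, equicorrelation(3, 0.5))
        res = pca(data)
        ssq = (res.loadings.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(ssq, res.eigenvalues[: res.n_retained], atol=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateColumnError):
            pca(df)


class TestVarimax:
    def test_perfect_simple_structure_is_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.85], [0.0, 0.7]])
        rot = varimax(L)
        assert np.allclose(align_loadings(rot, L), L, atol=1e-7)

    def test_two_component_rotation_matches_angle_grid_search(self, rng):
        L = np.array([[0.8, 0.3], [0.7, 0.4], [0.2, 0.8], [0.35, 0.75]])
        rot = varimax(L, kaiser_normalize=False)
        best, best_val = None, -np.inf
        for theta in np.linspace(0, np.pi / 2, 200001):
            c, s = np.cos(theta), np.sin(theta)
            cand = L @ np.array([[c, -s], [s, c]])
            val = varimax_criterion(cand)
            if val > best_val:
                best, best_val = cand, val
        assert varimax_criterion(rot) == pytest.approx(best_val, abs=1e-7)
        assert np.allclose(np.abs(align_loadings(rot, best)), np.abs(best), atol=1e-3)

    def test_criterion_never_decreases(self, rng):
        for _ in range(5):
            L = rng.uniform(-1, 1, size=(6, 3))
            rot = varimax(L, kaiser_normalize=False)
            assert varimax_criterion(rot) >= varimax_criterion(L) - 1e-12

    def test_rotation_preserves_total_retained_variance(self, rng):
        L = rng.uniform(-1, 1, size=(6, 2))
        rot = varimax(L)
        assert (rot**2).sum() == pytest.approx((L**2).sum(), rel=1e-9)

    def test_matches_statsmodels_gpa_rotation(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        L = np.array(
            [[0.8, 0.1], [0.75, 0.2], [0.1, 0.85], [0.15, 0.8], [0.5, 0.5]]
        )
        want, _ = rotate_factors(L, "varimax")
        got = varimax(L, kaiser_normalize=False)
        assert np.allclose(align_loadings(got, want), want, atol=1e-5)

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            varimax(np.ones((4, 1)))


class TestFactorScores:
    def test_scores_have_zero_mean(self, rng):
        data = exact_corr_data(rng, 30, equicorrelation(4, 0.4))
        res = pca(data, min_retain=2)
        z = (data - data.mean(0)) / data.std(0, ddof=1)
        s = factor_scores(z, res.correlation_matrix, res.loadings)
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-10)

    def test_single_component_is_positive_rescale_of_projection(self, rng):
        data = exact_corr_data(rng, 30, equicorrelation(3, 0.6))
        res = pca(data)
        assert res.n_retained == 1
        z = (data - data.mean(0)) / data.std(0, ddof=1)
        lam = res.loadings.to_numpy()
        s = factor_scores(z, res.correlation_matrix, lam)[:, 0]
        proj = (z @ lam)[:, 0]
        ratio = s / proj
        assert ratio.std() < 1e-9 and ratio.mean() > 0

    def test_small_fixture_matches_matrix_algebra(self, rng):
        data = exact_corr_data(rng, 5, equicorrelation(3, 0.3))
        res = pca(data, min_retain=1)
        z = (data - data.mean(0)) / data.std(0, ddof=1)
        lam = res.loadings.to_numpy()
        r = res.correlation_matrix.to_numpy()
        want = z @ np.linalg.inv(r) @ lam
        got = factor_scores(z, r, lam)
        assert np.allclose(got, want, atol=1e-10)


class TestWeightsAndIndex:
    def test_printed_rotated_eigenvalues_give_printed_weights(self):
        w = component_weights([2.326, 2.261])
        assert round(float(w[0]), 3) == 0.507
        assert round(float(w[1]), 3) == 0.493

    def test_single_component_weight_is_one(self):
        assert component_weights([2.184]) == pytest.approx([1.0])

    def test_equal_eigenvalues_equal_weights(self):
        assert np.allclose(component_weights([1.3, 1.3]), 0.5)

    def test_single_component_index_is_minmax_of_score(self, rng):
        s = rng.normal(size=10)
        idx = composite_index(s, [1.0])
        want = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(idx, want)

    def test_degenerate_weight_ignores_other_component(self, rng):
        s = np.column_stack([rng.normal(size=8), rng.normal(size=8)])
        idx = composite_index(s, [1.0, 0.0])
        assert np.allclose(idx, composite_index(s[:, 0], [1.0]))

    def test_hand_computed_weighted_sum(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        combined = 0.6 * s[:, 0] + 0.4 * s[:, 1]
        want = (combined - combined.min()) / (combined.max() - combined.min())
        assert np.allclose(composite_index(s, [0.6, 0.4]), want)

    def test_weights_must_sum_to_one(self, rng):
        with pytest.raises(ValueError):
            composite_index(rng.normal(size=(5, 2)), [0.7, 0.7])


class TestGoldenLoadingArithmetic:
    """Square-and-sum identities of the printed loading tables."""

    VULN_LOADINGS = np.array([0.973, 0.968, -0.548])
    EXPO_ROTATED = np.array(
        [
            [0.728, -0.333],
            [0.873, 0.065],
            [0.021, 0.810],
            [-0.054, 0.905],
            [0.825, 0.384],
            [0.592, 0.723],
        ]
    )

    def test_vulnerability_eigenvalue_and_variance(self):
        ev = float((self.VULN_LOADINGS**2).sum())
        assert ev == pytest.approx(2.184, abs=0.005)
        assert ev / 3 * 100 == pytest.approx(72.8, abs=0.2)

    def test_exposure_rotated_eigenvalues(self):
        ssq = (self.EXPO_ROTATED**2).sum(axis=0)
        assert ssq[0] == pytest.approx(2.326, abs=0.005)
        assert ssq[1] == pytest.approx(2.261, abs=0.005)
        w = component_weights(ssq)
        assert round(float(w[0]), 3) == pytest.approx(0.507, abs=0.002)


class TestRecovery:
    def test_two_factor_model_recovered(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.85, 0.8, 0.75]
        L[3:, 1] = [0.85, 0.8, 0.7]
        lf = LatentFactorSpec(loading_matrix=L, noise_sd=0.3,
                              indicator_names=list("abcdef"))
        table = make_indicators(500, lf, seed=42)
        z = (table.values - table.values.mean()) / table.values.std(ddof=1)
        res = pca(z)
        assert res.n_retained == 2
        rot = varimax(res.loadings.to_numpy())
        # compare against the generating loadings rescaled to unit variance
        sd = np.sqrt((L**2).sum(axis=1) + 0.3**2)
        truth = L / sd[:, None]
        aligned = align_loadings(rot, truth)
        assert np.abs(aligned - truth).max() < 0.1


class TestBuildCompositeIndex:
    def test_full_chain_on_synthetic_table(self):
        table = make_indicators(24, seed=8)
        expo = table.values[
            [c for c in table.values.columns if c not in
             ("population_density", "household_density", "social_weaker_section")]
        ]
        idx, res = build_composite_index(expo, name="exposure")
        assert idx["value"].min() == pytest.approx(0.0)
        assert idx["value"].max() == pytest.approx(1.0)
        assert res.weights.sum() == pytest.approx(1.0)
        assert set(idx["category"]).issubset(
            {"Lowest", "Low", "Moderate", "High", "Highest"}
        )
        assert res.factor_scores.mean().abs().max() < 1e-10
        # rotation preserves total retained variance
        if res.n_retained >= 2:
            assert res.rotated_eigenvalues.sum() == pytest.approx(
                res.eigenvalues[: res.n_retained].sum(), rel=1e-9
            )
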