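"""Shape PCA, broken-stick selection, confidence bands and outlier flags."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taphomorph import (
    MorphospaceModel,
    broken_stick,
    confidence_bands,
    flag_outliers,
    gpa,
    halfwidth_from_eigenvalue,
    pca,
    reconstruct_shape,
    select_components,
    variance_table,
)
from taphomorph.morphospace import mahalanobis_ellipse, project_configuration

from conftest import TETRA, config_from_array, random_rotation


def jacobi_eigh(a, sweeps=60, tol=1e-14):
    """Independent eigen-oracle: cyclic Jacobi rotations on a symmetric
    matrix; returns eigenvalues (descending) and eigenvectors (columns)."""
    a = np.array(a, dtype=float)
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(sweeps):
        off = np.sqrt(np.sum(np.tril(a, -1) ** 2))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < 1e-300:
                    continue
                theta = 0.5 * np.arctan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = np.cos(theta), np.sin(theta)
                j = np.eye(n)
                j[p, p] = j[q, q] = c
                j[p, q] = s
                j[q, p] = -s
                a = j.T @ a @ j
                v = v @ j
    order = np.argsort(np.diag(a))[::-1]
    return np.diag(a)[order], v[:, order]


def _random_ensemble(n=6, k=5, seed=9, spread=0.08):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(k, 3))
    configs = [
        config_from_array(base + rng.normal(size=(k, 3)) * spread, f"s{i}")
        for i in range(n)
    ]
    return gpa(configs)


def _gaussian_model(n, sds, seed=0):
    """Synthetic MorphospaceModel with centered Gaussian score columns."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, len(sds))) * np.asarray(sds)
    scores -= scores.mean(axis=0)
    eigenvalues = scores.var(axis=0, ddof=1)
    p = eigenvalues / eigenvalues.sum()
    return MorphospaceModel(
        specimen_ids=[f"g{i}" for i in range(n)],
        landmark_ids=tuple(range(1, 3)),
        eigenvalues=eigenvalues,
        proportions=p,
        cumulative=np.cumsum(p),
        scores=scores,
        loadings=np.eye(len(sds), 6),
        mean_shape=np.zeros((2, 3)),
        n_specimens=n,
        n_landmarks=2,
    )


class TestPCA:
    def test_identical_shapes_have_no_variance(self):
        configs = [config_from_array(TETRA, f"s{i}") for i in range(4)]
        model = pca(gpa(configs))
        assert model.n_components == 0

    def test_two_distinct_shapes_are_rank_one(self):
        rng = np.random.default_rng(10)
        a = TETRA
        b = TETRA + rng.normal(size=TETRA.shape) * 0.1
        model = pca(gpa([config_from_array(x, f"s{i}") for i, x in enumerate([a, b, a])]))
        assert model.n_components == 1
        assert model.proportions[0] == pytest.approx(1.0)

    def test_matches_jacobi_oracle(self):
        ens = _random_ensemble()
        model = pca(ens)
        flat = ens.flattened()
        centered = flat - flat.mean(axis=0)
        cov = centered.T @ centered / (len(flat) - 1)
        evals, evecs = jacobi_eigh(cov)
        np.testing.assert_allclose(
            model.eigenvalues, evals[: model.n_components], atol=1e-12
        )
        for j in range(model.n_components):
            cos = abs(model.loadings[j] @ evecs[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_trace_conservation(self, fitted):
        _, ens, model = fitted
        flat = ens.flattened()
        total = ((flat - flat.mean(axis=0)) ** 2).sum() / (len(flat) - 1)
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-10)

    def test_model_invariants(self, fitted):
        _, _, model = fitted
        assert np.all(np.diff(model.eigenvalues) <= 1e-18)
        assert model.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-12)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-10)
        assert model.n_components <= min(
            model.n_specimens - 1, 3 * model.n_landmarks - 7
        )

    def test_reconstruction_of_centered_data(self, fitted):
        _, ens, model = fitted
        flat = ens.flattened()
        centered = flat - flat.mean(axis=0)
        rebuilt = model.scores @ model.loadings
        np.testing.assert_allclose(rebuilt, centered, atol=1e-8)

    def test_scores_invariant_to_joint_rotation(self):
        ens = _random_ensemble(seed=12)
        model = pca(ens)
        rot = random_rotation(np.random.default_rng(13))
        rotated = ens
        rotated.aligned = ens.aligned @ rot.T
        rotated.consensus = ens.consensus @ rot.T
        model2 = pca(rotated)
        for j in range(model.n_components):
            np.testing.assert_allclose(
                np.abs(model2.scores[:, j]), np.abs(model.scores[:, j]), atol=1e-8
            )

    def test_too_few_specimens(self):
        configs = [config_from_array(TETRA, "a"), config_from_array(TETRA, "b")]
        ens = gpa(configs)
        with pytest.raises(ValueError, match=">= 3"):
            pca(ens)


class TestVarianceTable:
    def test_forced_arithmetic(self):
        model = _gaussian_model(50, [3.0, 1.0], seed=1)
        # overwrite with exact eigenvalues to pin the arithmetic
        model.eigenvalues = np.array([3.0, 1.0])
        model.proportions = model.eigenvalues / 4.0
        model.cumulative = np.cumsum(model.proportions)
        tab = variance_table(model)
        assert list(tab["proportion_pct"]) == [75.0, 25.0]
        assert list(tab["cumulative_pct"]) == [75.0, 100.0]

    def test_cumulative_ends_at_100(self, fitted):
        _, _, model = fitted
        tab = variance_table(model)
        assert tab["cumulative_pct"].iloc[-1] == pytest.approx(100.0, abs=1e-9)
        ratio = tab["eigenvalue"] / tab["proportion_pct"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)


class TestBrokenStick:
    def test_single_component(self):
        np.testing.assert_allclose(broken_stick(1), [1.0])

    def test_three_components_harmonic_sums(self):
        np.testing.assert_allclose(
            broken_stick(3), [0.6111, 0.2778, 0.1111], atol=1e-4
        )

    @given(st.integers(1, 200))
    def test_sums_to_one_and_decreases(self, p):
        b = broken_stick(p)
        assert b.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(b) < 0) or p == 1

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            broken_stick(0)


class TestSelectComponents:
    def test_boundary_equality_retains_nothing(self):
        model = _gaussian_model(40, [1.0, 1.0])
        model.proportions = np.array([0.75, 0.25])
        model.eigenvalues = model.proportions.copy()
        # p=2 thresholds are exactly (0.75, 0.25): strict comparison -> 0
        assert select_components(model, rule="broken_stick") == 0

    def test_dominant_first_component(self):
        model = _gaussian_model(40, [1.0, 1.0, 1.0])
        model.proportions = np.array([0.9, 0.05, 0.05])
        model.eigenvalues = model.proportions.copy()
        assert select_components(model, rule="broken_stick") == 1

    def test_fixed_k(self, fitted):
        _, _, model = fitted
        assert select_components(model, rule="fixed_k", fixed_k=4) == 4


class TestConfidenceBands:
    def test_degenerate_scores(self):
        model = _gaussian_model(10, [1.0])
        model.scores = np.zeros((10, 1))
        (band,) = confidence_bands(model, [1])
        assert band.half_width == 0.0
        assert band.lower == band.upper == band.mean

    def test_hand_computed_sample_sd(self):
        model = _gaussian_model(3, [1.0])
        model.scores = np.array([[-2.0], [0.0], [2.0]])
        (band,) = confidence_bands(model, [1])
        assert band.sd == pytest.approx(2.0)
        assert band.lower == pytest.approx(-3.92)
        assert band.upper == pytest.approx(3.92)
        assert band.upper - band.lower == pytest.approx(2 * band.half_width)

    def test_halfwidth_equals_multiplier_times_root_eigenvalue(self, fitted):
        _, _, model = fitted
        bands = confidence_bands(model, [1, 2, 3, 4])
        for b in bands:
            assert b.half_width == pytest.approx(
                halfwidth_from_eigenvalue(model.eigenvalues[b.pc_index - 1]),
                rel=1e-10,
            )

    def test_mahalanobis_alternative(self, fitted):
        _, _, model = fitted
        ell = mahalanobis_ellipse(model, 1, 2)
        assert ell["semi_axes"][0] >= ell["semi_axes"][1] >= 0


class TestOutliers:
    def test_all_within_bands_is_empty(self):
        model = _gaussian_model(100, [1.0], seed=3)
        bands = confidence_bands(model, [1], multiplier=100.0)
        report = flag_outliers(model, bands)
        assert report.per_pc[1] == []
        assert report.flagged_specimens() == []

    def test_planted_extreme_specimen(self):
        model = _gaussian_model(30, [1.0, 1.0], seed=4)
        sd = model.scores[:, 0].std(ddof=1)
        model.scores[5, 0] = model.scores[:, 0].mean() + 5 * sd
        bands = confidence_bands(model, [1, 2])
        report = flag_outliers(model, bands)
        assert "g5" in report.per_pc[1]
        assert report.per_specimen["g5"] == [1]

    def test_gaussian_flag_rate_near_five_percent(self):
        model = _gaussian_model(10_000, [1.0], seed=5)
        bands = confidence_bands(model, [1])
        report = flag_outliers(model, bands)
        rate = len(report.per_pc[1]) / 10_000
        assert rate == pytest.approx(0.05, abs=0.01)


class TestReconstruction:
    def test_zero_score_returns_mean(self, fitted):
        _, _, model = fitted
        np.testing.assert_array_equal(reconstruct_shape(model, 1, 0.0), model.mean_shape)

    def test_round_trip_score(self, fitted):
        _, _, model = fitted
        shape = reconstruct_shape(model, 2, 0.043)
        scores = project_configuration(model, shape)
        assert scores[1] == pytest.approx(0.043, abs=1e-10)

    def test_difference_parallel_to_loading(self, fitted):
        _, _, model = fitted
        hi = reconstruct_shape(model, 1, 0.1).ravel()
        lo = reconstruct_shape(model, 1, -0.1).ravel()
        diff = hi - lo
        cos = diff @ model.loadings[0] / np.linalg.norm(diff)
        assert cos == pytest.approx(1.0, abs=1e-12)
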