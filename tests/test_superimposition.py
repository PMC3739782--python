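"""GPA correctness: invariance, oracle equivalence, descent, no reflections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taphomorph import gpa, procrustes_distance, tangent_project
from taphomorph.superimposition import optimal_rotation

from conftest import TETRA, config_from_array, random_rotation


def euler_rotation(ax, ay, az):
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def grid_search_distance(a, b, levels=4, coarse=24):
    """Independent rotation oracle: coarse-to-fine grid search over Euler
    angles minimizing the summed squared distance of ``b @ R.T`` to ``a``.
    Refines to ~1e-3 rad resolution and below."""
    center = np.zeros(3)
    width = np.pi
    best = (np.inf, center)
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, coarse) for c in center]
        for ax in axes[0]:
            for ay in axes[1]:
                for az in axes[2]:
                    r = euler_rotation(ax, ay, az)
                    d = np.sum((a - b @ r.T) ** 2)
                    if d < best[0]:
                        best = (d, np.array([ax, ay, az]))
        center = best[1]
        width = width / (coarse / 4)
    return np.sqrt(best[0])


def centered_unit(coords):
    c = coords - coords.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


class TestProcrustesDistance:
    def test_identical_shapes(self):
        assert procrustes_distance(TETRA, TETRA) < 1e-12

    def test_pure_rotation_is_zero(self):
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        assert procrustes_distance(TETRA, TETRA @ rot.T) < 1e-12

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        a = centered_unit(TETRA)
        b = centered_unit(TETRA + rng.normal(size=TETRA.shape) * 0.15)
        ours = procrustes_distance(a, b)
        oracle = grid_search_distance(a, b)
        assert ours == pytest.approx(oracle, abs=2e-4)
        assert ours <= oracle + 1e-12  # SVD optimum can only be at least as good

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = centered_unit(rng.normal(size=(5, 3)))
        b = centered_unit(rng.normal(size=(5, 3)))
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(TETRA, TETRA[:3])


class TestGPA:
    def _perturbed_tetra_set(self, n=3, scale=0.05, seed=4):
        rng = np.random.default_rng(seed)
        return [
            config_from_array(
                TETRA + rng.normal(size=TETRA.shape) * scale, specimen_id=f"t{i}"
            )
            for i in range(n)
        ]

    def test_identical_inputs_align_exactly(self):
        configs = [config_from_array(TETRA, specimen_id=f"s{i}") for i in range(4)]
        ens = gpa(configs)
        assert ens.residual_sum() < 1e-24
        for shape in ens.aligned:
            np.testing.assert_allclose(shape, ens.consensus, atol=1e-12)

    def test_similarity_copy_has_zero_shape_distance(self):
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        copy = 2.7 * TETRA @ rot.T + np.array([5.0, -3.0, 11.0])
        ens = gpa([config_from_array(TETRA, "a"), config_from_array(copy, "b")])
        assert procrustes_distance(ens.aligned[0], ens.aligned[1]) < 1e-10

    def test_invariant_to_input_similarity_transforms(self):
        configs = self._perturbed_tetra_set(n=4)
        ref = gpa(configs).aligned
        rng = np.random.default_rng(6)
        moved = list(configs)
        coords = configs[2].as_array()
        moved[2] = config_from_array(
            0.31 * coords @ random_rotation(rng).T + rng.normal(size=3) * 40,
            specimen_id="t2",
        )
        again = gpa(moved).aligned
        np.testing.assert_allclose(again, ref, atol=1e-8)

    def test_monotone_descent_of_residuals(self, fitted):
        _, ens, _ = fitted
        hist = ens.residual_history
        assert len(hist) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_two_specimen_closed_form(self):
        """For two shapes the GPA residual equals the ordinary Procrustes
        solution given in closed form by the singular values of X1' X2."""
        rng = np.random.default_rng(7)
        a = centered_unit(rng.normal(size=(6, 3)))
        b = centered_unit(rng.normal(size=(6, 3)))
        d = procrustes_distance(a, b)
        svals = np.linalg.svd(b.T @ a, compute_uv=False)
        sign = np.sign(np.linalg.det(b.T @ a))
        traced = svals[0] + svals[1] + sign * svals[2]
        closed = np.sqrt(max(0.0, 2.0 - 2.0 * traced))  # both shapes unit size
        assert d == pytest.approx(closed, abs=1e-10)

    def test_consensus_matches_oracle_alternation(self):
        """GPA agrees with an independent alternation that uses grid-search
        rotations instead of the SVD solver."""
        configs = self._perturbed_tetra_set(n=3)
        ens = gpa(configs)

        shapes = np.array([centered_unit(c.as_array()) for c in configs])
        consensus = shapes[0].copy()
        for _ in range(60):
            for i in range(3):
                best_d, best_r = np.inf, np.eye(3)
                # reuse euler grid around the SVD-free coarse-to-fine search
                center = np.zeros(3)
                width = np.pi
                for _level in range(4):
                    grid = [np.linspace(c - width, c + width, 16) for c in center]
                    for ax in grid[0]:
                        for ay in grid[1]:
                            for az in grid[2]:
                                r = euler_rotation(ax, ay, az)
                                d = np.sum((consensus - shapes[i] @ r.T) ** 2)
                                if d < best_d:
                                    best_d, best_r = d, r
                                    center = np.array([ax, ay, az])
                    width /= 4
                shapes[i] = shapes[i] @ best_r.T
            new_consensus = shapes.mean(axis=0)
            new_consensus = new_consensus / np.sqrt(np.sum(new_consensus**2))
            if np.sum((new_consensus - consensus) ** 2) < 1e-16:
                consensus = new_consensus
                break
            consensus = new_consensus

        oracle_resid = float(np.sum((shapes - shapes.mean(axis=0)) ** 2))
        assert ens.residual_sum() == pytest.approx(oracle_resid, abs=1e-5)
        # consensus agreement limited by the oracle's final grid resolution
        assert procrustes_distance(ens.consensus, consensus) < 5e-3

    def test_reflected_shape_not_collapsed(self):
        """A mirror-image specimen keeps a nonzero shape distance: the solver
        must never apply a reflection, or left/right taphonomic asymmetry
        would be silently destroyed."""
        chiral = np.array(
            [[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0, 0, 1.0], [1.2, 0.8, 0.4]]
        )
        mirror = chiral * np.array([1, -1, 1])
        ens = gpa([config_from_array(chiral, "a"), config_from_array(mirror, "b")])
        assert procrustes_distance(ens.aligned[0], ens.aligned[1]) > 0.05
        r = optimal_rotation(centered_unit(mirror), centered_unit(chiral))
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_rotations_always_proper(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        r = optimal_rotation(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-10)

    def test_input_validation(self):
        lone = [config_from_array(TETRA)]
        with pytest.raises(ValueError, match=">= 2"):
            gpa(lone)
        collinear = [
            config_from_array(np.outer(np.arange(4), [1.0, 0, 0]), f"c{i}")
            for i in range(2)
        ]
        with pytest.raises(ValueError, match="collinear"):
            gpa(collinear)
        mismatched = [
            config_from_array(TETRA, "a"),
            config_from_array(TETRA, "b", start_id=2),
        ]
        with pytest.raises(ValueError, match="common landmark set"):
            gpa(mismatched)


class TestTangentProjection:
    def test_consensus_is_fixed_point(self, fitted):
        _, ens, _ = fitted
        flat = ens.consensus.ravel()
        c_hat = flat / np.linalg.norm(flat)
        # the consensus satisfies the projection constraint exactly
        assert flat @ c_hat == pytest.approx(np.linalg.norm(flat), abs=1e-12)

    def test_idempotent(self, fitted):
        _, ens, _ = fitted
        again = tangent_project(ens)
        np.testing.assert_allclose(again.aligned, ens.aligned, atol=1e-12)

    def test_perturbation_is_second_order(self):
        """Projection moves a shape by O(rho^2) of its Procrustes distance
        to the consensus."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=(10, 3))
        configs = [
            config_from_array(base + rng.normal(size=base.shape) * 0.012, f"s{i}")
            for i in range(8)
        ]
        ens = gpa(configs)
        rhos = [
            procrustes_distance(shape, ens.consensus) for shape in ens.aligned
        ]
        assert max(rhos) < 0.05
        proj = tangent_project(ens)
        change = np.abs(proj.aligned - ens.aligned).max()
        assert change < max(rhos) ** 2
        assert change < 2.5e-3
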