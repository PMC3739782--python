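"""Generalized Procrustes Analysis (GPA).

GPA removes position, scale and orientation from a sample of landmark
configurations so that only *shape* differences remain: every configuration
is centered on the origin, scaled to unit centroid size, and rotated to
minimize its summed squared landmark distance to a consensus (mean) shape,
iterating until the consensus stabilizes.

Rotations are proper (determinant +1).  Reflections are never applied:
left/right asymmetry is a real signal in taphonomically deformed material
and must survive superimposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks_io import LandmarkConfiguration, centroid_size

__all__ = [
    "AlignedEnsemble",
    "gpa",
    "procrustes_distance",
    "optimal_rotation",
    "tangent_project",
]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 200


@dataclass
class AlignedEnsemble:
    """Procrustes-superimposed configurations and their consensus.

    ``aligned`` is an ``n x K x 3`` array: each slice is centered at the
    origin with unit centroid size.  ``centroid_sizes`` keeps the original
    sizes (length units) for later allometry tests.  ``landmark_ids`` maps
    rows of each slice back to scheme ids.
    """

    specimen_ids: list[str]
    landmark_ids: tuple[int, ...]
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    tangent_projected: bool = False
    residual_history: list[float] = None  # summed squared residuals per iteration

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """n x 3K matrix of aligned coordinates (rows are specimens)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def residual_sum(self) -> float:
        """Summed squared distances of all specimens to the consensus."""
        return float(np.sum((self.aligned - self.consensus) ** 2))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ``||target - source @ R||_F``.

    Solved by SVD of ``source.T @ target`` with the usual determinant
    correction, so a reflection is never returned even when it would fit
    better.
    """
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:  # degenerate: pick the proper branch explicitly
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0:
        raise ValueError("configuration has zero centroid size")
    return centered / size, size


def _check_nondegenerate(coords: np.ndarray, specimen_id: str) -> None:
    if coords.shape[0] < 4:
        raise ValueError(f"specimen {specimen_id!r}: need >= 4 landmarks, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError(f"specimen {specimen_id!r}: landmarks are collinear (degenerate)")


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> AlignedEnsemble:
    """Superimpose configurations by iterative Procrustes alignment.

    All specimens must share one landmark set with no missing data.  Each is
    centered and scaled to unit centroid size; the consensus is initialised
    from the first specimen and the align/average loop runs until the
    consensus moves by less than ``tol`` (root-summed-square) or ``max_iter``
    iterations (then ``converged`` is False and the partial result returned).
    """
    if len(configs) < 2:
        raise ValueError(f"GPA needs >= 2 specimens, got {len(configs)}")
    id_sets = {cfg.landmark_ids for cfg in configs}
    if len(id_sets) > 1:
        raise ValueError("specimens do not share a common landmark set")
    for cfg in configs:
        if cfg.missing:
            raise ValueError(
                f"specimen {cfg.specimen_id!r} has missing landmarks; "
                "exclude them (apply_exclusions) before GPA"
            )
    landmark_ids = configs[0].landmark_ids
    raw = np.array([cfg.as_array(landmark_ids) for cfg in configs])
    for cfg, coords in zip(configs, raw):
        _check_nondegenerate(coords, cfg.specimen_id)

    sizes = np.array([centroid_size(c) for c in raw])
    shapes = np.array([_center_scale(c)[0] for c in raw])

    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
        history.append(float(np.sum((shapes - shapes.mean(axis=0)) ** 2)))
        new_consensus = shapes.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    # final pass so every specimen is optimally rotated to the final consensus
    for i in range(shapes.shape[0]):
        shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)

    # canonical orientation: principal axes of the consensus with fixed signs,
    # so the result is invariant to how the inputs happened to be oriented
    v = _canonical_frame(shapes.mean(axis=0))
    shapes = shapes @ v
    consensus = consensus @ v

    return AlignedEnsemble(
        specimen_ids=[cfg.specimen_id for cfg in configs],
        landmark_ids=landmark_ids,
        aligned=shapes,
        centroid_sizes=sizes,
        consensus=shapes.mean(axis=0),
        iterations=iterations,
        converged=converged,
        residual_history=history,
    )


def _canonical_frame(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to its principal-axis frame.

    Axes are ordered by decreasing spread; the sign of the first two axes is
    fixed by making the consensus coordinate of largest magnitude along each
    positive, and the third axis is their cross product (det +1).  This
    makes GPA output orientation a deterministic function of the consensus
    shape alone, not of the input orientations.
    """
    evals, vecs = np.linalg.eigh(consensus.T @ consensus)
    v = vecs[:, np.argsort(evals)[::-1]]
    proj = consensus @ v
    for j in range(2):
        k = int(np.argmax(np.abs(proj[:, j])))
        if proj[k, j] < 0:
            v[:, j] = -v[:, j]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return v


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between ``a`` and ``b`` after optimally
    rotating ``b`` onto ``a`` (proper rotation only; no centering/scaling)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    rotated = b @ optimal_rotation(b, a)
    return float(np.sqrt(np.sum((a - rotated) ** 2)))


def tangent_project(ensemble: AlignedEnsemble) -> AlignedEnsemble:
    """Orthogonally project aligned shapes onto the tangent space at the consensus.

    Shapes of unit centroid size live on a unit sphere in 3K dimensions; PCA
    assumes a flat space.  Each flattened shape ``x`` is replaced by its
    orthogonal projection onto the hyperplane through the consensus and
    normal to it: ``x - (x . c_hat - |c|) c_hat``, pinning the component
    along the consensus direction.
    The map is idempotent and perturbs a shape at Procrustes distance rho
    from the consensus by O(rho^2).
    """
    flat = ensemble.flattened()
    c = ensemble.consensus.ravel()
    c_norm = float(np.linalg.norm(c))
    c = c / c_norm
    proj = flat - np.outer(flat @ c - c_norm, c)
    aligned = proj.reshape(ensemble.aligned.shape)
    return AlignedEnsemble(
        specimen_ids=list(ensemble.specimen_ids),
        landmark_ids=ensemble.landmark_ids,
        aligned=aligned,
        centroid_sizes=ensemble.centroid_sizes.copy(),
        consensus=aligned.mean(axis=0),
        iterations=ensemble.iterations,
        converged=ensemble.converged,
        tangent_projected=True,
        residual_history=list(ensemble.residual_history or []),
    )
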