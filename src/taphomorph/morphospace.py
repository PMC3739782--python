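"""Shape-space PCA, variance accounting, component selection and intervals.

The aligned (and, by default, tangent-projected) coordinates of an
:class:`~taphomorph.superimposition.AlignedEnsemble` are flattened to 3K
variables and eigen-decomposed about their mean.  On top of the
decomposition this module provides:

* a variance table (eigenvalue, proportion, cumulative) per PC;
* the broken-stick rule for choosing how many PCs carry signal;
* per-axis 95% confidence bands ``mean +/- 1.96 sigma`` (sample SD) and
  outlier flagging against them;
* shape reconstruction along a PC axis (wireframes, OBJ export).

Because scores are centered and the eigenvalues are sample variances of the
scores, a PC's band half-width equals ``1.96 * sqrt(eigenvalue)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .superimposition import AlignedEnsemble

__all__ = [
    "MorphospaceModel",
    "ConfidenceBand",
    "OutlierReport",
    "pca",
    "variance_table",
    "broken_stick",
    "select_components",
    "confidence_bands",
    "halfwidth_from_eigenvalue",
    "mahalanobis_ellipse",
    "flag_outliers",
    "reconstruct_shape",
    "project_configuration",
    "export_wireframe_obj",
]

NULL_EIGENVALUE_RTOL = 1e-12
DEFAULT_CONFIDENCE_MULTIPLIER = 1.96


@dataclass
class MorphospaceModel:
    """Eigenstructure of the shape space.

    ``loadings`` has one row per PC (each a unit 3K vector); ``scores`` is
    ``n_specimens x n_pcs`` with zero-mean columns; eigenvalues are the
    sample (n-1) variances of the score columns, in descending order.
    """

    specimen_ids: list[str]
    landmark_ids: tuple[int, ...]
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    mean_shape: np.ndarray
    n_specimens: int
    n_landmarks: int

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.specimen_ids, name="specimen"),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


@dataclass(frozen=True)
class ConfidenceBand:
    """Per-axis interval ``mean +/- multiplier * sd`` (default 95%: 1.96)."""

    pc_index: int  # 1-based
    mean: float
    sd: float
    half_width: float
    lower: float
    upper: float


@dataclass
class OutlierReport:
    """Specimens whose score falls strictly outside a PC's confidence band."""

    per_pc: dict[int, list[str]]
    per_specimen: dict[str, list[int]]

    def flagged_specimens(self) -> list[str]:
        return sorted(s for s, pcs in self.per_specimen.items() if pcs)


def pca(ensemble: AlignedEnsemble) -> MorphospaceModel:
    """Eigen-decompose the covariance of flattened aligned coordinates.

    Computed by SVD of the centered data matrix (numerically equivalent to
    diagonalizing the 3K x 3K covariance).  Superimposition removes seven
    degrees of freedom in 3D (translation 3, rotation 3, scale 1), so at
    most ``min(n - 1, 3K - 7)`` eigenvalues are non-null; anything below
    ``1e-12`` of the largest is treated as exactly zero.  Loading signs are
    fixed by making each loading's largest-magnitude element positive.
    """
    n = ensemble.n_specimens
    if n < 3:
        raise ValueError(f"PCA needs >= 3 specimens, got {n}")
    flat = ensemble.flattened()
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)

    if eigenvalues.size and eigenvalues[0] > 0:
        # absolute floor: aligned shapes have unit centroid size, so any
        # real variance is far above squared machine-precision jitter
        cutoff = max(NULL_EIGENVALUE_RTOL * eigenvalues[0], 1e-24)
        keep = eigenvalues > cutoff
    else:
        keep = np.zeros(eigenvalues.shape, dtype=bool)
    eigenvalues = eigenvalues[keep]
    loadings = vt[keep]
    scores = centered @ loadings.T

    # sign convention: largest-magnitude element of each loading is positive
    for j in range(loadings.shape[0]):
        k = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, k] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]

    total = float(eigenvalues.sum())
    proportions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return MorphospaceModel(
        specimen_ids=list(ensemble.specimen_ids),
        landmark_ids=ensemble.landmark_ids,
        eigenvalues=eigenvalues,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        scores=scores,
        loadings=loadings,
        mean_shape=mean_flat.reshape(-1, 3),
        n_specimens=n,
        n_landmarks=ensemble.n_landmarks,
    )


def variance_table(model: MorphospaceModel) -> pd.DataFrame:
    """Eigenvalue / proportion / cumulative table, one row per non-null PC."""
    return pd.DataFrame(
        {
            "pc": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "proportion_pct": model.proportions * 100.0,
            "cumulative_pct": model.cumulative * 100.0,
        }
    )


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected proportions for ``p`` components.

    ``b_k = (1/p) * sum_{i=k}^{p} 1/i`` — the expected length of the k-th
    longest piece of a unit stick broken at p-1 uniform points.  Strictly
    decreasing; sums to 1.
    """
    if p < 1:
        raise ValueError(f"need p >= 1 components, got {p}")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def select_components(
    model: MorphospaceModel, rule: str = "broken_stick", fixed_k: int | None = None
) -> int:
    """Number of PCs to interpret.

    ``broken_stick``: the largest k such that PCs 1..k each *strictly* exceed
    their broken-stick threshold (stops at the first failure).  ``fixed_k``:
    the configured count, for analyses that retain axes by interpretability.
    """
    if rule == "fixed_k":
        if fixed_k is None:
            raise ValueError("rule 'fixed_k' requires fixed_k")
        return int(fixed_k)
    if rule != "broken_stick":
        raise ValueError(f"unknown rule {rule!r}")
    thresholds = broken_stick(model.n_components)
    k = 0
    for prop, thr in zip(model.proportions, thresholds):
        if prop > thr:
            k += 1
        else:
            break
    return k


def halfwidth_from_eigenvalue(
    eigenvalue: float, multiplier: float = DEFAULT_CONFIDENCE_MULTIPLIER
) -> float:
    """Band half-width implied by a PC's eigenvalue.

    Score columns are centered and their sample (n-1) variance equals the
    eigenvalue, so the band half-width is ``multiplier * sqrt(eigenvalue)``
    -- usable when only a variance table is available.
    """
    if eigenvalue < 0:
        raise ValueError("eigenvalue must be nonnegative")
    return multiplier * float(np.sqrt(eigenvalue))


def confidence_bands(
    model: MorphospaceModel,
    pcs: Iterable[int] | None = None,
    multiplier: float = DEFAULT_CONFIDENCE_MULTIPLIER,
) -> list[ConfidenceBand]:
    """Per-PC interval ``mean +/- multiplier * sd`` with the sample (n-1) SD.

    ``pcs`` are 1-based indices (default: all non-null PCs).  Since score
    columns are centered, the mean is ~0 and ``sd = sqrt(eigenvalue)``.
    """
    if model.n_specimens < 2:
        raise ValueError("confidence bands need >= 2 specimens")
    if pcs is None:
        pcs = range(1, model.n_components + 1)
    bands = []
    for pc in pcs:
        if not 1 <= pc <= model.n_components:
            raise IndexError(f"PC{pc} does not exist (model has {model.n_components})")
        col = model.scores[:, pc - 1]
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        hw = multiplier * sd
        bands.append(
            ConfidenceBand(
                pc_index=pc, mean=mean, sd=sd, half_width=hw, lower=mean - hw, upper=mean + hw
            )
        )
    return bands


def mahalanobis_ellipse(
    model: MorphospaceModel, pc_x: int, pc_y: int, multiplier: float = DEFAULT_CONFIDENCE_MULTIPLIER
) -> dict:
    """Covariance (Mahalanobis) ellipse parameters for a 2D score plot.

    Offered as an alternative to the default per-axis bands: returns the
    ellipse center, semi-axes (``multiplier`` standard deviations along the
    2x2 score-covariance eigenvectors) and orientation angle in radians.
    """
    pts = model.scores[:, [pc_x - 1, pc_y - 1]]
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return {
        "center": pts.mean(axis=0).tolist(),
        "semi_axes": (multiplier * np.sqrt(np.maximum(evals, 0))).tolist(),
        "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
    }


def flag_outliers(model: MorphospaceModel, bands: Sequence[ConfidenceBand]) -> OutlierReport:
    """Flag specimens strictly outside each band, per PC independently."""
    per_pc: dict[int, list[str]] = {}
    per_specimen: dict[str, list[int]] = {s: [] for s in model.specimen_ids}
    for band in bands:
        col = model.scores[:, band.pc_index - 1]
        out = [
            sid
            for sid, val in zip(model.specimen_ids, col)
            if val < band.lower or val > band.upper
        ]
        per_pc[band.pc_index] = out
        for sid in out:
            per_specimen[sid].append(band.pc_index)
    return OutlierReport(per_pc=per_pc, per_specimen=per_specimen)


def reconstruct_shape(model: MorphospaceModel, pc: int, score: float) -> np.ndarray:
    """K x 3 configuration at ``score`` along a PC: mean + score * loading."""
    if not 1 <= pc <= model.n_components:
        raise IndexError(f"PC{pc} does not exist (model has {model.n_components})")
    flat = model.mean_shape.ravel() + score * model.loadings[pc - 1]
    return flat.reshape(-1, 3)


def project_configuration(model: MorphospaceModel, coords: np.ndarray) -> np.ndarray:
    """Scores of an aligned K x 3 configuration (or n x K x 3 stack) in the
    model's morphospace: centered on the model mean, rotated by its loadings."""
    coords = np.asarray(coords, dtype=float)
    flat = coords.reshape(-1, model.mean_shape.size) - model.mean_shape.ravel()
    scores = flat @ model.loadings.T
    return scores[0] if coords.ndim == 2 else scores


def export_wireframe_obj(
    coords: np.ndarray, edges: Sequence[tuple[int, int]], path: str | Path
) -> None:
    """Write a K x 3 configuration as an OBJ wireframe (vertices + line elements).

    ``edges`` are 1-based vertex index pairs, matching the row order of
    ``coords``; viewable in standard mesh viewers.
    """
    coords = np.asarray(coords, dtype=float)
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in coords]
    for a, b in edges:
        if not (1 <= a <= len(coords) and 1 <= b <= len(coords)):
            raise IndexError(f"edge ({a},{b}) references a vertex outside 1..{len(coords)}")
        lines.append(f"l {a} {b}")
    Path(path).write_text("\n".join(lines) + "\n")
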