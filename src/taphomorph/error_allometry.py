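"""Digitizing-error protocol, allometry tests, and sensitivity re-runs.

*Error protocol*: one specimen is digitized R times; the replicates are
projected into the morphospace and their Euclidean distances to the
replicate mean (over the first P PCs, default 4) are compared with the
distances of every other specimen to that mean.  If the replicate cloud and
the rest of the sample do not overlap, measurement error is negligible
relative to between-specimen shape variation.

*Allometry*: Spearman's rank correlation r_s between each PC's scores and
centroid size, two-sided.  Rank-based because fossil size samples are
rarely normal.  Exact permutation p-values for small n, t-approximation
otherwise.

*Sensitivity*: drop named specimens and re-run the whole superimposition +
PCA + allometry pipeline on the reduced sample (never a projection of the
old scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .landmarks_io import LandmarkConfiguration
from .morphospace import DEFAULT_CONFIDENCE_MULTIPLIER, MorphospaceModel, pca
from .superimposition import gpa, tangent_project

__all__ = [
    "ErrorSample",
    "AllometryResult",
    "error_distances",
    "spearman_allometry",
    "spearman_with_pvalue",
    "sensitivity_rerun",
]

EXACT_PERMUTATION_MAX_N = 10
ALPHA = 0.05


@dataclass
class ErrorSample:
    """Replicate digitizations of one specimen in PC space.

    ``replicate_distances`` are Euclidean distances of each replicate score
    vector to the replicate mean over the first P PCs;
    ``other_distances`` the same for every other specimen.  ``overlap`` is
    True when the farthest replicate reaches at least as far as the nearest
    other specimen.
    """

    specimen_id: str
    pcs: tuple[int, ...]
    replicate_scores: np.ndarray
    mean_vector: np.ndarray
    replicate_distances: np.ndarray
    other_ids: list[str]
    other_distances: np.ndarray
    overlap: bool


@dataclass(frozen=True)
class AllometryResult:
    """Spearman rank correlation of one PC's scores against centroid size."""

    pc_index: int
    r_s: float
    p_value: float
    n: int
    subset_label: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def error_distances(
    scores: np.ndarray,
    specimen_ids: list[str],
    replicate_scores: np.ndarray,
    n_pcs: int = 4,
    replicate_id: str = "error-sample",
) -> ErrorSample:
    """Euclidean distances of replicates and other specimens to the replicate mean.

    ``scores`` (n x P_model) are main-sample scores and ``replicate_scores``
    (R x P_model) the replicate digitizations projected into the same
    morphospace; distances use the first ``n_pcs`` axes only.
    """
    scores = np.asarray(scores, dtype=float)
    replicate_scores = np.asarray(replicate_scores, dtype=float)
    if replicate_scores.ndim != 2 or replicate_scores.shape[0] < 2:
        raise ValueError("need >= 2 replicate digitizations")
    if n_pcs < 1:
        raise ValueError("need at least one PC axis")
    if n_pcs > scores.shape[1] or n_pcs > replicate_scores.shape[1]:
        raise ValueError(
            f"requested first {n_pcs} PCs but score tables have "
            f"{scores.shape[1]} and {replicate_scores.shape[1]} columns"
        )
    reps = replicate_scores[:, :n_pcs]
    others = scores[:, :n_pcs]
    mean_vec = reps.mean(axis=0)
    rep_d = np.linalg.norm(reps - mean_vec, axis=1)
    other_d = np.linalg.norm(others - mean_vec, axis=1)
    return ErrorSample(
        specimen_id=replicate_id,
        pcs=tuple(range(1, n_pcs + 1)),
        replicate_scores=reps,
        mean_vector=mean_vec,
        replicate_distances=rep_d,
        other_ids=list(specimen_ids),
        other_distances=other_d,
        overlap=bool(rep_d.max() >= other_d.min()),
    )


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("rank correlation undefined: a variable is constant")
    return float(rx @ ry) / denom


def spearman_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r_s with a two-sided p-value.

    Exact permutation null (all n! orderings of one variable's ranks) for
    n <= 10; otherwise the usual t-approximation with n-2 degrees of
    freedom.  Ties are handled by midranks in both regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    r = _spearman_r(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rxc = rx - rx.mean()
        denom_x = float(rxc @ rxc)
        ryc = ry - ry.mean()
        denom = math.sqrt(denom_x * float(ryc @ ryc))
        # enumerate orderings of y's ranks in chunks to bound memory
        target = abs(r) - 1e-12
        count = 0
        total = 0
        chunk: list[tuple] = []

        def flush(chunk_list: list[tuple]) -> int:
            perm = np.array(chunk_list, dtype=float) - ry.mean()
            rs = (perm @ rxc) / denom
            return int(np.sum(np.abs(rs) >= target))

        for p in permutations(ry):
            chunk.append(p)
            if len(chunk) == 100_000:
                count += flush(chunk)
                total += len(chunk)
                chunk = []
        if chunk:
            count += flush(chunk)
            total += len(chunk)
        p_value = count / total
    else:
        if abs(r) >= 1.0:
            p_value = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p_value = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, min(1.0, p_value)


def spearman_allometry(
    scores: np.ndarray,
    sizes: np.ndarray,
    pcs: list[int] | None = None,
    subset_label: str = "",
) -> list[AllometryResult]:
    """Spearman test of each requested PC's scores against centroid size."""
    scores = np.asarray(scores, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    if scores.shape[0] != n:
        raise ValueError("scores and sizes disagree on specimen count")
    if n < 4:
        raise ValueError(f"need n >= 4 specimens, got {n}")
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.all(sizes == sizes[0]):
        raise ValueError("rank correlation undefined: all centroid sizes equal")
    if pcs is None:
        pcs = list(range(1, min(4, scores.shape[1]) + 1))
    results = []
    for pc in pcs:
        if not 1 <= pc <= scores.shape[1]:
            raise IndexError(f"PC{pc} does not exist (score table has {scores.shape[1]})")
        r, p = spearman_with_pvalue(scores[:, pc - 1], sizes)
        results.append(AllometryResult(pc_index=pc, r_s=r, p_value=p, n=n, subset_label=subset_label))
    return results


def sensitivity_rerun(
    configs: list[LandmarkConfiguration],
    drop: list[str],
    pcs: list[int] | None = None,
    subset_label: str | None = None,
    tangent: bool = True,
) -> tuple[MorphospaceModel, list[AllometryResult]]:
    """Full re-superimposition and re-PCA after dropping named specimens.

    The reduced sample is re-aligned from the raw configurations (dropping a
    specimen changes the consensus, hence every aligned shape), then PCA and
    the allometry tests are recomputed.  ``drop = []`` reproduces the full
    analysis exactly.
    """
    known = {c.specimen_id for c in configs}
    unknown = [d for d in drop if d not in known]
    if unknown:
        raise KeyError(f"unknown specimen id(s) in drop list: {unknown}")
    kept = [c for c in configs if c.specimen_id not in set(drop)]
    if len(kept) < 4:
        raise ValueError(f"dropping {len(drop)} specimens leaves {len(kept)} < 4")
    if subset_label is None:
        subset_label = f"all-{len(kept)}" if not drop else f"minus-{'-'.join(drop)}"
    ensemble = gpa(kept)
    if tangent:
        ensemble = tangent_project(ensemble)
    model = pca(ensemble)
    results = spearman_allometry(
        model.scores, ensemble.centroid_sizes, pcs=pcs, subset_label=subset_label
    )
    return model, results


def band_halfwidth_after_drop(model: MorphospaceModel, pc: int, drop_id: str) -> float:
    """Half-width of a PC's 95% band recomputed on the score set minus one
    specimen (score-level sensitivity; no re-superimposition)."""
    keep = [i for i, sid in enumerate(model.specimen_ids) if sid != drop_id]
    if len(keep) == len(model.specimen_ids):
        raise KeyError(f"unknown specimen id {drop_id!r}")
    col = model.scores[keep, pc - 1]
    return DEFAULT_CONFIDENCE_MULTIPLIER * float(col.std(ddof=1))
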