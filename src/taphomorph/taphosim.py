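"""Synthetic taphonomic-deformation simulator.

Builds a parametric, exactly bilaterally symmetric "skull" landmark template
on the packaged 56-landmark scheme, deforms it with operators idealizing the
deformation styles recurrent in crushed fossil skulls, and simulates cohorts
of specimens for pipeline validation:

* ``dorsoventral_compression`` -- z squeezed toward the mid-height plane,
  uniformly or grading in caudally from a hinge (flat-lying burial load);
* ``mediolateral_compression`` -- y squeezed toward the sagittal plane
  (side-lying burial, giving a tall narrow skull);
* ``unilateral_crush`` -- one side only pushed toward the midline, smoothly
  graded so the sagittal plane stays fixed;
* ``caudal_rotation`` -- the braincase region rigidly pitched about a
  mediolateral hinge while the rostrum is left bit-identical (the
  "undistorted rostrum" deformation style);
* ``allometric_juvenile`` -- isotropic downscaling plus a fixed
  enlarged-orbit / shortened-rostrum shape offset emulating ontogeny.

Template coordinates use +x rostro-caudal (rostrum tip near x = 0), +y
toward the left side, +z dorsal, with z = 0 at mid-height.  All geometry is
invented but placed to respect the anatomical descriptions of the scheme
(naris/orbit/fenestra rings, jugal horns at maximal |y|, squamosal and
quadrate points far caudally).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .landmarks_io import (
    LandmarkConfiguration,
    LandmarkScheme,
    SpecimenMetadata,
    default_scheme,
)
from .morphospace import MorphospaceModel
from .superimposition import optimal_rotation

__all__ = [
    "SkullTemplateParams",
    "DeformationSpec",
    "CohortSpec",
    "RecoveryReport",
    "make_template",
    "deform",
    "simulate_cohort",
    "mode_direction",
    "recovery_report",
    "DEFORMATION_MODES",
]

DEFORMATION_MODES = (
    "dorsoventral_compression",
    "mediolateral_compression",
    "unilateral_crush",
    "caudal_rotation",
    "allometric_juvenile",
)

# Right-side and midline landmark placements as fractions of (length,
# half-width, height): x in [0,1] rostral->caudal, y in [-1,0] (right side;
# mirrored to +y for the left), z in [-0.5, 0.5] about mid-height.
_RIGHT_FRACTIONS: dict[int, tuple[float, float, float]] = {
    1: (0.00, 0.0, -0.35),   # ventral rostral tip, midline
    2: (0.05, 0.0, 0.25),    # dorsal rostralmost nasal, midline
    3: (0.20, -0.15, 0.45),
    4: (0.10, -0.30, 0.00),  # naris ring
    5: (0.15, -0.30, 0.08),
    6: (0.20, -0.30, 0.00),
    7: (0.15, -0.30, -0.08),
    8: (0.37, -0.45, 0.10),  # orbit ring
    9: (0.45, -0.45, 0.22),
    10: (0.53, -0.45, 0.10),
    11: (0.45, -0.45, -0.02),
    12: (0.55, -0.40, 0.35),
    13: (0.63, -0.50, -0.05),  # lateral temporal fenestra ring
    14: (0.70, -0.50, 0.07),
    15: (0.77, -0.50, -0.05),
    16: (0.70, -0.50, -0.17),
    17: (0.50, -0.60, -0.15),
    18: (0.65, -0.55, -0.30),
    19: (0.58, -0.42, 0.30),
    20: (0.85, -0.45, 0.05),
    21: (0.85, -0.45, -0.35),
    22: (0.90, -0.45, -0.15),
    23: (0.95, -0.35, 0.25),
    24: (0.55, -1.00, -0.10),  # jugal horn: maximal |y|, flare added below
    25: (0.78, -0.20, 0.45),   # supratemporal fenestra ring
    26: (0.85, -0.10, 0.45),
    27: (0.92, -0.20, 0.45),
    28: (0.85, -0.30, 0.45),
    29: (0.85, 0.0, 0.50),   # sagittal crest, midline
    30: (0.45, 0.0, 0.48),   # frontal suture, midline
}
_ORBIT_IDS_RIGHT = (8, 9, 10, 11)
_ROSTRAL_FRACTION = 0.25  # landmarks rostral to this take the juvenile rostrum offset


@dataclass(frozen=True)
class SkullTemplateParams:
    """Dimensions (length units, defaults ~ a large adult skull in mm) and
    scheme for the synthetic template.  ``jugal_flare`` is the extra lateral
    offset of the jugal-horn landmarks as a fraction of the half-width.

    The default proportions are deliberately anisotropic (x spread > z
    spread > y spread).  Identifiability of the compression modes in shape
    space requires distinct axis spreads: for a near-isotropic template,
    dorsoventral and mediolateral compression directions are strongly
    correlated (their shape-space cosine is -sqrt(ab/((1-a)(1-b))) for z-
    and y-variance fractions a, b) and no ordination method could separate
    them -- the synthetic validation would test nothing.
    """

    scheme: LandmarkScheme = field(default_factory=default_scheme)
    length: float = 220.0
    width: float = 100.0
    height: float = 150.0
    jugal_flare: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DeformationSpec:
    """One parametric taphonomic deformation operator.

    ``magnitude`` is the compression factor c in (0, 1] for the compression
    and crush modes, the rotation angle theta (radians) for
    ``caudal_rotation``, and the isotropic scale s in (0, 1] for
    ``allometric_juvenile``.  ``hinge_fraction`` positions the rostrocaudal
    hinge (fraction of skull length) for ``caudal_rotation`` and for graded
    compression; ``falloff`` smooths spatially graded crushing.
    """

    mode: str
    magnitude: float
    side: str | None = None
    hinge_fraction: float = 0.5
    falloff: float = 0.3
    graded: bool = False
    shape_offset: float | None = None  # allometric_juvenile only; length units

    def __post_init__(self) -> None:
        if self.mode not in DEFORMATION_MODES:
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if self.mode in ("dorsoventral_compression", "mediolateral_compression",
                         "unilateral_crush", "allometric_juvenile"):
            if not 0 < self.magnitude <= 1:
                raise ValueError(f"{self.mode}: compression/scale factor must be in (0, 1]")
        if self.mode == "unilateral_crush" and self.side not in ("left", "right"):
            raise ValueError("unilateral_crush requires side 'left' or 'right'")
        if not 0 <= self.hinge_fraction <= 1:
            raise ValueError("hinge_fraction must be in [0, 1]")
        if self.falloff <= 0:
            raise ValueError("falloff must be positive")

    def label(self) -> str:
        return f"{self.mode}[{self.side}]" if self.side else self.mode


@dataclass(frozen=True)
class CohortSpec:
    """Simulation design for a cohort of deformed specimens.

    ``mode_mixture`` maps deformation mode labels (optionally
    ``unilateral_crush:left`` / ``:right``) to sampling weights;
    ``magnitude_ranges`` gives per-mode uniform sampling ranges.  Noise SDs
    are in template length units; with the default ~200 mm template the
    individual-variation SD of 1.5 is biological-scale and the digitizing
    SD of 0.5 is stylus-scale.

    ``composition`` controls how deformations combine.  ``"independent"``
    (default) treats each listed mode's weight as an application
    probability: every specimen receives each mode independently with that
    probability, composed in listing order with an independently sampled
    magnitude -- so specimens can carry combinations of deformations (a
    dorsoventrally crushed skull additionally crushed on one side) or none
    at all (an effectively undistorted specimen).  ``"exclusive"`` draws
    exactly one mode per specimen from the weights (which must then sum to
    1), emulating a cohort of cleanly distinct burial styles.
    """

    n_specimens: int = 28
    mode_mixture: dict = field(
        default_factory=lambda: {
            # application probabilities: flat-lying compaction (dorsoventral
            # load) affects most buried skulls; lateral styles are rarer
            "dorsoventral_compression": 0.60,
            "mediolateral_compression": 0.25,
            "unilateral_crush:left": 0.10,
            "unilateral_crush:right": 0.10,
            "caudal_rotation": 0.20,
        }
    )
    magnitude_ranges: dict = field(
        default_factory=lambda: {
            "dorsoventral_compression": (0.6, 1.0),
            "mediolateral_compression": (0.7, 1.0),
            "unilateral_crush": (0.6, 0.95),
            "caudal_rotation": (0.0, 0.35),
        }
    )
    individual_variation_sd: float = 1.5
    digitizing_noise_sd: float = 0.5
    n_juveniles: int = 3
    juvenile_scale_range: tuple[float, float] = (0.35, 0.55)
    composition: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composition not in ("exclusive", "independent"):
            raise ValueError("composition must be 'exclusive' or 'independent'")
        w = np.array(list(self.mode_mixture.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("mode_mixture weights must be nonnegative")
        if self.composition == "exclusive" and not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("exclusive composition requires weights summing to 1")
        if self.composition == "independent" and np.any(w > 1):
            raise ValueError("independent composition requires probabilities in [0, 1]")
        if self.individual_variation_sd < 0 or self.digitizing_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_juveniles < 0 or self.n_juveniles > self.n_specimens:
            raise ValueError("n_juveniles must be between 0 and n_specimens")


@dataclass
class RecoveryReport:
    """How well the fitted morphospace recovers the generating deformations.

    ``per_mode`` maps each generating mode label to its normalized direction
    vector in shape space, the |cosine| with every retained PC loading, and
    the best-matching PC.  ``per_specimen`` pairs each specimen's true mode
    with its PC scores.
    """

    per_mode: dict[str, dict]
    per_specimen: list[dict]

    def best_pc(self, mode_label: str) -> int:
        return self.per_mode[mode_label]["best_pc"]

    def alignment(self, mode_label: str) -> float:
        return self.per_mode[mode_label]["best_cosine"]


def make_template(params: SkullTemplateParams | None = None) -> LandmarkConfiguration:
    """Build the exactly mirror-symmetric template configuration.

    Right-side/midline landmarks are placed from the fraction table and the
    left side is produced by y -> -y, so paired landmarks satisfy
    (x, y, z) <-> (x, -y, z) exactly and midline landmarks have y = 0.
    Deterministic: the same params always give the same coordinates.
    """
    if params is None:
        params = SkullTemplateParams()
    scheme = params.scheme
    half_w = params.width / 2.0
    points: dict[int, np.ndarray] = {}
    for rid, (fx, fy, fz) in _RIGHT_FRACTIONS.items():
        if rid not in set(scheme.ids):
            continue
        y = fy * half_w
        if rid == 24:  # jugal horn flares beyond the nominal half-width
            y = -(1.0 + params.jugal_flare) * half_w
        points[rid] = np.array([fx * params.length, y, fz * params.height])
    for rid, lid in scheme.bilateral_pairs.items():
        if rid in points and lid not in points:
            x, y, z = points[rid]
            points[lid] = np.array([x, -y, z])
    missing = set(scheme.ids) - set(points)
    if missing:
        raise ValueError(f"template placement misses scheme ids {sorted(missing)}")
    return LandmarkConfiguration(
        specimen_id="template",
        points=points,
        metadata=SpecimenMetadata(
            nominal_taxon="template",
            age_class="adult",
            skull_length=params.length,
            source=f"synthetic template seed={params.seed}",
        ),
    )


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def deform(config: LandmarkConfiguration, spec: DeformationSpec) -> LandmarkConfiguration:
    """Apply one deformation operator; compose calls left-to-right for stacks.

    Identity magnitudes (c = 1, theta = 0, s = 1) return coordinates
    bit-identical to the input.
    """
    ids = sorted(config.points)
    coords = np.array([config.points[i] for i in ids], dtype=float)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    x_min, x_max = x.min(), x.max()
    span = x_max - x_min
    z_mid = (z.min() + z.max()) / 2.0
    out = coords.copy()

    if spec.mode == "dorsoventral_compression" and spec.magnitude == 1.0:
        pass  # exact identity, bit-identical output
    elif spec.mode == "allometric_juvenile" and spec.magnitude == 1.0 and not spec.shape_offset:
        pass
    elif spec.mode == "unilateral_crush" and spec.magnitude == 1.0:
        pass
    elif spec.mode == "dorsoventral_compression":
        c = spec.magnitude
        if spec.graded:
            g = _smoothstep((x - (x_min + spec.hinge_fraction * span)) / (spec.falloff * span))
        else:
            g = np.ones_like(x)
        out[:, 2] = z_mid + (z - z_mid) * (1.0 - (1.0 - c) * g)
    elif spec.mode == "mediolateral_compression":
        out[:, 1] = y * spec.magnitude
    elif spec.mode == "unilateral_crush":
        c = spec.magnitude
        half_w = float(np.abs(y).max())
        on_side = y < 0 if spec.side == "right" else y > 0
        s = _smoothstep(np.abs(y) / (spec.falloff * half_w))
        factor = np.where(on_side, 1.0 - (1.0 - c) * s, 1.0)
        out[:, 1] = y * factor
    elif spec.mode == "caudal_rotation":
        theta = spec.magnitude
        x_h = x_min + spec.hinge_fraction * span
        caudal = x > x_h
        if theta != 0.0 and np.any(caudal):
            ct, st = math.cos(theta), math.sin(theta)
            dx, dz = x[caudal] - x_h, z[caudal] - z_mid
            out[caudal, 0] = x_h + ct * dx + st * dz
            out[caudal, 2] = z_mid - st * dx + ct * dz
    elif spec.mode == "allometric_juvenile":
        s = spec.magnitude
        offset = spec.shape_offset
        if offset is None:
            # modest ontogenetic shape change: juveniles sit in a displaced
            # but nearby region of shape space, not a separate cluster
            offset = 0.06 * (1.0 - s) * span
        centroid = coords.mean(axis=0)
        out = centroid + (coords - centroid) * s
        if offset != 0.0:
            out = out + _juvenile_offset_field(ids, coords, offset)
    if config.missing:
        raise ValueError("cannot deform a configuration with missing landmarks")
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        points={i: out[k] for k, i in enumerate(ids)},
        metadata=config.metadata,
    )


def _juvenile_offset_field(ids: list[int], coords: np.ndarray, offset: float) -> np.ndarray:
    """Enlarged-orbit / shortened-rostrum displacement field (length units).

    Orbit-ring landmarks move radially out from their orbit center by
    ``offset / 2``; landmarks in the rostral quarter shift caudally by
    ``offset``.  Applied symmetrically on both sides.
    """
    scheme = default_scheme()
    orbit_sets = []
    right_orbit = [i for i in _ORBIT_IDS_RIGHT if i in ids]
    left_orbit = [scheme.bilateral_pairs[i] for i in _ORBIT_IDS_RIGHT]
    left_orbit = [i for i in left_orbit if i in ids]
    if len(right_orbit) >= 2:
        orbit_sets.append(right_orbit)
    if len(left_orbit) >= 2:
        orbit_sets.append(left_orbit)
    index = {lid: k for k, lid in enumerate(ids)}
    disp = np.zeros_like(coords)
    for ring in orbit_sets:
        rows = [index[i] for i in ring]
        center = coords[rows].mean(axis=0)
        for row in rows:
            radial = coords[row] - center
            norm = np.linalg.norm(radial)
            if norm > 0:
                disp[row] += 0.5 * offset * radial / norm
    x = coords[:, 0]
    x_min = x.min()
    span = x.max() - x_min
    rostral = x < x_min + _ROSTRAL_FRACTION * span
    disp[rostral, 0] += offset
    return disp


def _spec_from_label(label: str, mag: float) -> DeformationSpec:
    mode, _, side = label.partition(":")
    if mode == "caudal_rotation":
        return DeformationSpec(mode=mode, magnitude=mag, hinge_fraction=0.5)
    if mode == "unilateral_crush":
        return DeformationSpec(mode=mode, magnitude=mag, side=side or "left")
    return DeformationSpec(mode=mode, magnitude=mag)


def _draw_specs(cohort: CohortSpec, rng: np.random.Generator) -> list[DeformationSpec]:
    labels = list(cohort.mode_mixture)
    if cohort.composition == "exclusive":
        weights = np.array([cohort.mode_mixture[m] for m in labels], dtype=float)
        labels = [labels[rng.choice(len(labels), p=weights / weights.sum())]]
    else:  # independent Bernoulli application per mode
        labels = [m for m in labels if rng.random() < cohort.mode_mixture[m]]
    specs = []
    for label in labels:
        mode = label.partition(":")[0]
        lo, hi = cohort.magnitude_ranges[mode]
        specs.append(_spec_from_label(label, float(rng.uniform(lo, hi))))
    return specs


def simulate_cohort(
    template: LandmarkConfiguration, cohort: CohortSpec
) -> list[LandmarkConfiguration]:
    """Simulate a cohort: deform the template, add noise, record the truth.

    Each specimen draws one deformation from the mixture; juveniles (the
    first ``n_juveniles``) are first downscaled with the allometric offset.
    Individual variation then digitizing noise are added as independent
    isotropic Gaussians per landmark.  The true mode, magnitudes and seed
    are recorded in the metadata (``nominal_taxon`` carries the mode label,
    ``source`` a JSON truth record).  Fully reproducible from the seed.
    """
    if cohort.n_specimens < 3:
        raise ValueError(f"need >= 3 specimens, got {cohort.n_specimens}")
    rng = np.random.default_rng(cohort.seed)
    configs: list[LandmarkConfiguration] = []
    k = len(template.points)
    for i in range(cohort.n_specimens):
        juvenile = i < cohort.n_juveniles
        working = template
        truth: dict = {"seed": cohort.seed, "index": i}
        if juvenile:
            s = float(rng.uniform(*cohort.juvenile_scale_range))
            jspec = DeformationSpec(mode="allometric_juvenile", magnitude=s)
            working = deform(working, jspec)
            truth["juvenile_scale"] = s
        dspecs = _draw_specs(cohort, rng)
        for dspec in dspecs:
            working = deform(working, dspec)
        truth.update(
            {
                "mode": "+".join(d.label() for d in dspecs) or "undeformed",
                "modes": [d.label() for d in dspecs],
                "magnitudes": {d.label(): d.magnitude for d in dspecs},
                "age_class": "juvenile" if juvenile else "adult",
            }
        )
        ids = sorted(working.points)
        coords = np.array([working.points[j] for j in ids])
        coords = coords + rng.normal(0.0, cohort.individual_variation_sd, size=(k, 3))
        coords = coords + rng.normal(0.0, cohort.digitizing_noise_sd, size=(k, 3))
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"sim{i + 1:03d}",
                points={j: coords[r] for r, j in enumerate(ids)},
                metadata=SpecimenMetadata(
                    nominal_taxon=truth["mode"],
                    age_class="juvenile" if juvenile else "adult",
                    skull_length=float(coords[:, 0].max() - coords[:, 0].min()),
                    source=json.dumps(truth, sort_keys=True),
                ),
            )
        )
    return configs


_REFERENCE_MAGNITUDES = {
    "dorsoventral_compression": 0.7,
    "mediolateral_compression": 0.8,
    "unilateral_crush": 0.7,
    "caudal_rotation": 0.25,
    "allometric_juvenile": 0.45,
}


def mode_direction(
    template: LandmarkConfiguration,
    spec: DeformationSpec,
    mean_shape: np.ndarray,
    landmark_ids: tuple[int, ...],
) -> np.ndarray:
    """Unit shape-space direction of a deformation mode, in the frame of
    ``mean_shape``.

    The template and its deformed copy are centered, scaled to unit centroid
    size and rotated into the mean-shape frame; their difference, with the
    component along the consensus direction removed (matching the tangent
    projection applied before PCA), is normalized to a unit 3K vector.
    """

    def unit(coords: np.ndarray) -> np.ndarray:
        c = coords - coords.mean(axis=0)
        return c / np.sqrt(np.sum(c**2))

    t = unit(template.as_array(landmark_ids))
    mean = np.asarray(mean_shape, dtype=float)
    t_al = t @ optimal_rotation(t, mean)
    d = unit(deform(template, spec).as_array(landmark_ids))
    d_al = d @ optimal_rotation(d, t_al)
    diff = (d_al - t_al).ravel()
    c_hat = mean.ravel() / np.linalg.norm(mean.ravel())
    diff = diff - (diff @ c_hat) * c_hat
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("deformation spec produces no shape change")
    return diff / norm


def recovery_report(
    template: LandmarkConfiguration,
    cohort_configs: list[LandmarkConfiguration],
    model: MorphospaceModel,
    n_pcs: int | None = None,
) -> RecoveryReport:
    """Score how the fitted PCs align with the generating deformation modes.

    For every deformation mode present in the cohort's truth records, the
    mode's shape-space direction (at a fixed reference magnitude) is
    compared with each retained PC loading by |cosine|; the argmax PC and
    its |cosine| summarize recovery.  Requires truth metadata written by
    :func:`simulate_cohort`.
    """
    truths = []
    for cfg in cohort_configs:
        try:
            truths.append(json.loads(cfg.metadata.source))
        except (json.JSONDecodeError, TypeError):
            raise ValueError(
                f"specimen {cfg.specimen_id!r} lacks simulation truth metadata"
            ) from None
    if n_pcs is None:
        n_pcs = min(4, model.n_components)
    labels = sorted({lab for t in truths for lab in t.get("modes", [t["mode"]])})
    per_mode: dict[str, dict] = {}
    for label in labels:
        mode, _, side = label.rstrip("]").partition("[")
        spec = DeformationSpec(
            mode=mode,
            magnitude=_REFERENCE_MAGNITUDES[mode],
            side=side or None,
        )
        direction = mode_direction(template, spec, model.mean_shape, model.landmark_ids)
        cosines = np.abs(model.loadings[:n_pcs] @ direction)
        best = int(np.argmax(cosines))
        per_mode[label] = {
            "direction": direction,
            "cosines": cosines,
            "best_pc": best + 1,
            "best_cosine": float(cosines[best]),
        }
    per_specimen = [
        {
            "specimen_id": cfg.specimen_id,
            "true_mode": truth["mode"],
            "age_class": truth["age_class"],
            "scores": model.scores[i, :n_pcs].tolist(),
        }
        for i, (cfg, truth) in enumerate(zip(cohort_configs, truths))
    ]
    return RecoveryReport(per_mode=per_mode, per_specimen=per_specimen)
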