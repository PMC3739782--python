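"""End-to-end analysis pipeline: filter -> GPA -> PCA -> bands -> reports.

This is the library form of the command line's ``run`` command.  Given a
:class:`PipelineConfig` it produces a deterministic report bundle on disk:
aligned coordinates, variance table, scores, confidence bands, outlier
report, optional error-sample distances, allometry results per configured
subset, wireframe OBJ exports and a run log.  Every run writes a manifest
naming the configuration hash so outputs are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .error_allometry import error_distances, sensitivity_rerun, spearman_allometry
from .landmarks_io import (
    LandmarkConfiguration,
    LandmarkScheme,
    apply_exclusions,
    default_scheme,
    read_landmarks,
    read_scheme,
    write_landmarks,
)
from .morphospace import (
    MorphospaceModel,
    confidence_bands,
    export_wireframe_obj,
    flag_outliers,
    pca,
    project_configuration,
    reconstruct_shape,
    select_components,
    variance_table,
)
from .superimposition import AlignedEnsemble, gpa, optimal_rotation, tangent_project

__all__ = ["PipelineConfig", "run_pipeline", "project_replicates", "default_wireframe"]

log = logging.getLogger("taphomorph")

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; YAML-serializable."""

    input_path: str = ""
    dialect: str = "csv"
    scheme_path: str | None = None  # None -> packaged psittacosaur scheme
    apply_exclusion_list: bool = True
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 200
    tangent: bool = True
    component_rule: str = "fixed_k"  # or "broken_stick"
    fixed_k: int = 4
    confidence_multiplier: float = 1.96
    error_sample_path: str | None = None
    error_sample_dialect: str = "csv"
    allometry_pcs: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    drop_subsets: dict[str, list[str]] = field(default_factory=dict)
    wireframe_path: str | None = None
    output_dir: str = "taphomorph_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.confidence_multiplier <= 0:
            raise ValueError("confidence_multiplier must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_wireframe(landmark_ids: tuple[int, ...]) -> list[tuple[int, int]]:
    """A basic skull wireframe as (landmark_id, landmark_id) edges.

    Connects the midline chain, the naris/orbit/temporal-fenestra rings on
    each side and the jugal/quadrate outline; edges whose landmarks are not
    retained are silently dropped.
    """
    rings = [
        (4, 5, 6, 7), (32, 33, 34, 35),       # nares
        (8, 9, 10, 11), (36, 37, 38, 39),     # orbits
        (13, 14, 15, 16), (41, 42, 43, 44),   # lateral temporal fenestrae
        (25, 26, 27, 28), (53, 54, 55, 56),   # supratemporal fenestrae
    ]
    chains = [
        (1, 2, 3, 30, 29),      # rostrum -> skull roof midline (right nasal)
        (1, 2, 31, 30),         # left nasal branch
        (2, 4), (2, 32),        # nasal to nares
        (3, 9), (31, 37),       # nasal height to orbit roof
        (30, 9), (30, 37),      # frontal suture to orbits
        (10, 12, 13), (38, 40, 41),  # postorbital bar
        (11, 24, 16), (39, 52, 44),  # jugal horn triangles
        (14, 19), (42, 47),     # temporal roof
        (15, 20, 22, 23), (43, 48, 50, 51),  # quadrate/squamosal outline
        (29, 27), (29, 55), (23, 28), (51, 56),
    ]
    edges: list[tuple[int, int]] = []
    for ring in rings:
        for a, b in zip(ring, ring[1:] + ring[:1]):
            edges.append((a, b))
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            edges.append((a, b))
    present = set(landmark_ids)
    return [(a, b) for a, b in edges if a in present and b in present]


def read_wireframe(path: str | Path) -> list[tuple[int, int]]:
    """Read a wireframe-connectivity file: one ``id id`` pair per line."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two landmark ids")
        edges.append((int(parts[0]), int(parts[1])))
    return edges


def project_replicates(
    ensemble: AlignedEnsemble, model: MorphospaceModel, replicates: list[LandmarkConfiguration]
) -> np.ndarray:
    """Project replicate digitizations into an existing morphospace.

    Each replicate is restricted to the model's landmark set, centered,
    scaled to unit centroid size, rotated onto the ensemble consensus and
    (if the ensemble was tangent-projected) projected onto the tangent
    plane, then expressed in PC scores.  The main-sample model is untouched.
    """
    scores = []
    c_flat = ensemble.consensus.ravel()
    c_norm = float(np.linalg.norm(c_flat))
    c_hat = c_flat / c_norm
    for rep in replicates:
        coords = rep.restrict(model.landmark_ids).as_array(model.landmark_ids)
        coords = coords - coords.mean(axis=0)
        coords = coords / np.sqrt(np.sum(coords**2))
        coords = coords @ optimal_rotation(coords, ensemble.consensus)
        flat = coords.ravel()
        if ensemble.tangent_projected:
            flat = flat - (flat @ c_hat - c_norm) * c_hat
        scores.append(project_configuration(model, flat.reshape(-1, 3)))
    return np.array(scores)


def _df_aligned(ensemble: AlignedEnsemble) -> pd.DataFrame:
    rows = []
    for sid, coords in zip(ensemble.specimen_ids, ensemble.aligned):
        for lid, (x, y, z) in zip(ensemble.landmark_ids, coords):
            rows.append((sid, lid, x, y, z))
    return pd.DataFrame(rows, columns=["specimen", "landmark_id", "x", "y", "z"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Returns a summary dict (also written as ``summary.json``).  Deterministic
    for a fixed config: rerunning produces byte-identical outputs.
    """
    out = Path(config.output_dir)
    scheme = _load_scheme(config)
    if not Path(config.input_path).exists():
        raise FileNotFoundError(f"input landmark file not found: {config.input_path}")
    if config.error_sample_path and not Path(config.error_sample_path).exists():
        raise FileNotFoundError(f"error-sample file not found: {config.error_sample_path}")

    out.mkdir(parents=True, exist_ok=True)
    _setup_run_log(out / "run.log")
    log.info("taphomorph %s | config hash %s", __version__, config.config_hash())

    configs = read_landmarks(config.input_path, config.dialect)
    log.info("read %d specimens from %s (%s dialect)", len(configs), config.input_path, config.dialect)

    if config.apply_exclusion_list:
        configs, report = apply_exclusions(configs, scheme)
        log.info(
            "exclusions: %d/%d landmarks retained; %d/%d specimens retained",
            report["n_retained_landmarks"], report["n_scheme_landmarks"],
            report["n_retained_specimens"], report["n_input_specimens"],
        )
    else:
        report = {"applied": False}
    (out / "exclusion_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    ensemble = gpa(configs, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
    log.info("GPA converged=%s after %d iterations", ensemble.converged, ensemble.iterations)
    if config.tangent:
        ensemble = tangent_project(ensemble)
        log.info("tangent projection applied")
    model = pca(ensemble)
    k = select_components(model, rule=config.component_rule, fixed_k=config.fixed_k)
    log.info("PCA: %d non-null PCs; %d retained by rule %s", model.n_components, k, config.component_rule)

    _df_aligned(ensemble).to_csv(out / "aligned.csv", index=False, float_format=_FLOAT_FMT)
    consensus_cfg = LandmarkConfiguration(
        specimen_id="consensus",
        points={lid: ensemble.consensus[i] for i, lid in enumerate(ensemble.landmark_ids)},
    )
    write_landmarks([consensus_cfg], out / "consensus.csv", "csv")
    pd.DataFrame(
        {"specimen": ensemble.specimen_ids, "centroid_size": ensemble.centroid_sizes}
    ).to_csv(out / "centroid_sizes.csv", index=False, float_format=_FLOAT_FMT)
    variance_table(model).to_csv(out / "variance_table.csv", index=False, float_format=_FLOAT_FMT)
    model.scores_frame().to_csv(out / "scores.csv", float_format=_FLOAT_FMT)

    pcs = list(range(1, min(max(k, 1), model.n_components) + 1))
    bands = confidence_bands(model, pcs, multiplier=config.confidence_multiplier)
    pd.DataFrame([vars(b) for b in bands]).to_csv(
        out / "confidence_bands.csv", index=False, float_format=_FLOAT_FMT
    )
    outliers = flag_outliers(model, bands)
    (out / "outliers.json").write_text(
        json.dumps(
            {"per_pc": {str(p): ids for p, ids in outliers.per_pc.items()},
             "per_specimen": outliers.per_specimen},
            indent=2, sort_keys=True,
        ) + "\n"
    )
    for pc, ids in outliers.per_pc.items():
        log.info("PC%d outliers outside %.3g-sigma band: %s", pc, config.confidence_multiplier, ids or "none")

    wf_ids = (
        read_wireframe(config.wireframe_path)
        if config.wireframe_path
        else default_wireframe(ensemble.landmark_ids)
    )
    id_to_row = {lid: i + 1 for i, lid in enumerate(ensemble.landmark_ids)}
    wf_rows = [(id_to_row[a], id_to_row[b]) for a, b in wf_ids]
    for pc in pcs:
        sd = float(np.sqrt(model.eigenvalues[pc - 1]))
        for sign, tag in ((-3.0, "neg"), (3.0, "pos")):
            shape = reconstruct_shape(model, pc, sign * sd)
            export_wireframe_obj(shape, wf_rows, out / f"wireframe_pc{pc}_{tag}.obj")

    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_specimens": ensemble.n_specimens,
        "n_landmarks": ensemble.n_landmarks,
        "gpa_iterations": ensemble.iterations,
        "gpa_converged": ensemble.converged,
        "n_components": model.n_components,
        "k_retained": k,
        "first_k_cumulative_pct": float(model.cumulative[min(k, model.n_components) - 1] * 100)
        if k >= 1
        else 0.0,
        "outlier_specimens": outliers.flagged_specimens(),
    }

    if config.error_sample_path:
        reps = read_landmarks(config.error_sample_path, config.error_sample_dialect)
        reps = [r.restrict(ensemble.landmark_ids) for r in reps]
        rep_scores = project_replicates(ensemble, model, reps)
        n_err_pcs = min(4, model.n_components)
        err = error_distances(model.scores, model.specimen_ids, rep_scores, n_pcs=n_err_pcs)
        pd.DataFrame(
            {
                "specimen": [f"replicate_{i + 1}" for i in range(len(err.replicate_distances))]
                + err.other_ids,
                "kind": ["replicate"] * len(err.replicate_distances) + ["sample"] * len(err.other_ids),
                "distance": np.concatenate([err.replicate_distances, err.other_distances]),
            }
        ).to_csv(out / "error_distances.csv", index=False, float_format=_FLOAT_FMT)
        summary["error_overlap"] = err.overlap
        log.info("error protocol: overlap=%s", err.overlap)

    allometry_frames = []
    base = spearman_allometry(
        model.scores, ensemble.centroid_sizes,
        pcs=[p for p in config.allometry_pcs if p <= model.n_components],
        subset_label=f"all-{ensemble.n_specimens}",
    )
    allometry_frames.append(pd.DataFrame([vars(r) for r in base]))
    for label, drop in sorted(config.drop_subsets.items()):
        _, res = sensitivity_rerun(
            configs, drop,
            pcs=[p for p in config.allometry_pcs if p <= model.n_components],
            subset_label=label, tangent=config.tangent,
        )
        allometry_frames.append(pd.DataFrame([vars(r) for r in res]))
        log.info("subset %s (n=%d) allometry recomputed", label, len(configs) - len(drop))
    pd.concat(allometry_frames, ignore_index=True).to_csv(
        out / "allometry.csv", index=False, float_format=_FLOAT_FMT
    )
    summary["allometry"] = [vars(r) for r in base]

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "config": asdict(config),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _teardown_run_log()
    return summary


def _load_scheme(config: PipelineConfig) -> LandmarkScheme:
    if config.scheme_path is None:
        return default_scheme()
    p = Path(config.scheme_path)
    if not p.exists():
        raise FileNotFoundError(f"scheme file not found: {p}")
    return read_scheme(p)


_run_handler: logging.Handler | None = None


def _setup_run_log(path: Path) -> None:
    global _run_handler
    _teardown_run_log()
    if path.exists():
        path.unlink()  # keep reruns byte-identical
    _run_handler = logging.FileHandler(path)
    _run_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(_run_handler)
    log.setLevel(logging.INFO)


def _teardown_run_log() -> None:
    global _run_handler
    if _run_handler is not None:
        log.removeHandler(_run_handler)
        _run_handler.close()
        _run_handler = None
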