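"""Landmark dataset I/O, the landmark scheme, and exclusion filtering.

A *landmark* is a named, homologous 3D point digitized on every specimen
(e.g. "Ventral tip of the rostral on midline").  Datasets are exchanged in
three text dialects common in geometric morphometrics:

* ``morphologika`` -- count headers (``$specimens``/``$landmarks``), a
  ``$names`` block, and per-specimen coordinate blocks;
* ``tps`` -- ``LM3=K`` records followed by ``x y z`` rows and an ``ID=`` line;
* ``csv`` -- long format with columns ``specimen,landmark_id,x,y,z``
  (``NA`` marks a missing landmark).

The canonical in-memory form is :class:`LandmarkConfiguration`; a
:class:`LandmarkScheme` carries anatomical labels, bilateral left/right
pairing, midline membership and the not-retained flag used by
:func:`apply_exclusions`.
"""

from __future__ import annotations

import csv as _csvmod
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LandmarkScheme",
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "ParseError",
    "ExclusionError",
    "default_scheme",
    "read_scheme",
    "read_landmarks",
    "write_landmarks",
    "apply_exclusions",
    "centroid_size",
    "reference_values",
]

_MISSING_SENTINELS = {"", "na", "nan", "n/a", "missing", "9999", "-9999"}


class ParseError(ValueError):
    """A landmark file could not be parsed; the message names the line."""


class ExclusionError(ValueError):
    """Exclusion filtering left nothing to analyse."""


@dataclass(frozen=True)
class SpecimenMetadata:
    """Nominal taxon, age class and size information for one specimen."""

    nominal_taxon: str = ""
    age_class: str = "adult"
    skull_length: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.age_class not in ("juvenile", "adult"):
            raise ValueError(f"age_class must be 'juvenile' or 'adult', got {self.age_class!r}")


@dataclass(frozen=True)
class LandmarkScheme:
    """Ordered landmark ids with anatomy, bilateral pairing and exclusions.

    ``bilateral_pairs`` is stored symmetrically (both directions present);
    ``midline_ids`` lie on the sagittal plane and are never paired.
    """

    landmarks: tuple[tuple[int, str], ...]
    bilateral_pairs: Mapping[int, int] = field(default_factory=dict)
    excluded_ids: frozenset[int] = frozenset()
    midline_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.landmarks]
        if len(ids) != len(set(ids)):
            raise ValueError("landmark ids must be unique")
        if ids != sorted(ids):
            raise ValueError("landmark ids must be in increasing order")
        idset = set(ids)
        for a, b in self.bilateral_pairs.items():
            if a == b:
                raise ValueError(f"landmark {a} paired with itself")
            if self.bilateral_pairs.get(b) != a:
                raise ValueError(f"bilateral pair {a}<->{b} is not symmetric")
            if a not in idset or b not in idset:
                raise ValueError(f"pair {a}<->{b} references an unknown id")
        if not set(self.excluded_ids) <= idset:
            raise ValueError("excluded_ids must be a subset of the scheme ids")
        if set(self.midline_ids) & set(self.bilateral_pairs):
            raise ValueError("midline landmarks cannot be members of bilateral pairs")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.landmarks)

    @property
    def retained_ids(self) -> tuple[int, ...]:
        return tuple(i for i in self.ids if i not in self.excluded_ids)

    def description(self, landmark_id: int) -> str:
        for i, d in self.landmarks:
            if i == landmark_id:
                return d
        raise KeyError(landmark_id)

    def subset(self, keep: Iterable[int]) -> "LandmarkScheme":
        """Scheme restricted to ``keep`` (order preserved; pairs pruned)."""
        keep = set(keep)
        lms = tuple((i, d) for i, d in self.landmarks if i in keep)
        pairs = {a: b for a, b in self.bilateral_pairs.items() if a in keep and b in keep}
        return LandmarkScheme(
            landmarks=lms,
            bilateral_pairs=pairs,
            excluded_ids=frozenset(self.excluded_ids & keep),
            midline_ids=frozenset(self.midline_ids & keep),
        )


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D landmark coordinates with a missing-data mask."""

    specimen_id: str
    points: dict[int, np.ndarray]
    missing: set[int] = field(default_factory=set)
    metadata: SpecimenMetadata = field(default_factory=SpecimenMetadata)

    def __post_init__(self) -> None:
        pts = {}
        for k, v in self.points.items():
            a = np.asarray(v, dtype=float)
            if a.shape != (3,) or not np.all(np.isfinite(a)):
                raise ValueError(
                    f"specimen {self.specimen_id!r}: landmark {k} must be a finite 3-vector"
                )
            pts[int(k)] = a
        self.points = pts
        self.missing = {int(m) for m in self.missing}
        if self.missing & set(self.points):
            raise ValueError("a landmark cannot be both present and missing")

    @property
    def landmark_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.points) | self.missing))

    def as_array(self, ids: Sequence[int] | None = None) -> np.ndarray:
        """K x 3 coordinate array in the order of ``ids`` (default: sorted present ids)."""
        if ids is None:
            ids = sorted(self.points)
        try:
            return np.array([self.points[i] for i in ids], dtype=float)
        except KeyError as exc:
            raise KeyError(
                f"specimen {self.specimen_id!r} is missing landmark {exc.args[0]}"
            ) from None

    def restrict(self, ids: Iterable[int]) -> "LandmarkConfiguration":
        keep = set(ids)
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            points={i: p.copy() for i, p in self.points.items() if i in keep},
            missing=self.missing & keep,
            metadata=self.metadata,
        )


# ---------------------------------------------------------------------------
# scheme I/O


def read_scheme(path: str | Path) -> LandmarkScheme:
    """Read a landmark scheme from CSV (columns id,description,pair,midline,excluded)."""
    path = Path(path)
    landmarks: list[tuple[int, str]] = []
    pairs: dict[int, int] = {}
    midline: set[int] = set()
    excluded: set[int] = set()
    with path.open(newline="") as fh:
        for lineno, row in enumerate(_csvmod.DictReader(fh), start=2):
            try:
                lid = int(row["id"])
            except (KeyError, TypeError, ValueError):
                raise ParseError(f"{path}:{lineno}: bad or missing landmark id") from None
            landmarks.append((lid, (row.get("description") or "").strip()))
            if row.get("pair"):
                pairs[lid] = int(row["pair"])
            if row.get("midline") and int(row["midline"]):
                midline.add(lid)
            if row.get("excluded") and int(row["excluded"]):
                excluded.add(lid)
    return LandmarkScheme(
        landmarks=tuple(landmarks),
        bilateral_pairs=pairs,
        excluded_ids=frozenset(excluded),
        midline_ids=frozenset(midline),
    )


def default_scheme() -> LandmarkScheme:
    """The packaged 56-landmark psittacosaur skull scheme (44 retained)."""
    with resources.as_file(
        resources.files("taphomorph.data").joinpath("psittacosaur_scheme.csv")
    ) as p:
        return read_scheme(p)


def reference_values() -> dict:
    """Published reference values (eigenvalue table, CI half-widths, counts)."""
    text = resources.files("taphomorph.data").joinpath("psittacosaur_reference.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# landmark dataset I/O

_DIALECTS = ("morphologika", "tps", "csv")


def read_landmarks(path: str | Path, dialect: str = "csv") -> list[LandmarkConfiguration]:
    """Read landmark configurations from ``path`` in the named dialect."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = path.read_text()
    reader = {"morphologika": _read_morphologika, "tps": _read_tps, "csv": _read_csv}[dialect]
    configs = reader(text, str(path))
    counts = {len(c.landmark_ids) for c in configs}
    if len(counts) > 1:
        raise ParseError(f"{path}: inconsistent landmark counts across specimens: {sorted(counts)}")
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration], path: str | Path, dialect: str = "csv"
) -> None:
    """Write configurations to ``path``; decimal text round-trips bit-exactly."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    writer = {"morphologika": _write_morphologika, "tps": _write_tps, "csv": _write_csv}[dialect]
    path.write_text(writer(configs))


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_float(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{where}: non-numeric coordinate {token!r}") from None


def _read_csv(text: str, name: str) -> list[LandmarkConfiguration]:
    by_spec: dict[str, LandmarkConfiguration] = {}
    rows = _csvmod.reader(text.splitlines())
    header = next(rows, None)
    if header is None or [h.strip().lower() for h in header[:5]] != [
        "specimen",
        "landmark_id",
        "x",
        "y",
        "z",
    ]:
        raise ParseError(f"{name}:1: malformed header (expected specimen,landmark_id,x,y,z)")
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 5:
            raise ParseError(f"{name}:{lineno}: expected 5 columns, got {len(row)}")
        spec, lid_s, xs, ys, zs = (c.strip() for c in row[:5])
        try:
            lid = int(lid_s)
        except ValueError:
            raise ParseError(f"{name}:{lineno}: bad landmark id {lid_s!r}") from None
        cfg = by_spec.setdefault(
            spec, LandmarkConfiguration(specimen_id=spec, points={}, missing=set())
        )
        if any(v.lower() in _MISSING_SENTINELS for v in (xs, ys, zs)):
            cfg.missing.add(lid)
        else:
            cfg.points[lid] = np.array(
                [_parse_float(v, f"{name}:{lineno}") for v in (xs, ys, zs)]
            )
    if not by_spec:
        raise ParseError(f"{name}: no specimens found")
    return list(by_spec.values())


def _write_csv(configs: Sequence[LandmarkConfiguration]) -> str:
    lines = ["specimen,landmark_id,x,y,z"]
    for cfg in configs:
        for lid in cfg.landmark_ids:
            if lid in cfg.missing:
                lines.append(f"{cfg.specimen_id},{lid},NA,NA,NA")
            else:
                x, y, z = cfg.points[lid]
                lines.append(f"{cfg.specimen_id},{lid},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    return "\n".join(lines) + "\n"


def _read_morphologika(text: str, name: str) -> list[LandmarkConfiguration]:
    lines = text.splitlines()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$"):
            current = line[1:].strip().lower()
            sections[current] = []
        elif current is None:
            raise ParseError(f"{name}:{lineno}: content before any $section header")
        else:
            sections[current].append((lineno, line))
    for required in ("specimens", "landmarks", "rawpoints"):
        if required not in sections:
            raise ParseError(f"{name}: malformed header: missing ${required} section")
    try:
        n_spec = int(sections["specimens"][0][1])
        n_lm = int(sections["landmarks"][0][1])
    except (IndexError, ValueError):
        raise ParseError(f"{name}: malformed $specimens/$landmarks count") from None
    names = [v for _, v in sections.get("names", [])]
    if names and len(names) != n_spec:
        raise ParseError(f"{name}: $names lists {len(names)} names for {n_spec} specimens")

    configs: list[LandmarkConfiguration] = []
    cur: LandmarkConfiguration | None = None
    next_lid = 1
    for lineno, line in sections["rawpoints"]:
        if line.startswith("'"):
            cur = LandmarkConfiguration(specimen_id=line[1:].strip(), points={}, missing=set())
            configs.append(cur)
            next_lid = 1
            continue
        if cur is None:
            raise ParseError(f"{name}:{lineno}: coordinates before any 'specimen label")
        tokens = line.split()
        if len(tokens) != 3:
            raise ParseError(f"{name}:{lineno}: expected 3 coordinates, got {len(tokens)}")
        if all(t.lower() in _MISSING_SENTINELS for t in tokens):
            cur.missing.add(next_lid)
        else:
            cur.points[next_lid] = np.array(
                [_parse_float(t, f"{name}:{lineno}") for t in tokens]
            )
        next_lid += 1
    if len(configs) != n_spec:
        raise ParseError(f"{name}: header promises {n_spec} specimens, found {len(configs)}")
    for cfg in configs:
        if len(cfg.landmark_ids) != n_lm:
            raise ParseError(
                f"{name}: specimen {cfg.specimen_id!r} has {len(cfg.landmark_ids)} landmarks, "
                f"header promises {n_lm}"
            )
    if names:
        for cfg, nm in zip(configs, names):
            cfg.specimen_id = nm if cfg.specimen_id in ("", nm) else cfg.specimen_id
    return configs


def _write_morphologika(configs: Sequence[LandmarkConfiguration]) -> str:
    n_lm = len(configs[0].landmark_ids) if configs else 0
    out = ["$specimens", str(len(configs)), "$landmarks", str(n_lm), "$names"]
    out += [c.specimen_id for c in configs]
    out.append("$rawpoints")
    for cfg in configs:
        out.append(f"'{cfg.specimen_id}")
        for lid in cfg.landmark_ids:
            if lid in cfg.missing:
                out.append("9999 9999 9999")
            else:
                out.append(" ".join(_fmt(v) for v in cfg.points[lid]))
    return "\n".join(out) + "\n"


def _read_tps(text: str, name: str) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    cur_points: list[np.ndarray | None] = []
    expect = 0
    cur_id = ""
    pending = False

    def flush(lineno: int) -> None:
        nonlocal pending
        if not pending:
            return
        if len(cur_points) != expect:
            raise ParseError(
                f"{name}:{lineno}: LM3={expect} but {len(cur_points)} coordinate rows"
            )
        pts = {i + 1: p for i, p in enumerate(cur_points) if p is not None}
        missing = {i + 1 for i, p in enumerate(cur_points) if p is None}
        configs.append(
            LandmarkConfiguration(
                specimen_id=cur_id or f"specimen_{len(configs) + 1}",
                points=pts,
                missing=missing,
            )
        )
        pending = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            flush(lineno)
            try:
                expect = int(line[4:])
            except ValueError:
                raise ParseError(f"{name}:{lineno}: malformed header {line!r}") from None
            cur_points, cur_id, pending = [], "", True
        elif upper.startswith("ID="):
            cur_id = line[3:].strip()
        elif upper.startswith(("IMAGE=", "SCALE=")):
            continue
        elif pending:
            tokens = line.split()
            if len(tokens) != 3:
                raise ParseError(f"{name}:{lineno}: expected 3 coordinates, got {len(tokens)}")
            if all(t.lower() in _MISSING_SENTINELS for t in tokens):
                cur_points.append(None)
            else:
                cur_points.append(
                    np.array([_parse_float(t, f"{name}:{lineno}") for t in tokens])
                )
        else:
            raise ParseError(f"{name}:{lineno}: unexpected content {line!r}")
    flush(len(text.splitlines()))
    if not configs:
        raise ParseError(f"{name}: no LM3 records found")
    return configs


def _write_tps(configs: Sequence[LandmarkConfiguration]) -> str:
    out: list[str] = []
    for cfg in configs:
        ids = cfg.landmark_ids
        out.append(f"LM3={len(ids)}")
        for lid in ids:
            if lid in cfg.missing:
                out.append("9999 9999 9999")
            else:
                out.append(" ".join(_fmt(v) for v in cfg.points[lid]))
        out.append(f"ID={cfg.specimen_id}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# filtering and size


def apply_exclusions(
    configs: Sequence[LandmarkConfiguration], scheme: LandmarkScheme
) -> tuple[list[LandmarkConfiguration], dict]:
    """Drop excluded landmarks everywhere, then drop specimens still incomplete.

    Landmarks flagged in ``scheme.excluded_ids`` are removed from every
    configuration.  Any specimen that is missing one of the *retained*
    landmarks after that is dropped (trading landmarks for specimens is the
    scheme author's call, recorded in the exclusion flags, not done here).
    Returns the retained configurations and a JSON-serializable report.
    """
    retained_ids = scheme.retained_ids
    if not retained_ids:
        raise ExclusionError("exclusion list removes every landmark in the scheme")
    kept: list[LandmarkConfiguration] = []
    dropped: list[dict] = []
    for cfg in configs:
        sub = cfg.restrict(retained_ids)
        absent = [i for i in retained_ids if i not in sub.points]
        if absent:
            dropped.append({"specimen_id": cfg.specimen_id, "missing_landmarks": absent})
        else:
            kept.append(sub)
    if not kept:
        raise ExclusionError("every specimen is missing at least one retained landmark")
    report = {
        "n_input_specimens": len(configs),
        "n_retained_specimens": len(kept),
        "n_scheme_landmarks": len(scheme.ids),
        "n_retained_landmarks": len(retained_ids),
        "excluded_landmarks": sorted(scheme.excluded_ids),
        "dropped_specimens": dropped,
    }
    return kept, report


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard geometric-morphometric size measure; invariant to rotation
    and translation, linear under isotropic scaling.
    """
    if isinstance(config, LandmarkConfiguration):
        if config.missing:
            raise ValueError(
                f"specimen {config.specimen_id!r} has missing landmarks "
                f"{sorted(config.missing)}; centroid size is undefined"
            )
        coords = config.as_array()
    else:
        coords = np.asarray(config, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))
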