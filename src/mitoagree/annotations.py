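"""Data model and file I/O for multi-observer point annotations.

Annotations are point marks (pixel coordinates, 0-based, x = column,
y = row, origin top-left, sub-pixel values allowed) placed by an observer
on mitotic figures within one tumor region.  A study is a collection of
cases, each annotated by one or more observers.

The on-disk format is a CSV with columns ``case_id, observer_id, x_px,
y_px``.  A row with blank coordinates is an explicit empty marker: it
records that the observer examined the case and found zero mitoses, which
is distinct from the observer being absent for that case.  This
distinction matters because the Dice coefficient of two empty annotation
sets is defined as 1.

Per-case physical metadata (region area in mm^2, resolution in um/pixel)
lives in a sidecar CSV keyed by case_id, with study-wide defaults of
2.0 mm^2 and 0.25 um/pixel.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PointAnnotation",
    "CaseAnnotations",
    "StudyDataset",
    "CaseMetadata",
    "AnnotationFormatError",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "filter_cases",
]

DEFAULT_REGION_AREA_MM2 = 2.0
DEFAULT_UM_PER_PIXEL = 0.25

ANNOTATION_COLUMNS = ("case_id", "observer_id", "x_px", "y_px")
METADATA_COLUMNS = ("case_id", "region_area_mm2", "um_per_pixel")


class AnnotationFormatError(ValueError):
    """Raised for malformed annotation or metadata files."""


@dataclass(frozen=True)
class PointAnnotation:
    """A single point mark: ``x`` is the column, ``y`` the row, in pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y)):
            if not math.isfinite(v):
                raise ValueError(f"coordinate {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"coordinate {name} must be non-negative, got {v!r}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class CaseMetadata:
    """Physical metadata for one case's counting region."""

    region_area_mm2: float = DEFAULT_REGION_AREA_MM2
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL

    def __post_init__(self) -> None:
        if self.region_area_mm2 <= 0:
            raise ValueError("region_area_mm2 must be > 0")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")


@dataclass
class CaseAnnotations:
    """One observer's point annotations for one case.

    ``count`` is the mitotic count C for this (case, observer) pair: the
    number of point marks.  An instance with zero points is a valid,
    explicit "zero mitoses seen" record.
    """

    case_id: str
    observer_id: str
    points: list[PointAnnotation] = field(default_factory=list)
    region_area_mm2: float = DEFAULT_REGION_AREA_MM2
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL

    def __post_init__(self) -> None:
        if self.region_area_mm2 <= 0:
            raise ValueError("region_area_mm2 must be > 0")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")
        self.points = [
            p if isinstance(p, PointAnnotation) else PointAnnotation(*p)
            for p in self.points
        ]

    @property
    def count(self) -> int:
        return len(self.points)

    def coords(self) -> list[tuple[float, float]]:
        return [p.as_tuple() for p in self.points]


@dataclass
class StudyDataset:
    """All annotations of a study: ``cases[case_id][observer_id]``."""

    cases: dict[str, dict[str, CaseAnnotations]] = field(default_factory=dict)
    observers: list[str] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def case_ids(self) -> list[str]:
        return sorted(self.cases)

    def add(self, ann: CaseAnnotations) -> None:
        self.cases.setdefault(ann.case_id, {})[ann.observer_id] = ann
        if ann.observer_id not in self.observers:
            self.observers.append(ann.observer_id)

    def get(self, case_id: str, observer_id: str) -> CaseAnnotations:
        try:
            return self.cases[case_id][observer_id]
        except KeyError:
            raise KeyError(
                f"no annotations for observer {observer_id!r} in case {case_id!r}"
            ) from None

    def counts(self, observer_id: str) -> dict[str, int]:
        """Per-case mitotic counts for one observer (cases where present)."""
        return {
            cid: obs[observer_id].count
            for cid, obs in self.cases.items()
            if observer_id in obs
        }


def _parse_coord(raw: str, column: str, line_no: int) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise AnnotationFormatError(
            f"line {line_no}: non-numeric {column} value {raw!r}"
        ) from None
    return value


def read_metadata(path: str | Path) -> dict[str, CaseMetadata]:
    """Read the sidecar metadata CSV (case_id, region_area_mm2, um_per_pixel)."""
    path = Path(path)
    out: dict[str, CaseMetadata] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for col in METADATA_COLUMNS:
            if col not in fields:
                raise AnnotationFormatError(
                    f"metadata file {path} is missing required column {col!r}"
                )
        for line_no, row in enumerate(reader, start=2):
            out[row["case_id"]] = CaseMetadata(
                region_area_mm2=_parse_coord(
                    row["region_area_mm2"], "region_area_mm2", line_no
                ),
                um_per_pixel=_parse_coord(row["um_per_pixel"], "um_per_pixel", line_no),
            )
    return out


def write_metadata(metadata: Mapping[str, CaseMetadata], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for case_id in sorted(metadata):
            md = metadata[case_id]
            writer.writerow([case_id, repr(md.region_area_mm2), repr(md.um_per_pixel)])
    return path


def read_annotations(
    path: str | Path,
    metadata: str | Path | Mapping[str, CaseMetadata] | None = None,
) -> StudyDataset:
    """Read an annotations CSV into a :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV with header ``case_id, observer_id, x_px, y_px``.  Rows with
        blank ``x_px`` and ``y_px`` are empty markers ("zero mitoses").
    metadata
        Optional sidecar metadata: a path to a metadata CSV or a mapping
        ``case_id -> CaseMetadata``.  Cases absent from the metadata fall
        back to the study-wide defaults (2.0 mm^2, 0.25 um/pixel).
    """
    path = Path(path)
    if metadata is None:
        meta: Mapping[str, CaseMetadata] = {}
    elif isinstance(metadata, (str, Path)):
        meta = read_metadata(metadata)
    else:
        meta = metadata

    dataset = StudyDataset()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for col in ANNOTATION_COLUMNS:
            if col not in fields:
                raise AnnotationFormatError(
                    f"annotations file {path} is missing required column {col!r}"
                )
        for line_no, row in enumerate(reader, start=2):
            case_id = row["case_id"]
            observer_id = row["observer_id"]
            md = meta.get(case_id, CaseMetadata())
            if case_id not in dataset.cases or observer_id not in dataset.cases[case_id]:
                dataset.add(
                    CaseAnnotations(
                        case_id,
                        observer_id,
                        [],
                        region_area_mm2=md.region_area_mm2,
                        um_per_pixel=md.um_per_pixel,
                    )
                )
            x_raw = (row["x_px"] or "").strip()
            y_raw = (row["y_px"] or "").strip()
            if not x_raw and not y_raw:
                continue  # explicit empty marker
            if not x_raw or not y_raw:
                raise AnnotationFormatError(
                    f"line {line_no}: one of x_px/y_px is blank; blank both "
                    "for an empty marker or neither for a point"
                )
            point = PointAnnotation(
                _parse_coord(x_raw, "x_px", line_no),
                _parse_coord(y_raw, "y_px", line_no),
            )
            dataset.cases[case_id][observer_id].points.append(point)
    return dataset


def _format_coord(v: float) -> str:
    # repr round-trips floats exactly; integers print without trailing .0 noise
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_annotations(dataset: StudyDataset, path: str | Path) -> Path:
    """Write a dataset to CSV, re-readable by :func:`read_annotations`.

    Row order is deterministic: sorted by (case_id, observer_id), points
    in stored order.  An empty :class:`CaseAnnotations` becomes a single
    row with blank coordinates so it survives a round trip.
    """
    if not dataset.cases:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for case_id in sorted(dataset.cases):
            for observer_id in sorted(dataset.cases[case_id]):
                ann = dataset.cases[case_id][observer_id]
                if not ann.points:
                    writer.writerow([case_id, observer_id, "", ""])
                for p in ann.points:
                    writer.writerow(
                        [case_id, observer_id, _format_coord(p.x), _format_coord(p.y)]
                    )
    return path


def filter_cases(
    dataset: StudyDataset,
    required_observers: Iterable[str],
    min_mean_count: float | None = None,
) -> StudyDataset:
    """Keep cases annotated by every required observer.

    With ``min_mean_count`` set, additionally require the mean count over
    the required observers to be strictly greater than the threshold
    (used e.g. to restrict to cases with average count > 6).
    """
    required = list(required_observers)
    if not required:
        raise ValueError("required_observers must not be empty")
    unknown = [o for o in required if o not in dataset.observers]
    if unknown:
        raise ValueError(f"unknown observer id(s): {unknown}")
    kept = StudyDataset(observers=list(dataset.observers))
    for case_id in sorted(dataset.cases):
        obs_map = dataset.cases[case_id]
        if not all(o in obs_map for o in required):
            continue
        if min_mean_count is not None:
            mean_count = sum(obs_map[o].count for o in required) / len(required)
            if not mean_count > min_mean_count:
                continue
        kept.cases[case_id] = dict(obs_map)
    return kept
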