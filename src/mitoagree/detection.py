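"""Probability-map post-processing for automatic mitosis detection.

A detector emits a per-pixel probability map over the tumor region.
Point detections are the local maxima whose value strictly exceeds an
operating threshold (default 0.85).  Plateaus — connected regions of
equal maximal value — yield a single detection at their centroid.  The
operating threshold itself can be selected on a validation set by
scanning a grid and maximizing the pooled Dice coefficient between
extracted detections and reference annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotations import StudyDataset
from .dice import dice_from_counts
from .matching import DEFAULT_TOLERANCE_PX, match_points

__all__ = [
    "ProbabilityMap",
    "DetectionConfig",
    "extract_detections",
    "select_operating_point",
    "read_probability_map",
    "write_probability_map",
]

DEFAULT_THRESHOLD = 0.85


@dataclass
class ProbabilityMap:
    """2-D detector output grid with values in [0, 1]."""

    values: np.ndarray
    case_id: str = ""
    um_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a nonempty 2-D grid")
        if not np.isfinite(v).all():
            raise ValueError("probability map contains non-finite values")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")
        self.values = v


@dataclass(frozen=True)
class DetectionConfig:
    """Detection-extraction settings.

    ``threshold``: minimum (exclusive) peak value; ``connectivity``:
    4- or 8-neighborhood for the local-maximum test; ``min_separation``:
    if > 0, detections closer than this many pixels are merged keeping
    the higher-valued one (0 disables).
    """

    threshold: float = DEFAULT_THRESHOLD
    connectivity: int = 8
    min_separation: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


def _footprint(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    fp = np.zeros((3, 3), dtype=bool)
    fp[1, :] = True
    fp[:, 1] = True
    return fp


def extract_detections(
    pmap: ProbabilityMap, config: DetectionConfig | None = None
) -> list[tuple[float, float]]:
    """Extract point detections as (x, y) local maxima above threshold.

    A pixel is a local maximum when no neighbor (under the configured
    connectivity) has a larger value; connected equal-valued maxima form
    a plateau and contribute one detection at the plateau centroid.  Only
    maxima with value strictly greater than the threshold are kept.
    """
    config = config or DetectionConfig()
    v = pmap.values
    fp = _footprint(config.connectivity)
    local_max = v >= ndimage.maximum_filter(v, footprint=fp, mode="nearest")
    mask = local_max & (v > config.threshold)
    if not mask.any():
        return []
    structure = fp  # plateau connectivity matches the maximum test
    labels, n_labels = ndimage.label(mask, structure=structure)
    centroids = ndimage.center_of_mass(mask, labels, range(1, n_labels + 1))
    peak_values = ndimage.maximum(v, labels, range(1, n_labels + 1))
    detections = [
        (float(col), float(row), float(val))
        for (row, col), val in zip(centroids, np.atleast_1d(peak_values))
    ]
    if config.min_separation > 0:
        detections = _merge_close(detections, config.min_separation)
    detections.sort(key=lambda d: (-d[2], d[0], d[1]))
    return [(x, y) for x, y, _ in detections]


def _merge_close(
    detections: list[tuple[float, float, float]], min_separation: float
) -> list[tuple[float, float, float]]:
    """Greedy non-maximum suppression: keep higher-valued detections."""
    ordered = sorted(detections, key=lambda d: (-d[2], d[0], d[1]))
    kept: list[tuple[float, float, float]] = []
    for x, y, val in ordered:
        if all(
            (x - kx) ** 2 + (y - ky) ** 2 >= min_separation**2
            for kx, ky, _ in kept
        ):
            kept.append((x, y, val))
    return kept


def select_operating_point(
    maps: Sequence[ProbabilityMap],
    references: StudyDataset,
    observer_id: str | None = None,
    grid: Sequence[float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE_PX,
    config: DetectionConfig | None = None,
) -> tuple[float, float]:
    """Choose the detection threshold that maximizes pooled Dice.

    For every threshold in ``grid`` (default 0.50 to 0.99 step 0.01),
    detections are extracted from all maps and matched against the
    reference annotations of ``observer_id`` (required when the dataset
    has several observers); the pooled Dice over cases is the selection
    criterion.  Ties go to the lowest threshold.  Returns
    ``(threshold, pooled_dice)``.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.995, 0.01), 2)
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    if any(not 0 < t < 1 for t in grid):
        raise ValueError("thresholds must lie in (0, 1)")
    if observer_id is None:
        if len(references.observers) != 1:
            raise ValueError(
                "observer_id is required when references contain several observers"
            )
        observer_id = references.observers[0]
    ref_points = {}
    for pmap in maps:
        if pmap.case_id not in references.cases or observer_id not in references.cases[
            pmap.case_id
        ]:
            raise ValueError(
                f"no reference annotations for case {pmap.case_id!r} "
                f"(observer {observer_id!r})"
            )
        ref_points[pmap.case_id] = references.get(pmap.case_id, observer_id).coords()

    base = config or DetectionConfig()
    best_threshold, best_dice = None, -1.0
    for t in grid:
        cfg = DetectionConfig(
            threshold=t,
            connectivity=base.connectivity,
            min_separation=base.min_separation,
        )
        n_det = n_ref = n_shared = 0
        for pmap in maps:
            det = extract_detections(pmap, cfg)
            ref = ref_points[pmap.case_id]
            m = match_points(det, ref, tolerance)
            n_det += len(det)
            n_ref += len(ref)
            n_shared += m.n_matched
        d = dice_from_counts(n_det, n_ref, n_shared)
        if d > best_dice:  # strict: ties keep the lowest threshold
            best_threshold, best_dice = t, d
    return (float(best_threshold), float(best_dice))


def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> Path:
    """Write a probability map.

    ``.csv``/``.txt`` write a delimited text grid with full float
    precision (bit-exact round trip); ``.png`` writes 16-bit grayscale
    (value scaled by 65535, quantized).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        np.savetxt(path, pmap.values, delimiter=",", fmt="%.17g")
    elif suffix == ".png":
        from PIL import Image

        quantized = np.round(pmap.values * 65535).astype(np.uint16)
        Image.fromarray(quantized).save(path)
    else:
        raise ValueError(f"unsupported probability-map format: {suffix!r}")
    return path


def read_probability_map(
    path: str | Path, case_id: str = "", um_per_pixel: float = 0.25
) -> ProbabilityMap:
    """Read a probability map written by :func:`write_probability_map`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    elif suffix == ".png":
        from PIL import Image

        values = np.asarray(Image.open(path), dtype=float) / 65535.0
    else:
        raise ValueError(f"unsupported probability-map format: {suffix!r}")
    return ProbabilityMap(values, case_id=case_id or path.stem, um_per_pixel=um_per_pixel)
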