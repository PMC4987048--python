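"""Dice similarity statistics for object-level agreement.

The Dice similarity coefficient between two annotation sets A and B is

    D = 2 |A∩B| / (|A| + |B|)

where |A∩B| is the number of matched objects under the distance tolerance.
D ranges from 0 (no shared objects) to 1 (identical sets); the Dice
coefficient of two empty sets is defined as 1, so agreement on "no mitoses
here" counts as perfect agreement.

D is reported pooled over the whole study (counts and shared counts summed
over cases before forming the ratio) and per individual case.  Confidence
intervals come from a case-level percentile bootstrap: whole cases are
resampled with replacement, which respects the within-case clustering of
objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .annotations import StudyDataset
from .matching import DEFAULT_TOLERANCE_PX, match_points

__all__ = [
    "DiceResult",
    "BootstrapSpec",
    "dice_from_counts",
    "case_match_triples",
    "pooled_dice",
    "per_case_dice",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Case-resampling bootstrap settings for percentile intervals."""

    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class DiceResult:
    """Dice coefficient with the counts behind it and an optional CI."""

    value: float
    n_a: int
    n_b: int
    n_shared: int
    ci: tuple[float, float] | None = None


def dice_from_counts(n_a: int, n_b: int, n_shared: int) -> float:
    """Dice coefficient from set sizes and the shared-object count.

    Returns ``2 * n_shared / (n_a + n_b)``, and 1.0 when both sets are
    empty (perfect agreement on absence).
    """
    if n_a < 0 or n_b < 0 or n_shared < 0:
        raise ValueError("counts must be non-negative")
    if n_shared > min(n_a, n_b):
        raise ValueError(
            f"n_shared={n_shared} exceeds min(n_a, n_b)={min(n_a, n_b)}"
        )
    if n_a + n_b == 0:
        return 1.0
    return 2.0 * n_shared / (n_a + n_b)


def case_match_triples(
    dataset: StudyDataset,
    obs_a: str,
    obs_b: str,
    tolerance: float = DEFAULT_TOLERANCE_PX,
) -> list[tuple[str, int, int, int]]:
    """Per-case (case_id, |A|, |B|, |A∩B|) triples for one observer pair."""
    triples = []
    for case_id in dataset.case_ids():
        obs_map = dataset.cases[case_id]
        for obs in (obs_a, obs_b):
            if obs not in obs_map:
                raise ValueError(
                    f"observer {obs!r} has no annotations for case {case_id!r}"
                )
        a = obs_map[obs_a].coords()
        b = obs_map[obs_b].coords()
        m = match_points(a, b, tolerance)
        triples.append((case_id, len(a), len(b), m.n_matched))
    return triples


def _pooled_value(triples: Sequence[tuple[int, int, int]]) -> float:
    n_a = sum(t[0] for t in triples)
    n_b = sum(t[1] for t in triples)
    n_shared = sum(t[2] for t in triples)
    return dice_from_counts(n_a, n_b, n_shared)


def _median_case_value(triples: Sequence[tuple[int, int, int]]) -> float:
    return float(np.median([dice_from_counts(*t) for t in triples]))


_STATISTICS: dict[str, Callable] = {
    "pooled_dice": _pooled_value,
    "median_case_dice": _median_case_value,
}


def bootstrap_ci(
    triples: Sequence[tuple[int, int, int]],
    statistic: str | Callable[[Sequence[tuple[int, int, int]]], float],
    spec: BootstrapSpec,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a Dice statistic, resampling whole cases.

    ``triples`` are per-case (|A|, |B|, |A∩B|) records; ``statistic`` is
    ``"pooled_dice"``, ``"median_case_dice"`` or any callable mapping a
    resampled triple list to a number.  Deterministic for a given seed.
    """
    if len(triples) < 2:
        raise ValueError("bootstrap requires at least 2 cases")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    arr = np.asarray([(t[-3], t[-2], t[-1]) for t in triples], dtype=int)
    n = len(arr)
    rng = np.random.default_rng(spec.seed)
    replicates = np.empty(spec.n_boot)
    for k in range(spec.n_boot):
        idx = rng.integers(0, n, n)
        replicates[k] = stat([tuple(row) for row in arr[idx]])
    alpha = 1.0 - spec.level
    low, high = np.quantile(replicates, [alpha / 2, 1 - alpha / 2])
    return (float(low), float(high))


def _bootstrap_fast_pooled(
    arr: np.ndarray, spec: BootstrapSpec
) -> tuple[float, float]:
    # vectorized pooled-Dice bootstrap: resample case indices, sum columns
    n = len(arr)
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, (spec.n_boot, n))
    sums = arr[idx].sum(axis=1)  # (n_boot, 3): n_a, n_b, n_shared
    denom = sums[:, 0] + sums[:, 1]
    values = np.where(denom > 0, 2.0 * sums[:, 2] / np.maximum(denom, 1), 1.0)
    alpha = 1.0 - spec.level
    low, high = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return (float(low), float(high))


def pooled_dice(
    dataset: StudyDataset,
    obs_a: str,
    obs_b: str,
    tolerance: float = DEFAULT_TOLERANCE_PX,
    ci_spec: BootstrapSpec | None = None,
) -> DiceResult:
    """Study-wide Dice for an observer pair: counts summed over cases.

    With ``ci_spec`` given, attaches a case-level percentile bootstrap CI.
    """
    triples = case_match_triples(dataset, obs_a, obs_b, tolerance)
    counts = [(na, nb, ns) for _, na, nb, ns in triples]
    n_a = sum(c[0] for c in counts)
    n_b = sum(c[1] for c in counts)
    n_shared = sum(c[2] for c in counts)
    ci = None
    if ci_spec is not None:
        ci = _bootstrap_fast_pooled(np.asarray(counts, dtype=int), ci_spec)
    return DiceResult(
        value=dice_from_counts(n_a, n_b, n_shared),
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        ci=ci,
    )


def per_case_dice(
    dataset: StudyDataset,
    obs_a: str,
    obs_b: str,
    tolerance: float = DEFAULT_TOLERANCE_PX,
) -> list[tuple[str, DiceResult]]:
    """Dice per individual case (empty-vs-empty cases score 1)."""
    out = []
    for case_id, n_a, n_b, n_shared in case_match_triples(
        dataset, obs_a, obs_b, tolerance
    ):
        out.append(
            (
                case_id,
                DiceResult(
                    value=dice_from_counts(n_a, n_b, n_shared),
                    n_a=n_a,
                    n_b=n_b,
                    n_shared=n_shared,
                ),
            )
        )
    return out
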