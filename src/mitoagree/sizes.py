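"""Physical-size comparison of low- vs high-agreement objects.

Objects annotated by only one observer ("poor agreement") tend to be
smaller mitotic figures than objects all observers marked ("good
agreement") — small figures are easy to miss when scanning a slide and
their identifying features are harder to judge.  This module groups
consensus objects by the number of annotating observers and compares the
group mean lengths (largest cross-section, in um) with a two-sample
t-test (Welch by default).

Lengths are consumed as data, from a measurement file or the simulator;
measuring objects in image pixels is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .matching import ConsensusObject

__all__ = [
    "MeasuredObject",
    "SizeComparison",
    "assign_agreement_groups",
    "compare_sizes",
]


@dataclass(frozen=True)
class MeasuredObject:
    """A consensus object with its measured length."""

    object_id: int
    length_um: float
    n_observers: int
    detected_by_automatic: bool = False

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be > 0")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")


@dataclass(frozen=True)
class SizeComparison:
    """Two-sample t-test summary of poor- vs good-agreement lengths."""

    mean_poor: float
    mean_good: float
    t_statistic: float
    p_value: float
    n_poor: int
    n_good: int
    equal_var: bool = False


def assign_agreement_groups(
    objects: Sequence[ConsensusObject],
    sizes: Mapping[int, float],
    n_total_observers: int,
    automatic_ids: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[MeasuredObject], list[MeasuredObject]]:
    """Split consensus objects into poor- and good-agreement groups.

    Poor agreement: annotated by exactly one observer.  Good agreement:
    annotated by all ``n_total_observers``.  Objects in between are
    excluded.  ``sizes`` maps object_id to length in um and must cover
    every grouped object.  ``automatic_ids`` names member ids that are
    automatic detectors rather than human observers; membership of those
    sets the ``detected_by_automatic`` flag and does not count toward
    ``n_observers``.
    """
    poor: list[MeasuredObject] = []
    good: list[MeasuredObject] = []
    for obj in objects:
        human_members = [o for o in obj.member_points if o not in automatic_ids]
        n_obs = len(human_members)
        if n_obs not in (1, n_total_observers) or n_obs == 0:
            continue
        if obj.object_id not in sizes:
            raise KeyError(f"no size measurement for object {obj.object_id}")
        measured = MeasuredObject(
            object_id=obj.object_id,
            length_um=float(sizes[obj.object_id]),
            n_observers=n_obs,
            detected_by_automatic=any(o in automatic_ids for o in obj.member_points),
        )
        if n_obs == 1:
            poor.append(measured)
        if n_obs == n_total_observers:
            good.append(measured)
    return poor, good


def _lengths(group: Sequence) -> np.ndarray:
    vals = [
        g.length_um if isinstance(g, MeasuredObject) else float(g) for g in group
    ]
    return np.asarray(vals, dtype=float)


def compare_sizes(
    poor: Sequence,
    good: Sequence,
    equal_var: bool = False,
) -> SizeComparison:
    """Two-sided two-sample t-test of group mean lengths.

    Accepts lengths in um or :class:`MeasuredObject` lists.  Welch
    (unequal variance) by default; set ``equal_var=True`` for the
    pooled-variance variant.
    """
    a, b = _lengths(poor), _lengths(good)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 measurements")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return SizeComparison(
        mean_poor=float(a.mean()),
        mean_good=float(b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_poor=len(a),
        n_good=len(b),
        equal_var=equal_var,
    )
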