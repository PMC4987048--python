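"""Object correspondence between point annotations under a distance tolerance.

Two marks denote the same physical object when their Euclidean distance is
strictly below a tolerance radius — by default 30 pixels, i.e. 7.5 um at
0.25 um/pixel, roughly the size of a mitotic figure.  Correspondence is
established as an optimal one-to-one assignment: among all matchings whose
pair distances are below the tolerance, the one with the maximum number of
pairs is chosen, and among those the one with the smallest total distance.
This makes the shared-object count |A∩B| well defined, symmetric in the two
observers, and verifiable against brute-force enumeration.

``build_consensus`` extends pairwise matching to any number of observers by
greedily clustering marks into physical objects (at most one mark per
observer per object), which underlies the poor/good-agreement grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .annotations import PointAnnotation

__all__ = [
    "DEFAULT_TOLERANCE_PX",
    "MatchResult",
    "ConsensusObject",
    "match_points",
    "shared_count",
    "build_consensus",
]

DEFAULT_TOLERANCE_PX = 30.0


def _as_coords(points: Sequence) -> np.ndarray:
    """Coerce a sequence of PointAnnotation / (x, y) pairs to an (n, 2) array."""
    if len(points) == 0:
        return np.empty((0, 2), dtype=float)
    rows = []
    for p in points:
        if isinstance(p, PointAnnotation):
            rows.append((p.x, p.y))
        else:
            x, y = p
            rows.append((float(x), float(y)))
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one correspondence between two point sets under a tolerance.

    ``pairs`` holds (index_in_a, index_in_b, distance_px) triples sorted by
    index_in_a; every pair distance is strictly below ``tolerance``.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    tolerance: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


def match_points(
    a: Sequence,
    b: Sequence,
    tolerance: float = DEFAULT_TOLERANCE_PX,
) -> MatchResult:
    """Optimally match two point sets one-to-one under a distance tolerance.

    Only pairs with Euclidean distance strictly less than ``tolerance``
    may be matched (a pair at exactly the tolerance does not match).  The
    returned matching maximizes the number of matched pairs and, among
    matchings of maximal cardinality, minimizes the total matched
    distance.  Deterministic; empty inputs are valid.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    pa, pb = _as_coords(a), _as_coords(b)
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        return MatchResult(
            pairs=(),
            unmatched_a=tuple(range(na)),
            unmatched_b=tuple(range(nb)),
            tolerance=float(tolerance),
        )

    dist = cdist(pa, pb)
    feasible = dist < tolerance
    # Penalty large enough that one extra feasible pair always beats any
    # saving in matched distance: every feasible distance is < tolerance.
    penalty = (min(na, nb) + 1.0) * tolerance
    cost = np.where(feasible, dist, penalty)
    rows, cols = linear_sum_assignment(cost)

    pairs = []
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            pairs.append((int(i), int(j), float(dist[i, j])))
    pairs.sort()
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_a=tuple(i for i in range(na) if i not in matched_a),
        unmatched_b=tuple(j for j in range(nb) if j not in matched_b),
        tolerance=float(tolerance),
    )


def shared_count(m: MatchResult) -> int:
    """Number of objects both observers annotated: |A∩B| = number of pairs."""
    return m.n_matched


@dataclass(frozen=True)
class ConsensusObject:
    """A physical object reconstructed from multiple observers' marks.

    ``n_observers`` is how many observers annotated the object — the
    quantity behind poor (1 observer) vs good (all observers) agreement
    groups.
    """

    object_id: int
    member_points: Mapping[str, PointAnnotation]
    centroid: tuple[float, float]

    @property
    def n_observers(self) -> int:
        return len(self.member_points)


def build_consensus(
    annotations: Mapping[str, Sequence],
    tolerance: float = DEFAULT_TOLERANCE_PX,
) -> list[ConsensusObject]:
    """Cluster per-observer point annotations into physical objects.

    Observers are processed in sorted id order.  Each observer's points
    are assigned (optimal one-to-one matching under ``tolerance``) to the
    running cluster centroids; matched points join their cluster and the
    centroid is recomputed as the mean of member points, unmatched points
    seed new clusters.  Every input point ends up in exactly one object,
    and an object holds at most one point per observer.

    Returns objects sorted by descending ``n_observers``, then centroid.
    """
    if not annotations:
        raise ValueError("at least one observer required")
    clusters: list[dict] = []  # {"members": {obs: PointAnnotation}, "centroid": (x, y)}

    def _centroid(members: dict[str, PointAnnotation]) -> tuple[float, float]:
        xs = [p.x for p in members.values()]
        ys = [p.y for p in members.values()]
        return (float(np.mean(xs)), float(np.mean(ys)))

    for observer_id in sorted(annotations):
        coords = _as_coords(annotations[observer_id])
        points = [PointAnnotation(float(x), float(y)) for x, y in coords]
        open_clusters = [c for c in clusters if observer_id not in c["members"]]
        centroids = [c["centroid"] for c in open_clusters]
        m = match_points([p.as_tuple() for p in points], centroids, tolerance)
        matched_points = set()
        for ip, ic, _ in m.pairs:
            cluster = open_clusters[ic]
            cluster["members"][observer_id] = points[ip]
            cluster["centroid"] = _centroid(cluster["members"])
            matched_points.add(ip)
        for ip, p in enumerate(points):
            if ip not in matched_points:
                clusters.append({"members": {observer_id: p}, "centroid": p.as_tuple()})

    clusters.sort(key=lambda c: (-len(c["members"]), c["centroid"]))
    return [
        ConsensusObject(
            object_id=i,
            member_points=dict(c["members"]),
            centroid=c["centroid"],
        )
        for i, c in enumerate(clusters)
    ]
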