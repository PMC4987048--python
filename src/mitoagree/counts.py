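"""Count- and score-level agreement statistics.

The mitotic count per 2 mm^2 (mitotic activity index) is discretized into
the three-bin mitotic activity score used in breast-cancer grading:
score 1 for 0-6 mitoses, score 2 for 7-12, score 3 for more than 12.
Score agreement between observer pairs is summarized by 3x3 confusion
matrices and the quadratic-weighted Cohen's kappa, whose weights
``w_ij = 1 - (i-j)^2 / (k-1)^2`` penalize two-point score discrepancies
(score 1 vs score 3 — the clinically serious errors) four times as hard
as one-point ones.

Count agreement is summarized by Bland-Altman analysis on log10-scaled
counts: the mean paired difference b measures systematic bias, and the
limits of agreement b ± 1.96·sd bracket ~95% of the paired differences.
Counts are right-skewed, hence the log transform; the +1 offset keeps
zero counts finite while preserving ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SCORE_BIN_EDGES",
    "ScoreConfusion",
    "KappaResult",
    "BlandAltmanResult",
    "mitotic_score",
    "normalized_count",
    "confusion",
    "quadratic_weighted_kappa",
    "two_point_discrepancies",
    "bland_altman_log",
]

N_SCORES = 3
SCORE_BIN_EDGES = (6, 12)  # score 1: <= 6, score 2: 7..12, score 3: > 12


def normalized_count(count: float, region_area_mm2: float = 2.0) -> float:
    """Rescale a raw count to the standard 2 mm^2 reference area."""
    if region_area_mm2 <= 0:
        raise ValueError("region_area_mm2 must be > 0")
    return count * 2.0 / region_area_mm2


def mitotic_score(count: float) -> int:
    """Mitotic activity score from a count per 2 mm^2.

    0-6 mitoses -> 1, 7-12 -> 2, more than 12 -> 3.  Counts normalized
    from a non-standard region area may be fractional; binning uses the
    same edges.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if count <= SCORE_BIN_EDGES[0]:
        return 1
    if count <= SCORE_BIN_EDGES[1]:
        return 2
    return 3


@dataclass(frozen=True)
class ScoreConfusion:
    """3x3 score confusion matrix; entry (i, j) counts cases scored i by
    the row observer and j by the column observer (scores 1..3)."""

    matrix: np.ndarray
    row_observer: str = "a"
    col_observer: str = "b"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.shape != (N_SCORES, N_SCORES):
            raise ValueError(f"matrix must be 3x3, got shape {m.shape}")
        if (m < 0).any():
            raise ValueError("matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    row_observer: str = "a",
    col_observer: str = "b",
) -> ScoreConfusion:
    """Tally paired per-case scores into a 3x3 confusion matrix."""
    if len(scores_a) != len(scores_b):
        raise ValueError(
            f"score lists differ in length: {len(scores_a)} vs {len(scores_b)}"
        )
    m = np.zeros((N_SCORES, N_SCORES), dtype=int)
    for sa, sb in zip(scores_a, scores_b):
        if not (1 <= sa <= N_SCORES and 1 <= sb <= N_SCORES):
            raise ValueError(f"scores must be in 1..{N_SCORES}, got ({sa}, {sb})")
        m[sa - 1, sb - 1] += 1
    return ScoreConfusion(m, row_observer, col_observer)


@dataclass(frozen=True)
class KappaResult:
    """Quadratic-weighted Cohen's kappa with optional bootstrap CI.

    ``undefined`` is set when chance agreement is perfect (degenerate
    marginals), where kappa has no value; ``kappa`` is then NaN.
    """

    kappa: float
    ci: tuple[float, float] | None = None
    undefined: bool = False
    weighting: str = "quadratic"


def _weighted_kappa_value(m: np.ndarray) -> float:
    n = m.sum()
    i, j = np.indices((N_SCORES, N_SCORES))
    w = 1.0 - (i - j) ** 2 / (N_SCORES - 1) ** 2
    p_obs = (w * m).sum() / n
    expected = np.outer(m.sum(axis=1), m.sum(axis=0)) / n**2
    p_exp = (w * expected).sum()
    if np.isclose(1.0 - p_exp, 0.0):
        return float("nan")
    return float((p_obs - p_exp) / (1.0 - p_exp))


def quadratic_weighted_kappa(
    m: ScoreConfusion, ci_spec=None
) -> KappaResult:
    """Quadratic-weighted Cohen's kappa from a score confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with agreement weights
    ``w_ij = 1 - (i-j)^2/(k-1)^2`` applied to the observed matrix (p_o)
    and to the product of its marginals (p_e).  When both marginals are
    concentrated so that 1 - p_e = 0, kappa is undefined and flagged.

    ``ci_spec`` (a :class:`mitoagree.dice.BootstrapSpec`) attaches a
    case-level percentile bootstrap CI, resampling the scored cases with
    replacement (equivalently, a multinomial resample of the matrix
    cells).
    """
    mat = m.matrix
    if mat.sum() == 0:
        raise ValueError("confusion matrix is empty")
    value = _weighted_kappa_value(mat.astype(float))
    if np.isnan(value):
        return KappaResult(kappa=float("nan"), undefined=True)
    ci = None
    if ci_spec is not None:
        rng = np.random.default_rng(ci_spec.seed)
        n = int(mat.sum())
        probs = (mat / n).ravel()
        reps = []
        for _ in range(ci_spec.n_boot):
            resampled = rng.multinomial(n, probs).reshape(N_SCORES, N_SCORES)
            reps.append(_weighted_kappa_value(resampled.astype(float)))
        reps = np.asarray(reps)
        reps = reps[~np.isnan(reps)]
        alpha = 1.0 - ci_spec.level
        low, high = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        ci = (float(low), float(high))
    return KappaResult(kappa=value, ci=ci)


def two_point_discrepancies(m: ScoreConfusion) -> int:
    """Cases where the two observers' scores differ by two points
    (score 1 vs score 3) — the clinically serious disagreements."""
    return int(m.matrix[0, 2] + m.matrix[2, 0])


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and limits of agreement on log10(x+1) counts."""

    mean_difference: float
    la_low: float
    la_high: float
    n: int
    transform: str = "log10(x+1)"


def bland_altman_log(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired counts on the log10(x+1) scale.

    Differences ``d_i = log10(a_i + 1) - log10(b_i + 1)`` give the mean
    difference b and limits of agreement b ± 1.96·sd (sample sd, n-1).
    """
    if len(counts_a) != len(counts_b):
        raise ValueError(
            f"count lists differ in length: {len(counts_a)} vs {len(counts_b)}"
        )
    if len(counts_a) < 2:
        raise ValueError("need at least 2 paired counts")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    d = np.log10(a + 1.0) - np.log10(b + 1.0)
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean_diff,
        la_low=mean_diff - 1.96 * sd,
        la_high=mean_diff + 1.96 * sd,
        n=len(d),
    )
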