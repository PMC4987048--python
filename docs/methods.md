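# Methods

## Point matching

Two marks refer to the same physical object when their Euclidean
distance is strictly less than a tolerance radius; the default of
30 pixels (7.5 μm at 0.25 μm/pixel) corresponds to the typical size of a
mitotic figure. Coordinates are 0-based with x = column, y = row, origin
top-left, and may be sub-pixel; μm inputs should be converted to pixels
via the case resolution before matching.

A shared-object count |A∩B| needs a *matching rule*, not just a distance
rule. `match_points` computes the optimal one-to-one assignment — first
maximizing the number of matched pairs among pairs under the tolerance,
then minimizing the total matched distance — via the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`) on a cost matrix in which
infeasible pairs carry a penalty of `(min(|A|,|B|)+1)·tolerance`, large
enough that an extra feasible pair always dominates any distance saving.
Greedy nearest-first matching can be both suboptimal and asymmetric;
optimal assignment is deterministic, symmetric in the pair count, and is
verified in the tests against exhaustive enumeration over all one-to-one
assignments for up to 6 points per side. For well-separated mitoses
(spacing beyond twice the tolerance) one-to-one matching and
any-within-radius counting coincide; the assignment rule only matters
for clustered marks, where it is the defensible choice.

Multi-observer consensus objects are built sequentially: observers in
sorted id order, each observer's points assigned to the running cluster
centroids under the same tolerance (at most one point per observer per
cluster), centroid recomputed after each merge, unmatched points seeding
new clusters. The result conserves points exactly. The construction is
order-dependent in pathological geometries; with objects spaced beyond
the tolerance it recovers the true per-object detection pattern, which
the tests verify against simulator ground truth.

## Agreement statistics

**Dice.** `D = 2|A∩B|/(|A|+|B|)`, with `D = 1` for two empty sets so
that agreement on absence counts as agreement — this requires the file
format to distinguish "observer saw zero mitoses" (an empty-marker row)
from "observer absent". Pooled D sums counts and shared counts over
cases before forming the ratio; per-case D is reported alongside as a
distribution, summarized by its median.

**Bootstrap.** Confidence intervals use a percentile bootstrap that
resamples whole cases with replacement (default 2000 replicates, 95%
level, explicit seed). Cases, not objects, are the exchangeable unit:
objects within a case share an observer's attention and the case's
difficulty, so object-level resampling would understate the variance.
The same case-level scheme covers pooled D, the median per-case D, and
kappa (where resampling cases is equivalent to a multinomial resample of
the confusion-matrix cells). Coverage is checked by simulation: across
500 replicate 30-case studies at sensitivity 0.8 the 95% interval covers
the construction's pooled D ≈ 91% of the time — the mild undercoverage
expected of percentile intervals at a few dozen cases.

**Scores and kappa.** The mitotic activity score bins the count per
2 mm²: 0–6 → 1, 7–12 → 2, >12 → 3. Counts from regions of non-standard
area are rescaled to 2 mm² before binning. Quadratic-weighted Cohen's
kappa uses weights `w_ij = 1 − (i−j)²/(k−1)²` (k = 3) applied to the
observed matrix and to the product of its marginals; it is undefined
(flagged, NaN) when chance weighted agreement is exactly 1. The
implementation is cross-checked in the tests against
`sklearn.metrics.cohen_kappa_score` on label lists.

**Bland-Altman.** Paired per-case counts are transformed as
`log10(x+1)`; the mean difference b and limits of agreement
`b ± 1.96·sd` (sample sd, n−1) are computed on that scale. Mitotic
counts are strongly right-skewed, hence the log; the +1 offset keeps
zero counts finite without reordering, and is recorded in the result's
`transform` tag since limits of agreement near zero counts depend on it.

**Display convention.** Dice values are computed and stored at full
precision. The two worked examples in the README (0.46 and 0.76 at two
decimals) follow the truncation-toward-zero display historically used
for them — 2·10/26 = 0.7692 truncates to 0.76 — and
`scripts/acceptance.py` applies the same convention to those two outputs
only.

**Size comparison.** Poor agreement = consensus objects with exactly one
annotating human observer; good = all observers. Intermediate objects
are excluded, automatic detections set a flag but do not count toward
the observer number. Lengths (largest cross-section, μm) are consumed as
data; measuring them from pixels is out of scope. The group comparison
is a two-sided two-sample t-test, Welch by default (robust to unequal
variances; the pooled-variance variant is available via `equal_var`),
cross-checked against a permutation test in the suite.

## Detection post-processing

A point detection is a local maximum of the probability map whose value
strictly exceeds the threshold (default 0.85). "Local maximum" means no
neighbor under the configured connectivity (8 by default) is larger;
connected equal-valued maxima form a plateau collapsed to one detection
at its centroid. An optional minimum-separation radius applies greedy
non-maximum suppression, keeping the higher-valued detection; it is off
by default since the matching tolerance already absorbs near-duplicate
peaks. Operating-point selection scans a threshold grid (default
0.50–0.99, step 0.01), computes pooled Dice between extracted detections
and reference annotations at each threshold, and returns the argmax,
ties going to the lowest threshold. Map I/O supports a delimited-text
dialect with bit-exact round trip and 16-bit grayscale PNG (quantized to
1/65535).

## The simulator

`simulate_study` emulates the statistical structure the analysis
assumes, with defaults fixed at study-realistic values:

| parameter | default | rationale |
|---|---|---|
| cases | 100, of which 84 complete for all humans | typical study size; incomplete cases lose one human's locations round-robin |
| region | 5657² px ≈ 2 mm² at 0.25 μm/px | the standard counting area |
| counts | negative binomial, mean 8, dispersion 1.5 | right-skewed, all three score bins populated |
| object spacing | ≥ 90 px (3× tolerance) | makes one-to-one matching unambiguous so statistic correctness is isolated from matcher ambiguity; `clustered=True` removes it to stress the matcher |
| lengths | log-normal, median 9.5 μm, σ = 0.18 | mitotic-figure scale |
| human observers | sensitivity 0.85, size-slope 0.25 /μm, 1 FP/mm², jitter σ 3 px | yields pairwise pooled D ≈ 0.65 and κ ≈ 0.8–0.9, the expert range; the slope puts single-observer objects near 8.7 μm vs ≈ 10 μm for all-observer objects |
| automatic detector | sensitivity 0.75, slope 0.35, 2 FP/mm², jitter 4 px | less sensitive, noisier than humans |

Detection of each true object is an independent Bernoulli draw with
probability `logistic(logit(s₀) + slope·(length − median))`; detected
marks get isotropic Gaussian jitter; false positives are Poisson per
mm², placed at least one tolerance away from any true object so they
never absorb a true match. Ground truth records which observer detected
which object, enabling closed-form checks: for two independent observers
with sensitivities s₁, s₂ and no false positives, pooled D →
2s₁s₂/(s₁+s₂).

What the simulator does **not** emulate: spatial clustering of mitoses
in proliferation hot-spots, correlated errors between observers (real
observers miss the *same* ambiguous objects more often than
independence predicts), observer-specific bias in what counts as a
mitosis, within-case sensitivity drift (fatigue), and any image-level
appearance. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated model, not that real
studies satisfy the model; with correlated observers the Dice statistics
remain valid descriptively but the closed-form sensitivity relation does
not apply.

Probability-map simulation places Gaussian bumps (σ = 2 px) of a chosen
peak value at true objects plus Poisson-placed distractor bumps at a
lower value; overlaps exceeding 1 are clipped with a warning. Tests use
small regions (150–3000 px sides) so maps and placement stay cheap; the
statistical checks scale their case numbers to ≥ 5000 objects where the
asymptotic claims require it.

## Numerical and API choices

- Strict inequalities at both decision boundaries (match distance <
  tolerance, peak value > threshold) as specified for the statistics;
  the score bins are closed on the stated integer edges.
- Assignment ties are resolved deterministically; matched pairs are
  reported sorted by first-set index.
- All randomness flows through `numpy.random.Generator` objects with
  explicit seeds; study simulation spawns per-observer child seeds from
  one root `SeedSequence`, so the whole study is byte-reproducible.
- `filter_cases` uses a strict `>` for the mean-count threshold (a mean
  of exactly 6 is dropped) and is idempotent.
- Degenerate inputs: empty point sets are valid everywhere; kappa flags
  undefined rather than raising; the t-test requires ≥ 2 values per
  group; the bootstrap requires ≥ 2 cases.

## Limitations

- The consensus clustering is a declared construction; other grouping
  schemes (e.g. global multi-way assignment) can differ on clustered
  marks.
- Percentile bootstrap intervals undercover slightly below ~50 cases;
  BCa intervals were not implemented.
- Kappa CIs are bootstrap-based; no asymptotic variant is provided.
- The package consumes probability maps; it contains no detector.
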