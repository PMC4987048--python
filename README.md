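# mitoagree

Object-level interobserver agreement analysis for mitosis counting in
breast-cancer histopathology.

Tumor proliferation is graded by counting mitotic figures in a 2 mm²
tumor region of an H&E-stained slide (the mitotic activity index, binned
into the three-level mitotic activity score of the modified
Bloom-Richardson system). Two pathologists can report near-identical
counts while disagreeing on *which* objects they counted. With digital
slides each mark is a pixel coordinate, so agreement can be measured at
the level of individual objects — and an automatic detector's point
output can be evaluated the same way. `mitoagree` is a library for that
analysis, aimed at pathology-image-analysis researchers running
multi-observer annotation studies or validating mitosis detectors.

## What it computes

Two marks denote the same object when their Euclidean distance is
strictly below a tolerance radius (default 30 px = 7.5 μm at
0.25 μm/pixel, about one mitotic figure). Correspondence is an optimal
one-to-one assignment: maximum number of matched pairs, then minimum
total distance. On top of that matching:

- **Dice similarity coefficient** `D = 2|A∩B| / (|A| + |B|)` between two
  observers' object sets, pooled over the study and per case, with
  case-resampling percentile bootstrap CIs. `D` between two empty sets
  is defined as 1.
- **Quadratic-weighted Cohen's kappa** on the 3×3 mitotic-activity-score
  confusion matrix (weights `w_ij = 1 − (i−j)²/(k−1)²`), plus the count
  of clinically serious two-point score discrepancies.
- **Bland-Altman analysis** of paired counts on the `log10(x+1)` scale:
  mean difference `b` and limits of agreement `b ± 1.96·sd`.
- **Size analysis**: marks from all observers are clustered into
  consensus objects; objects annotated by a single observer ("poor
  agreement") are compared in physical length against objects annotated
  by everyone ("good agreement") with a Welch t-test.
- **Detector post-processing**: point detections as thresholded local
  maxima of a probability map, and Dice-optimal operating-threshold
  selection on a validation set.
- **Observer simulator**: negative-binomial case counts, log-normal
  object sizes, observers with size-dependent sensitivity, false
  positives and localization jitter — so the entire pipeline runs, and
  is tested, without any external data.

## Worked example

Dice arithmetic on the canonical two-observer example
(`examples/worked_dice_and_kappa.py`):

```text
D(12, 14, shared=6)  = 0.4615
D(12, 14, shared=10) = 0.7692
pooled D(783, 698, shared=496) = 0.6698
quadratic-weighted kappa = 0.8926
two-point score discrepancies = 1
```

One observer counted 12 mitoses, the other 14, but only 6 marks referred
to the same objects: despite similar totals, barely half the objects
were shared (D = 0.46). A full simulated study
(`examples/simulated_study_report.py`, 100 cases, 84 complete for all
three human observers) prints, among others:

```text
observer_a observer_b  count_a  count_b  n_shared   dice  dice_ci_low  dice_ci_high
      obs1       obs2      732      720       472 0.6501       0.6129        0.6832
      obs1       auto      732      841       410 0.5213       0.4855        0.5537
```

Human pairs land at D ≈ 0.65 with kappa ≈ 0.8–0.9: observers agree on
scores far better than on individual objects. The automatic detector
agrees less (D ≈ 0.52) with more two-point score discrepancies. The
other example scripts demonstrate Dice-optimal threshold selection on
probability maps and the smaller mean size of poor-agreement objects.

A thin CLI wraps the same pipeline:

```bash
mitoagree simulate --seed 11 --out study/
mitoagree run --annotations study/annotations.csv --metadata study/metadata.csv \
    --observers obs1,obs2,obs3 --automatic auto --seed 11 --out report/
```

## Layout

- `src/mitoagree/` — library modules: `annotations` (I/O and data
  model), `matching`, `dice`, `counts`, `sizes`, `detection`,
  `simulate`, `report`, `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — models, parameters, numerical choices,
  limitations.
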