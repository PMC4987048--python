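"""Select a detector's operating threshold by maximizing pooled Dice.

A mitosis detector outputs a probability map per case; point detections
are local maxima above a threshold.  The threshold is tuned on a
validation set: scan a grid, compare detections with reference
annotations under the 30 px matching tolerance, keep the Dice-optimal
value.
"""

import numpy as np

from mitoagree import CaseAnnotations, StudyDataset, select_operating_point
from mitoagree.detection import DetectionConfig, extract_detections
from mitoagree.simulate import CaseGroundTruth, TrueObject, simulate_probability_map

rng = np.random.default_rng(7)
maps, references = [], StudyDataset()
for i in range(5):
    objects = [(rng.uniform(20, 130), rng.uniform(20, 130)) for _ in range(4)]
    case = CaseGroundTruth(
        case_id=f"case{i}",
        objects=[TrueObject(j, x, y, 9.5) for j, (x, y) in enumerate(objects)],
        region_width_px=150,
        region_height_px=150,
    )
    # true mitoses produce strong bumps (0.9); distractors weak ones (0.3)
    maps.append(simulate_probability_map(
        case, peak_value=0.9, noise_rate_per_mm2=2000.0, noise_value=0.3,
        seed=300 + i,
    ))
    references.add(CaseAnnotations(f"case{i}", "ref",
                                   [tuple(map(float, o)) for o in objects]))

threshold, dice = select_operating_point(maps, references, tolerance=10)
print(f"selected threshold = {threshold:.2f}, pooled Dice = {dice:.3f}")

detections = extract_detections(maps[0], DetectionConfig(threshold=threshold))
print(f"case0: {len(detections)} detections at the selected threshold")
# The chosen threshold sits between the distractor level (0.3) and the
# true-peak level (0.9), so every true object is detected and every
# distractor rejected: pooled Dice 1.0 on this separable fixture.
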