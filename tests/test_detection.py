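import numpy as np
import pytest

from mitoagree.annotations import CaseAnnotations, StudyDataset
from mitoagree.detection import (
    DetectionConfig,
    ProbabilityMap,
    extract_detections,
    read_probability_map,
    select_operating_point,
    write_probability_map,
)
from mitoagree.simulate import (
    CaseGroundTruth,
    TrueObject,
    simulate_probability_map,
)


def gaussian_bump_map(centers_amps, shape=(120, 120), sigma=3.0, case_id="c"):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    v = np.zeros(shape)
    for (cx, cy), amp in centers_amps:
        v += amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
    return ProbabilityMap(np.clip(v, 0, 1), case_id=case_id)


class TestExtractDetections:
    def test_all_zero_map_has_no_detections(self):
        pmap = ProbabilityMap(np.zeros((50, 50)))
        assert extract_detections(pmap) == []

    def test_single_bump_detected_at_peak(self):
        pmap = gaussian_bump_map([((50, 50), 0.9)], shape=(100, 100))
        dets = extract_detections(pmap, DetectionConfig(threshold=0.85))
        assert len(dets) == 1
        x, y = dets[0]
        assert abs(x - 50) <= 1 and abs(y - 50) <= 1

    def test_strict_threshold_excludes_equal_value_peak(self):
        v = np.zeros((30, 30))
        v[10, 10] = 0.85  # exactly at threshold: excluded
        v[20, 20] = 0.86
        dets = extract_detections(ProbabilityMap(v), DetectionConfig(threshold=0.85))
        assert dets == [(20.0, 20.0)]

    def test_subthreshold_distractor_ignored(self):
        pmap = gaussian_bump_map([((30, 30), 0.9), ((90, 90), 0.80)])
        dets = extract_detections(pmap, DetectionConfig(threshold=0.85))
        assert len(dets) == 1

    def test_plateau_yields_single_centroid_detection(self):
        v = np.zeros((40, 40))
        v[10:12, 10:14] = 0.9  # 2x4 flat plateau
        dets = extract_detections(ProbabilityMap(v))
        assert len(dets) == 1
        x, y = dets[0]
        assert x == pytest.approx(11.5) and y == pytest.approx(10.5)

    def test_detection_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        centers = [((rng.uniform(10, 110), rng.uniform(10, 110)), rng.uniform(0.3, 1.0))
                   for _ in range(12)]
        pmap = gaussian_bump_map(centers, shape=(130, 130), sigma=2.0)
        counts = [
            len(extract_detections(pmap, DetectionConfig(threshold=t)))
            for t in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_every_detection_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        v = rng.random((60, 60))
        pmap = ProbabilityMap(v)
        for t in (0.6, 0.9):
            for x, y in extract_detections(pmap, DetectionConfig(threshold=t)):
                assert v[round(y), round(x)] > t

    def test_min_separation_merges_keeping_higher_peak(self):
        v = np.zeros((40, 40))
        v[20, 10] = 0.9
        v[20, 14] = 0.95
        cfg = DetectionConfig(threshold=0.5, min_separation=10.0)
        dets = extract_detections(ProbabilityMap(v), cfg)
        assert dets == [(14.0, 20.0)]

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityMap(np.full((5, 5), 1.2))


class TestOperatingPoint:
    def _fixture(self):
        maps, ds = [], StudyDataset()
        rng = np.random.default_rng(5)
        for i in range(3):
            true = [(rng.uniform(20, 100), rng.uniform(20, 100)) for _ in range(3)]
            noise = [(rng.uniform(20, 100), rng.uniform(20, 100)) for _ in range(2)]
            centers = [(c, 0.9) for c in true] + [(c, 0.3) for c in noise]
            maps.append(gaussian_bump_map(centers, case_id=f"c{i}", sigma=2.0))
            ds.add(CaseAnnotations(f"c{i}", "ref", [tuple(map(float, c)) for c in true]))
        return maps, ds

    def test_threshold_lands_between_noise_and_peak_with_perfect_dice(self):
        maps, refs = self._fixture()
        threshold, dice = select_operating_point(maps, refs, tolerance=10)
        assert 0.3 < threshold < 0.9
        assert dice == 1.0

    def test_deterministic(self):
        maps, refs = self._fixture()
        assert select_operating_point(maps, refs) == select_operating_point(maps, refs)

    def test_empty_references_favor_silent_threshold(self):
        v = gaussian_bump_map([((40, 40), 0.7)], shape=(80, 80))
        ds = StudyDataset()
        ds.add(CaseAnnotations("c", "ref", []))
        v.case_id = "c"
        threshold, dice = select_operating_point([v], ds, grid=[0.5, 0.8])
        assert threshold == 0.8  # no detections -> empty-vs-empty Dice of 1
        assert dice == 1.0

    def test_case_without_reference_rejected(self):
        maps, refs = self._fixture()
        maps[0].case_id = "unknown"
        with pytest.raises(ValueError, match="unknown"):
            select_operating_point(maps, refs)


class TestMapIO:
    def test_text_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        pmap = ProbabilityMap(rng.random((20, 30)))
        path = write_probability_map(pmap, tmp_path / "m.csv")
        again = read_probability_map(path)
        assert np.array_equal(again.values, pmap.values)

    def test_png_round_trip_within_quantization(self, tmp_path):
        rng = np.random.default_rng(10)
        pmap = ProbabilityMap(rng.random((16, 16)))
        path = write_probability_map(pmap, tmp_path / "m.png")
        again = read_probability_map(path)
        assert np.abs(again.values - pmap.values).max() <= 1.0 / 65535


class TestSimulatedMaps:
    def _case(self, objects):
        return CaseGroundTruth(
            case_id="c",
            objects=[
                TrueObject(i, x, y, 9.5) for i, (x, y) in enumerate(objects)
            ],
            region_width_px=150,
            region_height_px=150,
        )

    def test_detections_recover_true_objects(self):
        case = self._case([(30, 40), (90, 50), (60, 120)])
        pmap = simulate_probability_map(case, peak_value=0.9, seed=1)
        dets = extract_detections(pmap, DetectionConfig(threshold=0.5))
        assert len(dets) == 3
        for x, y in dets:
            assert min((x - ox) ** 2 + (y - oy) ** 2
                       for ox, oy in [(30, 40), (90, 50), (60, 120)]) <= 1.0

    def test_empty_case_gives_zero_map(self):
        case = self._case([])
        pmap = simulate_probability_map(case, seed=0)
        assert pmap.values.max() == 0.0

    def test_operating_point_on_separable_simulated_maps(self):
        rng = np.random.default_rng(6)
        maps, ds = [], StudyDataset()
        for i in range(3):
            objs = [(rng.uniform(20, 130), rng.uniform(20, 130)) for _ in range(4)]
            case = self._case(objs)
            case.case_id = f"c{i}"
            pmap = simulate_probability_map(
                case, peak_value=0.9, noise_rate_per_mm2=2000.0,
                noise_value=0.3, seed=100 + i,
            )
            maps.append(pmap)
            ds.add(CaseAnnotations(f"c{i}", "ref", [tuple(map(float, o)) for o in objs]))
        threshold, dice = select_operating_point(maps, ds, tolerance=10)
        assert 0.3 < threshold < 0.9
        assert dice == 1.0
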