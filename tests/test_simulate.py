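import numpy as np
import pytest

from mitoagree.annotations import write_annotations
from mitoagree.dice import pooled_dice
from mitoagree.simulate import (
    ObserverProfile,
    SimulationParams,
    expected_pooled_dice,
    simulate_ground_truth,
    simulate_observer,
    simulate_study,
    write_ground_truth,
)


def _profiles(s, n=2, **kw):
    defaults = dict(size_slope=0.0, fp_rate=0.0, jitter_sigma=2.0)
    defaults.update(kw)
    return tuple(
        ObserverProfile(f"o{k}", base_sensitivity=s, **defaults) for k in range(n)
    )


class TestGroundTruth:
    def test_mean_count_recovered(self):
        params = SimulationParams(
            n_cases=100, count_mean=5.0, region_width_px=2500,
            region_height_px=2500, n_incomplete_cases=0, seed=7,
        )
        gt = simulate_ground_truth(params)
        assert abs(gt.total_objects / 100 - 5.0) < 1.0

    def test_deterministic_for_seed(self):
        params = SimulationParams(n_cases=10, seed=2, n_incomplete_cases=0)
        g1 = simulate_ground_truth(params)
        g2 = simulate_ground_truth(params)
        assert [o.x for c in g1.cases for o in c.objects] == [
            o.x for c in g2.cases for o in c.objects
        ]

    def test_poisson_limit_at_large_dispersion(self):
        params = SimulationParams(
            n_cases=2000, count_mean=5.0, count_dispersion=1e7,
            region_width_px=2500, region_height_px=2500,
            n_incomplete_cases=0, seed=13,
        )
        gt = simulate_ground_truth(params)
        counts = np.array([c.count for c in gt.cases])
        assert abs(counts.var() / counts.mean() - 1.0) < 0.15

    def test_overdispersion_with_small_dispersion(self):
        params = SimulationParams(
            n_cases=2000, count_mean=8.0, count_dispersion=1.5,
            region_width_px=3500, region_height_px=3500,
            n_incomplete_cases=0, seed=13,
        )
        counts = np.array([c.count for c in simulate_ground_truth(params).cases])
        # variance ≈ mean + mean^2/dispersion ≈ 8 + 42.7
        assert counts.var() > 3 * counts.mean()

    def test_minimum_spacing_enforced(self):
        params = SimulationParams(
            n_cases=20, count_mean=10, region_width_px=2000,
            region_height_px=2000, n_incomplete_cases=0, seed=3,
        )
        for case in simulate_ground_truth(params).cases:
            pts = np.array([(o.x, o.y) for o in case.objects])
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    assert np.hypot(*(pts[i] - pts[j])) >= 90.0

    def test_infeasible_spacing_raises_helpful_error(self):
        params = SimulationParams(
            n_cases=1, count_mean=200, count_dispersion=1e7,
            region_width_px=300, region_height_px=300,
            n_incomplete_cases=0, seed=1,
        )
        with pytest.raises(RuntimeError, match="larger region"):
            simulate_ground_truth(params)


class TestObserver:
    def test_perfect_observer_reproduces_truth(self):
        params = SimulationParams(
            n_cases=10, region_width_px=2000, region_height_px=2000,
            n_incomplete_cases=0, seed=5,
            profiles=_profiles(1.0, jitter_sigma=0.0),
        )
        gt = simulate_ground_truth(params)
        ann = simulate_observer(gt, params.profiles[0], seed=1)
        for case in gt.cases:
            truth = sorted((o.x, o.y) for o in case.objects)
            marks = sorted(ann[case.case_id].coords())
            assert marks == truth

    def test_sensitivity_recovered_from_detection_fractions(self):
        params = SimulationParams(
            n_cases=700, count_mean=8, region_width_px=3000,
            region_height_px=3000, n_incomplete_cases=0, seed=23,
            profiles=_profiles(0.8, n=1),
        )
        gt = simulate_ground_truth(params)
        simulate_observer(gt, params.profiles[0], seed=2)
        detected = np.concatenate([c.detections["o0"] for c in gt.cases])
        assert len(detected) >= 5000
        assert abs(detected.mean() - 0.8) < 0.02

    def test_size_slope_reproduces_smaller_poor_objects(self):
        params = SimulationParams(
            n_cases=250, count_mean=8, region_width_px=3000,
            region_height_px=3000, n_incomplete_cases=0, seed=29,
            profiles=_profiles(0.85, n=3, size_slope=0.5),
        )
        gt = simulate_ground_truth(params)
        for i, p in enumerate(params.profiles):
            simulate_observer(gt, p, seed=50 + i)
        lengths, n_det = [], []
        for case in gt.cases:
            det = sum(case.detections[f"o{k}"] for k in range(3))
            lengths.extend(o.length_um for o in case.objects)
            n_det.extend(det)
        lengths = np.array(lengths)
        n_det = np.array(n_det)
        assert lengths[n_det == 1].mean() < lengths[n_det == 3].mean()


class TestStudy:
    def test_full_pipeline_recovers_closed_form_dice(self):
        for s in (0.5, 0.8, 0.95):
            params = SimulationParams(
                n_cases=700, count_mean=8, region_width_px=3000,
                region_height_px=3000, n_incomplete_cases=0, seed=37,
                profiles=_profiles(s),
            )
            ds, gt = simulate_study(params)
            assert gt.total_objects >= 5000
            d = pooled_dice(ds, "o0", "o1").value
            assert abs(d - expected_pooled_dice(s, s)) < 0.02

    def test_study_reproducible_byte_identical(self, tmp_path):
        params = SimulationParams(n_cases=12, seed=19)
        d1, _ = simulate_study(params)
        d2, _ = simulate_study(params)
        p1 = write_annotations(d1, tmp_path / "a.csv")
        p2 = write_annotations(d2, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_incomplete_cases_drop_exactly_one_human(self):
        params = SimulationParams(n_cases=25, seed=3)  # default 16% -> 4 cases
        ds, _ = simulate_study(params)
        humans = {"obs1", "obs2", "obs3"}
        incomplete = [
            cid for cid, per_obs in ds.cases.items()
            if not humans <= set(per_obs)
        ]
        assert len(incomplete) == 4
        for cid in incomplete:
            assert len(humans & set(ds.cases[cid])) == 2
            assert "auto" in ds.cases[cid]

    def test_ground_truth_csv_lists_every_object(self, tmp_path):
        params = SimulationParams(n_cases=6, seed=8, n_incomplete_cases=0)
        ds, gt = simulate_study(params)
        path = tmp_path / "gt.csv"
        write_ground_truth(gt, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == gt.total_objects
        assert lines[0].startswith("case_id,object_id,x_px,y_px,length_um")


class TestClosedFormHelper:
    def test_rejects_double_zero(self):
        with pytest.raises(ValueError):
            expected_pooled_dice(0.0, 0.0)

    def test_harmonic_mean_structure(self):
        assert expected_pooled_dice(0.6, 0.9) == pytest.approx(0.72)
        assert expected_pooled_dice(1.0, 1.0) == 1.0
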