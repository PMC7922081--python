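"""Peak-location histogram and constrained layout design."""

import itertools

import numpy as np
import pytest

from insolesim import geometry, layout, synthetic
from insolesim.core import ValidationError
from insolesim.layout import LayoutConstraints, PeakHistogram


def _brute_force_per_frame_hist(recordings):
    counts = np.zeros(len(recordings[0].sensors), dtype=int)
    for rec in recordings:
        for t in range(rec.n_frames):
            frame = rec.pressures[t]
            if frame.max() <= 0:
                continue
            best, best_v = 0, frame[0]
            for i in range(1, len(frame)):
                if frame[i] > best_v:
                    best, best_v = i, frame[i]
            counts[best] += 1
    return counts


def _brute_force_per_trial_hist(recordings):
    counts = np.zeros(len(recordings[0].sensors), dtype=int)
    for rec in recordings:
        best, best_v = None, 0.0
        for t in range(rec.n_frames):
            for i in range(rec.n_sensors):
                if rec.pressures[t, i] > best_v:
                    best, best_v = i, rec.pressures[t, i]
        if best is not None:
            counts[best] += 1
    return counts


class TestPeakHistogram:
    def test_single_trial_counts_its_peak_sensor(self, recording_factory):
        p = np.zeros((4, 99))
        p[2, 12] = 1.0
        hist = layout.peak_location_histogram([recording_factory(p)])
        assert hist.counts[12] == 1
        assert hist.counts.sum() == 1

    def test_copies_accumulate_linearly(self, recording_factory):
        p = np.zeros((4, 99))
        p[2, 12] = 1.0
        recs = [recording_factory(p)] * 5
        hist = layout.peak_location_histogram(recs)
        assert hist.counts[12] == 5

    def test_per_trial_conserves_trial_count(self, rng, recording_factory):
        recs = [recording_factory(rng.uniform(0, 1, (10, 99))) for _ in range(7)]
        hist = layout.peak_location_histogram(recs, mode="per_trial")
        assert hist.counts.sum() == hist.n_trials == 7

    @pytest.mark.parametrize("mode", ["per_trial", "per_frame"])
    def test_matches_double_loop_oracle(self, mode, rng, recording_factory):
        recs = [recording_factory(rng.uniform(0, 1, (20, 99))) for _ in range(5)]
        hist = layout.peak_location_histogram(recs, mode=mode)
        oracle = (
            _brute_force_per_trial_hist(recs)
            if mode == "per_trial"
            else _brute_force_per_frame_hist(recs)
        )
        np.testing.assert_array_equal(hist.counts, oracle)

    def test_synthetic_gait_trials_match_oracle(self):
        recs = []
        for seed in range(4):
            params = synthetic.TrialParams(
                task="gait", noise_sd=0.002, seed=seed, n_steps=2
            )
            recs.append(synthetic.generate_gait_trial(params)[0])
        hist = layout.peak_location_histogram(recs, mode="per_trial")
        np.testing.assert_array_equal(hist.counts, _brute_force_per_trial_hist(recs))

    def test_mixed_geometries_rejected(self, recording_factory):
        a = recording_factory(np.zeros((2, 99)))
        b = recording_factory(
            np.zeros((2, 99)),
            sensors=synthetic.generate_template("40-41"),
            size="40-41",
        )
        with pytest.raises(ValidationError, match="mixed"):
            layout.peak_location_histogram([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError, match="at least one"):
            layout.peak_location_histogram([])


class TestDesignLayout:
    def test_uniform_histogram_meets_quotas(self, template_38):
        hist = PeakHistogram(
            counts=np.ones(99, dtype=int), n_trials=99, mode="per_frame",
            geometry=template_38,
        )
        lay = layout.design_layout(hist, template_38, insole_size="38-39")
        assert lay.n_sensors == 16
        counts = lay.region_counts()
        hind = counts.get("hindfoot_medial", 0) + counts.get("hindfoot_lateral", 0)
        mid = counts.get("midfoot_medial", 0) + counts.get("midfoot_lateral", 0)
        fore = counts.get("forefoot_medial", 0) + counts.get("forefoot_lateral", 0)
        assert (hind, mid, fore + counts.get("toes", 0)) == (4, 3, 9)

    def test_concentrated_histogram_picks_that_sensor_first(self, template_38):
        counts = np.zeros(99, dtype=int)
        hind_med = [
            i for i, s in enumerate(template_38) if s.region == "hindfoot_medial"
        ]
        target = hind_med[len(hind_med) // 2]
        counts[target] = 50
        hist = PeakHistogram(counts=counts, n_trials=50, mode="per_trial",
                             geometry=template_38)
        lay = layout.design_layout(hist, template_38, insole_size="38-39")
        first_hindfoot_medial = next(
            s for s in lay.sensors if s.region == "hindfoot_medial"
        )
        assert first_hindfoot_medial.center_x == template_38[target].center_x
        assert first_hindfoot_medial.center_y == template_38[target].center_y

    def test_greedy_matches_exhaustive_on_toy_candidates(self, template_38):
        """On a small candidate set, the greedy pick must equal the best
        feasible subset by total count whenever greedy is optimal there."""
        rng = np.random.default_rng(1)
        hind_med = [
            i for i, s in enumerate(template_38) if s.region == "hindfoot_medial"
        ][:12]
        counts = np.zeros(99, dtype=int)
        counts[hind_med] = rng.integers(1, 30, len(hind_med))
        constraints = LayoutConstraints(
            n_sensors=2, quotas=(("hindfoot_medial", 2),), min_gap=2.0
        )
        hist = PeakHistogram(counts=counts, n_trials=int(counts.sum()),
                             mode="per_frame", geometry=template_38)
        lay = layout.design_layout(hist, template_38, constraints, insole_size="38-39")

        # exhaustive oracle over all feasible pairs
        def feasible(pair):
            picks = [template_38[i] for i in pair]
            for s in picks:
                if not geometry.rect_inside(s.center_x, s.center_y, 15, 15, "38-39"):
                    return False
            a, b = picks
            return geometry.rect_gap(a.center, (15, 15), b.center, (15, 15)) >= 2.0

        best = max(
            (pair for pair in itertools.combinations(hind_med, 2) if feasible(pair)),
            key=lambda pair: (counts[pair[0]] + counts[pair[1]],
                              -template_38[pair[0]].center_y,
                              -template_38[pair[1]].center_y),
        )
        got = {(s.center_x, s.center_y) for s in lay.sensors}
        want = {(template_38[i].center_x, template_38[i].center_y) for i in best}
        assert got == want

    def test_unreachable_quota_names_region(self, template_38):
        counts = np.ones(99, dtype=int)
        hist = PeakHistogram(counts=counts, n_trials=99, mode="per_frame",
                             geometry=template_38)
        constraints = LayoutConstraints(
            n_sensors=30, quotas=(("midfoot_medial", 30),), min_gap=2.0
        )
        with pytest.raises(ValidationError, match="midfoot_medial"):
            layout.design_layout(hist, template_38, constraints, insole_size="38-39")

    def test_design_is_deterministic(self, template_38):
        hist = PeakHistogram(counts=np.ones(99, dtype=int), n_trials=99,
                             mode="per_frame", geometry=template_38)
        a = layout.design_layout(hist, template_38, insole_size="38-39")
        b = layout.design_layout(hist, template_38, insole_size="38-39")
        assert a.sensors == b.sensors

    def test_quota_sum_must_match_sensor_count(self):
        with pytest.raises(ValidationError, match="quotas sum"):
            LayoutConstraints(n_sensors=16, quotas=(("toes", 2),))


class TestDefaultLayout:
    @pytest.mark.parametrize("size", geometry.INSOLE_SIZES)
    def test_sixteen_sensors_and_3600_mm2(self, size):
        lay = layout.default_layout(size)
        assert lay.n_sensors == 16
        assert lay.sensorized_area_mm2 == pytest.approx(16 * 15 * 15, abs=1e-9)

    @pytest.mark.parametrize("size", geometry.INSOLE_SIZES)
    def test_region_quotas(self, size):
        counts = layout.default_layout(size).region_counts()
        assert counts["hindfoot_medial"] == 2
        assert counts["hindfoot_lateral"] == 2
        assert counts["midfoot_medial"] == 1
        assert counts["midfoot_lateral"] == 2
        assert counts.get("forefoot_medial", 0) + counts.get("forefoot_lateral", 0) == 7
        assert counts["toes"] == 2

    def test_layouts_scale_monotonically_with_size(self):
        small = layout.default_layout("38-39")
        large = layout.default_layout("44-45")
        for s, l in zip(small.sensors, large.sensors):
            assert l.center_y >= s.center_y

    def test_unknown_size_rejected(self):
        with pytest.raises(ValueError, match="unknown insole size"):
            layout.default_layout("37")


class TestScaleLayout:
    def test_scale_to_same_size_is_identity(self, default_layout_38):
        scaled = layout.scale_layout(default_layout_38, "38-39")
        for a, b in zip(scaled.sensors, default_layout_38.sensors):
            assert a.center_x == pytest.approx(b.center_x)
            assert a.center_y == pytest.approx(b.center_y)

    def test_count_preserved(self, default_layout_38):
        assert layout.scale_layout(default_layout_38, "44-45").n_sensors == 16

    def test_centers_follow_hand_computed_affine_map(self, default_layout_38):
        scaled = layout.scale_layout(default_layout_38, "42-43")
        rx = 86.0 / 80.0
        ry = 269.0 / 245.0
        for a, b in list(zip(scaled.sensors, default_layout_38.sensors))[:3]:
            assert a.center_x == pytest.approx(b.center_x * rx, rel=1e-12)
            assert a.center_y == pytest.approx(b.center_y * ry, rel=1e-12)

    def test_sensor_side_unchanged(self, default_layout_38):
        scaled = layout.scale_layout(default_layout_38, "44-45")
        assert all(s.width == 15.0 and s.height == 15.0 for s in scaled.sensors)
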