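import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

from rungwalk import events as ev
from rungwalk import tracking as tk
from rungwalk.pipeline import poses_from_ground_truth
from rungwalk.synth.crossing import CrossingStyle, generate_crossing
from rungwalk.synth.roi import synthesize_roi_traces


def make_poses(xs_cm, geometry, valid=None):
    poses = []
    for i, x in enumerate(xs_cm):
        if valid is not None and not valid[i]:
            poses.append(tk.PoseSample(i, None, None, False))
            continue
        nx, ny = geometry.cm_to_px(x, 3.0)
        e = tk.EllipseParams(nx - 30, ny, 40, 15, 0.0)
        poses.append(tk.PoseSample(i, (nx, ny), e, True))
    return poses


def pulse_trace(n, rises, rate=60.0, label="step_3_surface",
                role="surface", amplitude=1.0):
    v = np.zeros(n)
    for r in rises:
        v[r:r + 6] = amplitude
    v = gaussian_filter1d(v, 0.8)
    return tk.ActivationTrace(label, v, rate, role)


class TestCrossingExtraction:
    def test_run_on_one_side_is_not_a_crossing(self, geometry):
        xs = np.linspace(2, 20, 50)  # stays left of the midline
        crossings = ev.extract_crossings(make_poses(xs, geometry), geometry)
        assert crossings == []

    def test_monotone_span_becomes_one_crossing(self, geometry):
        xs = np.linspace(1, 47, 200)
        crossings = ev.extract_crossings(make_poses(xs, geometry), geometry)
        assert len(crossings) == 1
        assert crossings[0].direction == "LR"

    def test_short_pose_gaps_are_tolerated(self, geometry):
        xs = np.linspace(1, 47, 200)
        valid = np.ones(200, dtype=bool)
        valid[100:105] = False  # 5 frames < 0.25 s at 60 Hz
        crossings = ev.extract_crossings(make_poses(xs, geometry, valid),
                                         geometry)
        assert len(crossings) == 1

    def test_long_gaps_split_runs(self, geometry):
        xs = np.concatenate([np.linspace(1, 47, 100),
                             np.linspace(47, 1, 100)])
        valid = np.ones(200, dtype=bool)
        valid[98:102] = True
        valid[95:125] = False  # 0.5 s gap
        crossings = ev.extract_crossings(make_poses(xs, geometry, valid),
                                         geometry)
        assert len(crossings) == 2
        assert {c.direction for c in crossings} == {"LR", "RL"}

    def test_alternating_fixture_crossings(self, geometry, quiet_style):
        """Ten alternating generator crossings are recovered with
        alternating directions."""
        all_poses = []
        offset = 0
        for i in range(10):
            gt = generate_crossing(geometry, quiet_style, "stable", i,
                                   "LR" if i % 2 == 0 else "RL")
            for p in poses_from_ground_truth(gt, geometry):
                all_poses.append(tk.PoseSample(p.frame_index + offset,
                                               p.nose, p.ellipse, True))
            offset += len(gt.times) + 60  # 1 s apart
            all_poses.append(tk.PoseSample(offset - 1, None, None, False))
        crossings = ev.extract_crossings(all_poses, geometry)
        assert [c.direction for c in crossings] == ["LR", "RL"] * 5

    def test_mirroring_swaps_direction_labels_only(self, geometry):
        xs = np.linspace(1, 47, 200)
        mirrored = geometry.course_length - xs
        a = ev.extract_crossings(make_poses(xs, geometry), geometry)
        b = ev.extract_crossings(make_poses(mirrored, geometry), geometry)
        assert (a[0].start, a[0].end) == (b[0].start, b[0].end)
        assert {a[0].direction, b[0].direction} == {"LR", "RL"}


class TestStepDetection:
    def test_pulse_rise_detected_within_one_frame(self, geometry):
        trace = pulse_trace(300, [120])
        crossing = ev.Crossing(0, 299, "LR")
        frame = ev.detect_step(trace, crossing, threshold=0.2)
        assert abs(frame - 120) <= 1

    def test_flat_trace_yields_none(self):
        trace = tk.ActivationTrace("step_3_surface", np.zeros(100), 60.0)
        crossing = ev.Crossing(0, 99, "LR")
        assert ev.detect_step(trace, crossing, threshold=0.2) is None

    def test_first_of_two_pulses_wins(self):
        trace = pulse_trace(300, [100, 200])
        crossing = ev.Crossing(0, 299, "LR")
        frame = ev.detect_step(trace, crossing, threshold=0.2)
        assert abs(frame - 100) <= 1

    def test_threshold_must_be_positive(self):
        trace = pulse_trace(100, [50])
        with pytest.raises(ValueError):
            ev.detect_step(trace, ev.Crossing(0, 99, "LR"), threshold=-1.0)


class TestHeadConstraint:
    def test_nose_before_next_step_accepted(self, geometry):
        # contact on step 3; nose 3 cm before step 4's near edge
        x_nose = geometry.near_edge(4, 1) - 3.0
        poses = make_poses([x_nose] * 10, geometry)
        crossing = ev.Crossing(0, 9, "LR")
        result = ev.validate_step(5, 3, poses, geometry, crossing)
        assert isinstance(result, ev.StepEvent)

    def test_nose_beyond_next_step_rejected(self, geometry):
        x_nose = geometry.near_edge(4, 1) + 2.0
        poses = make_poses([x_nose] * 10, geometry)
        crossing = ev.Crossing(0, 9, "LR")
        result = ev.validate_step(5, 3, poses, geometry, crossing)
        assert result == "head_beyond_next_step"

    def test_missing_pose_rejected_with_reason(self, geometry):
        poses = make_poses([20.0] * 10, geometry,
                           valid=[False] * 10)
        crossing = ev.Crossing(0, 9, "LR")
        assert ev.validate_step(5, 3, poses, geometry, crossing) == "no_pose"

    def test_fixture_forelimb_accepted_and_hindlimb_rejected(self, geometry,
                                                             quiet_style):
        gt = generate_crossing(geometry, quiet_style, "stable", 31)
        poses = poses_from_ground_truth(gt, geometry)
        traces = synthesize_roi_traces(gt, geometry)
        crossings = ev.extract_crossings(poses, geometry)
        accepted, rejected = ev.detect_step_events(traces, crossings, poses,
                                                   geometry)
        assert len(accepted) == len(gt.fore_contacts)
        # hindlimb contact frames must fail the head constraint
        for h in (e for e in gt.contact_events if e.limb == "hind"):
            frame = int(round(h.time_s * geometry.frame_rate))
            result = ev.validate_step(frame, h.step_index, poses, geometry,
                                      crossings[0])
            assert not isinstance(result, ev.StepEvent)


class TestSlipDetection:
    def test_clean_crossing_yields_zero_candidates(self, geometry,
                                                   quiet_style):
        gt = generate_crossing(geometry, quiet_style, "stable", 7)
        traces = synthesize_roi_traces(gt, geometry)
        assert ev.detect_slip_candidates(traces) == []

    def test_every_slip_becomes_a_candidate(self, geometry):
        style = CrossingStyle(p_slip=0.6, speed_jitter_sd=0.0)
        gt = generate_crossing(geometry, style, "stable", 13)
        assert len(gt.slip_events) >= 2
        traces = synthesize_roi_traces(gt, geometry)
        candidates = ev.detect_slip_candidates(traces)
        assert len(candidates) == len(gt.slip_events)
        got_gaps = {c.gap_index for c in candidates}
        assert got_gaps == {s.gap_index for s in gt.slip_events}

    def test_candidate_count_monotone_in_threshold(self, geometry):
        style = CrossingStyle(p_slip=0.6, speed_jitter_sd=0.0)
        gt = generate_crossing(geometry, style, "stable", 13)
        traces = synthesize_roi_traces(gt, geometry, noise_sd=0.02)
        thresholds = [0.01, 0.05, 0.2, 1.0, 1e9]
        counts = [len(ev.detect_slip_candidates(traces, thr))
                  for thr in thresholds]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_label_join_and_reject_reasons(self):
        candidates = [ev.SlipCandidate(0, 10, 1), ev.SlipCandidate(1, 50, 2),
                      ev.SlipCandidate(2, 90, 3)]
        labels = pd.DataFrame({
            "candidate_id": [0, 1],
            "verdict": ["genuine", "tail"],
            "limb": ["hind", None],
        })
        slips = ev.apply_slip_labels(candidates, labels)
        assert [s.confirmed for s in slips] == [True, False, False]
        assert slips[0].limb == "hind"
        assert slips[1].reject_reason == "tail"
        assert slips[2].reject_reason == "none"

    def test_unknown_candidate_id_raises(self):
        labels = pd.DataFrame({"candidate_id": [9], "verdict": ["genuine"]})
        with pytest.raises(KeyError, match="9"):
            ev.apply_slip_labels([ev.SlipCandidate(0, 10, 1)], labels)


class TestPawSideClassification:
    def test_disjoint_histogram_families_separate_perfectly(self, rng):
        dark = [rng.integers(0, 40, (30, 30)).astype(np.uint8)
                for _ in range(10)]
        bright = [rng.integers(200, 255, (30, 30)).astype(np.uint8)
                  for _ in range(10)]
        labels, degenerate = ev.classify_paw_side(dark + bright, seed=0)
        assert not degenerate
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_identical_frames_flagged_degenerate(self):
        frames = [np.full((20, 20), 100, dtype=np.uint8)] * 6
        _, degenerate = ev.classify_paw_side(frames, seed=0)
        assert degenerate

    def test_luminance_asymmetry_recovered_after_mapping(self, rng):
        # left-paw frames carry a bright patch; right-paw frames are dim
        frames, truth = [], []
        for i in range(40):
            f = rng.normal(60, 5, (40, 40))
            if i % 2 == 0:
                f[10:25, 10:25] += 120
                truth.append("left")
            else:
                truth.append("right")
            frames.append(np.clip(f, 0, 255).astype(np.uint8))
        labels, _ = ev.classify_paw_side(frames, seed=1)
        sides = ev.map_clusters_to_sides(labels, {0: "left", 1: "right"})
        agreement = np.mean([s == t for s, t in zip(sides, truth)])
        assert agreement >= 0.9

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ev.classify_paw_side([np.zeros((5, 5))], k=2)


class TestEventInvariants:
    def test_step_events_lie_inside_their_crossing(self, geometry,
                                                   quiet_style):
        gt = generate_crossing(geometry, quiet_style, "unstable", 17)
        poses = poses_from_ground_truth(gt, geometry)
        traces = synthesize_roi_traces(gt, geometry)
        crossings = ev.extract_crossings(poses, geometry)
        accepted, _ = ev.detect_step_events(traces, crossings, poses,
                                            geometry)
        c = crossings[0]
        assert all(c.start <= e.frame <= c.end for e in accepted)
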