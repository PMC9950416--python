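"""End-to-end convenience pipelines on synthetic cohorts.

These helpers wire the synthetic generators through the tracking, event
detection and metrics layers, and are what the worked examples, the test
suite and the acceptance script run.  Ground truth is known for every
fixture, so each function returns both the pipeline's estimates and the
configured values they should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from rungwalk import events as ev
from rungwalk import metrics as mt
from rungwalk import tracking as tk
from rungwalk.geometry import CourseGeometry, scaled_fixture_geometry
from rungwalk.synth.crossing import (CrossingGroundTruth, CrossingStyle,
                                     generate_crossing)
from rungwalk.synth.render import RenderStyle, render_frames
from rungwalk.synth.roi import synthesize_roi_traces


def poses_from_ground_truth(gt: CrossingGroundTruth,
                            geometry: CourseGeometry) -> list[tk.PoseSample]:
    """Convert a ground-truth nose path into valid PoseSamples (px)."""
    poses = []
    sign = gt.direction_sign
    for i, (x, y) in enumerate(gt.nose_path):
        nx, ny = geometry.cm_to_px(x, y)
        bx, by = geometry.cm_to_px(x - sign * 8.0, y + 1.0)
        ellipse = tk.EllipseParams(bx, by, 6.0 * geometry.px_per_cm,
                                   2.2 * geometry.px_per_cm, 0.0)
        poses.append(tk.PoseSample(i, (nx, ny), ellipse, True))
    return poses


@dataclass(frozen=True)
class SimulatedTrial:
    record: mt.TrialRecord
    posture: mt.PostureSample | None
    profile: mt.SpeedProfile | None
    gt: CrossingGroundTruth


def simulate_trial(geometry: CourseGeometry, style: CrossingStyle,
                   trial_state: str, seed: int, direction: str,
                   session_day: int = 0, trial_ordinal: int = 1,
                   prev_states: tuple[str, str] | None = None,
                   animal_id: str | None = None, group: str | None = None,
                   ) -> SimulatedTrial:
    """Generate one trial and push it through the event pipeline.

    Produces the trial record (crossing + detected step events), the
    posture sample at the first manipulated step (None when the step
    event was not detected, e.g. on jump trials) and the speed profile.
    """
    gt = generate_crossing(geometry, style, trial_state, seed,
                           direction=direction, prev_states=prev_states)
    poses = poses_from_ground_truth(gt, geometry)
    traces = synthesize_roi_traces(gt, geometry)
    crossings = ev.extract_crossings(poses, geometry)
    if len(crossings) != 1:
        raise RuntimeError(
            f"expected one crossing, found {len(crossings)}")
    crossing = crossings[0]
    accepted, _ = ev.detect_step_events(traces, crossings, poses, geometry)
    record = mt.TrialRecord(
        crossing=crossing, session_day=session_day,
        trial_ordinal=trial_ordinal, state=trial_state,
        crossing_time=mt.crossing_time(crossing, geometry.frame_rate),
        prev_states=prev_states, step_events=tuple(accepted),
        animal_id=animal_id, group=group)

    sign = crossing.direction_sign
    first = geometry.first_center_step(sign)
    trigger = next((e for e in accepted if e.step_index == first), None)
    posture = None
    if trigger is not None:
        posture = mt.posture_at_step(poses, trigger, geometry, sign)
        if posture is not None:
            posture = mt.PostureSample(posture.progression, posture.height,
                                       posture.trigger_step, record)
    times = gt.times
    xs = gt.nose_path[:, 0]
    profile = mt.speed_profile(times, xs, geometry, sign)
    return SimulatedTrial(record, posture, profile, gt)


# ---------------------------------------------------------------------------
# cohort posture / speed analysis

def run_posture_cohort(seed: int = 0, n_control: int = 11,
                       n_lesion: int = 11, trials_per_state: int = 20,
                       geometry: CourseGeometry | None = None,
                       style: CrossingStyle | None = None) -> dict:
    """Block-protocol cohort: recover the stable-vs-unstable posture
    difference configured in the generator.

    Returns the per-trial posture table, the estimated progression and
    height differences with standard errors, the configured (true)
    differences, and the per-animal speedup indices together with the
    residual of the exact antisymmetry check (swapping the stable and
    unstable profile sets must negate the index).
    """
    geometry = geometry or scaled_fixture_geometry()
    style = style or CrossingStyle()
    rng = np.random.default_rng(seed)
    animals = ([("C%02d" % i, "control") for i in range(n_control)]
               + [("L%02d" % i, "lesion") for i in range(n_lesion)])

    rows = []
    speedups = []
    antisym_residual = 0.0
    for animal_id, group in animals:
        profiles: dict[str, list[mt.SpeedProfile]] = {"stable": [],
                                                      "unstable": []}
        heights = []
        for state in ("stable", "unstable"):
            for t in range(trials_per_state):
                direction = "LR" if t % 2 == 0 else "RL"
                trial = simulate_trial(
                    geometry, style, state,
                    seed=int(rng.integers(2 ** 31)), direction=direction,
                    trial_ordinal=t + 1, animal_id=animal_id, group=group)
                profiles[state].append(trial.profile)
                if trial.posture is not None:
                    rows.append({
                        "animal": animal_id, "group": group, "state": state,
                        "progression": trial.posture.progression,
                        "height": trial.posture.height,
                    })
                    heights.append(trial.posture.height)
        idx = mt.speedup_index(profiles["stable"], profiles["unstable"])
        swapped = mt.speedup_index(profiles["unstable"], profiles["stable"])
        antisym_residual = max(antisym_residual, abs(idx + swapped))
        speedups.append({"animal": animal_id, "group": group,
                         "speedup_index": idx})

    df = pd.DataFrame(rows)
    # per-animal mean nose height is the height reference
    df["height"] = df["height"] - df.groupby("animal")["height"] \
        .transform("mean")

    def diff_and_se(col: str) -> tuple[float, float]:
        s = df[df.state == "stable"][col]
        u = df[df.state == "unstable"][col]
        diff = s.mean() - u.mean()
        se = math.sqrt(s.var(ddof=1) / len(s) + u.var(ddof=1) / len(u))
        return float(diff), float(se)

    prog_diff, prog_se = diff_and_se("progression")
    height_diff, height_se = diff_and_se("height")
    true_prog = (style.stable_offset_mean[0] - style.unstable_offset_mean[0])
    true_height = (style.stable_offset_mean[1] - style.unstable_offset_mean[1])
    return {
        "samples": df,
        "speedups": pd.DataFrame(speedups),
        "progression_diff_cm": prog_diff,
        "progression_se": prog_se,
        "true_progression_diff_cm": true_prog,
        "height_diff_cm": height_diff,
        "height_se": height_se,
        "true_height_diff_cm": true_height,
        "speedup_antisymmetry_residual": antisym_residual,
        "n_trials": len(df),
    }


def run_jump_recovery(seed: int = 0, p_jump: float = 0.8,
                      n_trials: int = 40,
                      geometry: CourseGeometry | None = None) -> dict:
    """Estimate the center-step skip probability of one animal."""
    geometry = geometry or scaled_fixture_geometry()
    style = CrossingStyle(p_jump=p_jump)
    rng = np.random.default_rng(seed)
    records = []
    for t in range(n_trials):
        trial = simulate_trial(geometry, style, "stable",
                               seed=int(rng.integers(2 ** 31)),
                               direction="LR" if t % 2 == 0 else "RL",
                               trial_ordinal=t + 1)
        records.append(trial.record)
    stats = mt.jump_probability(records, geometry, animal_id="J00")
    # 99% normal-approximation binomial interval around the true rate
    half = 2.576 * math.sqrt(p_jump * (1 - p_jump) / n_trials)
    return {
        "estimate": stats.probability,
        "true_probability": p_jump,
        "n_trials": n_trials,
        "ci99_halfwidth": half,
        "within_ci": abs(stats.probability - p_jump) <= half,
    }


# ---------------------------------------------------------------------------
# rendered-video tracking evaluation

def run_tracking_eval(seed: int = 0, n_crossings: int = 3,
                      geometry: CourseGeometry | None = None,
                      style: CrossingStyle | None = None,
                      match_tol_frames: int = 4) -> dict:
    """Render crossings, track them, and score the pipeline against the
    ground truth.

    Reports nose localization error (px), step-event recall/precision
    against the ground-truth forelimb contacts, and the rejection rate
    of hindlimb-contact candidate frames under the head-position
    constraint.
    """
    geometry = geometry or scaled_fixture_geometry()
    # moderate height spread keeps the rendered body clear of the
    # step-surface ROI bands; posture means are the standard defaults
    style = style or CrossingStyle(stable_offset_sd=(0.6, 0.4),
                                   unstable_offset_sd=(0.6, 0.4),
                                   path_noise_sd=0.0)
    rng = np.random.default_rng(seed)
    rois = tk.default_rois(geometry)
    params = tk.TrackParams()

    nose_errors = []
    n_true = n_matched = n_accepted = 0
    n_hind = n_hind_rejected = 0
    for c in range(n_crossings):
        direction = "LR" if c % 2 == 0 else "RL"
        state = "stable" if c % 2 == 0 else "unstable"
        gt = generate_crossing(geometry, style, state,
                               seed=int(rng.integers(2 ** 31)),
                               direction=direction)
        frames, true_bg = render_frames(gt, geometry)
        bg = tk.estimate_background(frames[:: max(1, len(frames) // 40)])
        poses, traces = tk.track(frames, bg, rois, params,
                                 frame_rate=geometry.frame_rate,
                                 fallback_heading=gt.direction_sign)
        for p in poses:
            if not p.valid:
                continue
            tx, ty = geometry.cm_to_px(*gt.nose_path[p.frame_index])
            nose_errors.append(math.hypot(p.nose[0] - tx, p.nose[1] - ty))

        crossings = ev.extract_crossings(poses, geometry)
        accepted, _rejected = ev.detect_step_events(
            traces, crossings, poses, geometry)
        n_accepted += len(accepted)
        fore = {e.step_index: round(e.time_s * geometry.frame_rate)
                for e in gt.fore_contacts}
        n_true += len(fore)
        for e in accepted:
            if e.step_index in fore and \
                    abs(e.frame - fore[e.step_index]) <= match_tol_frames:
                n_matched += 1
        # head-position constraint on hindlimb-contact frames
        for h in gt.contact_events:
            if h.limb != "hind" or not crossings:
                continue
            frame = int(round(h.time_s * geometry.frame_rate))
            result = ev.validate_step(frame, h.step_index, poses, geometry,
                                      crossings[0])
            n_hind += 1
            if not isinstance(result, ev.StepEvent):
                n_hind_rejected += 1

    nose_errors = np.asarray(nose_errors)
    return {
        "mean_nose_error_px": float(nose_errors.mean()),
        "p95_nose_error_px": float(np.percentile(nose_errors, 95)),
        "step_recall": n_matched / n_true if n_true else float("nan"),
        "step_precision": n_matched / n_accepted if n_accepted
        else float("nan"),
        "hind_rejection_rate": n_hind_rejected / n_hind if n_hind
        else float("nan"),
        "n_true_steps": n_true,
        "n_hind_candidates": n_hind,
    }


# ---------------------------------------------------------------------------
# evoked-potential recovery

def run_ep_recovery(seed: int = 0, n_trials: int = 40,
                    state: str = "unstable", noise_white_sd: float = 50.0,
                    include_ipsi: bool = True) -> dict:
    """Inject template EPs into noise and recover them through the full
    synchronization/epoching/filtering path."""
    from rungwalk import evoked
    from rungwalk.synth.ecog import (EcogSimSpec, StepFieldEvent,
                                     synthesize_ecog)

    spec = EcogSimSpec(noise_white_sd=noise_white_sd)
    interval = 1.5  # s between successive step contacts
    events = []
    j = 0
    for i in range(n_trials):
        events.append(StepFieldEvent((j + 1) * interval, "contra", state))
        j += 1
        if include_ipsi:
            events.append(StepFieldEvent((j + 1) * interval, "ipsi", state))
            j += 1
    duration = (j + 1) * interval + 1.0
    sim = synthesize_ecog(events, spec, seed, duration)

    recording = evoked.EcogRecording(sim.samples, sim.sample_rate)
    fmap = evoked.build_frame_sample_map(sim.strobe, sim.frame_counters,
                                         sim.sample_rate)
    epochs = evoked.extract_epochs(recording, list(sim.events), fmap)
    processed = [evoked.baseline_epoch(evoked.filter_epoch(e))
                 for e in epochs]
    anterior = spec.anterior_channels
    processed = [replace(e, data=e.data[anterior]) for e in processed]
    erps = evoked.average_evoked(processed, grouping=("side", "state"))

    tpl = spec.ep_templates[state]
    contra = erps[("contra", state)]
    peak = evoked.measure_peak(contra, "negative", window_ms=(0.0, 200.0))
    out = {
        "amplitude_uv": peak.amplitude_uv,
        "latency_ms": peak.latency_ms,
        "true_amplitude_uv": tpl.amplitude_uv,
        "true_latency_ms": tpl.latency_ms,
        "amplitude_rel_error": abs(peak.amplitude_uv - tpl.amplitude_uv)
        / abs(tpl.amplitude_uv),
        "latency_error_ms": abs(peak.latency_ms - tpl.latency_ms),
        "n_trials": n_trials,
    }
    if include_ipsi:
        ipsi = erps[("ipsi", state)]
        ipeak = evoked.measure_peak(ipsi, "negative", window_ms=(0.0, 200.0))
        out["ipsi_peak_uv"] = ipeak.amplitude_uv
    return out
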