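"""Ground-truth crossing kinematics.

A crossing is modelled as a nose trajectory moving at a base speed along
the travel axis, with a state-dependent speed change after the first
manipulated step, a posture offset (progression and height of the nose at
the moment the forepaw contacts the first manipulated step), per-step paw
contact events, and optional paw-slip events in the gaps.

The model is deliberately simple — tracking and event detection rely only
on segmentation geometry and ROI activation timing — but it is
kinematically consistent: contact times are strictly increasing, the jump
strategy produces no contacts on the center steps, and the nose height at
the trigger moment equals the configured base height plus the drawn
height offset exactly.

Default posture offsets reproduce the block-protocol condition means
observed in the assay: nose progression 0.77 ± 0.93 cm and height
0.61 ± 1.02 cm on stable trials, versus −0.25 ± 0.73 cm progression and
−0.25 ± 0.69 cm height on unstable trials.  In history mode (randomized
days) the current state has no effect and the previous two trials shift
the mean by ±(0.10, 0.07) cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rungwalk.geometry import CourseGeometry

LR = "LR"
RL = "RL"

#: Posture offsets are clipped to this magnitude (cm) so that rendered
#: paths stay inside the frame.
_OFFSET_CLIP = 3.0


@dataclass(frozen=True)
class ContactEvent:
    time_s: float
    step_index: int
    limb: str  # "fore" | "hind"
    side: str  # "left" | "right"


@dataclass(frozen=True)
class SlipGroundTruth:
    time_s: float
    gap_index: int
    limb: str


@dataclass(frozen=True)
class CrossingStyle:
    """Strategy and posture parameters of the simulated animal."""

    p_jump: float = 0.0
    base_speed: float = 12.0          # cm/s
    speed_jitter_sd: float = 0.05     # lognormal sd of per-trial multiplier
    unstable_speed_factor: float = 0.8
    nose_lead: float = 0.0            # cm, nose ahead of paw at contact
    hind_lag: float = 9.0             # cm, nose ahead when hind paw lands
    base_nose_height: float = 3.5     # cm above step surface
    stable_offset_mean: tuple[float, float] = (0.77, 0.61)
    stable_offset_sd: tuple[float, float] = (0.93, 1.02)
    unstable_offset_mean: tuple[float, float] = (-0.25, -0.25)
    unstable_offset_sd: tuple[float, float] = (0.73, 0.69)
    history_mode: bool = False
    history_offset_mean: tuple[float, float] = (0.10, 0.07)
    history_offset_sd: tuple[float, float] = (0.58, 0.57)
    p_slip: float = 0.0               # per-gap slip probability
    hind_slip_frac: float = 0.8
    include_hind: bool = True
    bump_sigma: float = 1.5           # cm, width of the posture height bump
    path_noise_sd: float = 0.0        # cm, white noise on nose height

    def __post_init__(self) -> None:
        for name in ("p_jump", "p_slip", "hind_slip_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")


@dataclass(frozen=True)
class CrossingGroundTruth:
    direction: str                    # "LR" | "RL"
    strategy: str                     # "walk" | "jump"
    times: np.ndarray                 # (T,) s
    nose_path: np.ndarray             # (T, 2) cm, columns (x, height)
    contact_events: tuple[ContactEvent, ...]
    slip_events: tuple[SlipGroundTruth, ...]
    posture_offset: tuple[float, float]
    trial_state: str
    frame_rate: float

    @property
    def direction_sign(self) -> int:
        return 1 if self.direction == LR else -1

    @property
    def fore_contacts(self) -> tuple[ContactEvent, ...]:
        return tuple(e for e in self.contact_events if e.limb == "fore")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def _resolve_offset(style: CrossingStyle, trial_state: str,
                    prev_states: tuple[str, str] | None,
                    rng: np.random.Generator) -> tuple[float, float]:
    if style.history_mode:
        mean = np.zeros(2)
        if prev_states is not None and prev_states[0] == prev_states[1]:
            sign = 1.0 if prev_states[0] == "stable" else -1.0
            mean = sign * np.asarray(style.history_offset_mean)
        sd = np.asarray(style.history_offset_sd)
    elif trial_state == "stable":
        mean = np.asarray(style.stable_offset_mean)
        sd = np.asarray(style.stable_offset_sd)
    else:
        mean = np.asarray(style.unstable_offset_mean)
        sd = np.asarray(style.unstable_offset_sd)
    draw = rng.normal(mean, sd)
    return tuple(np.clip(draw, -_OFFSET_CLIP, _OFFSET_CLIP))


def generate_crossing(geometry: CourseGeometry,
                      style: CrossingStyle,
                      trial_state: str,
                      seed: int,
                      direction: str = LR,
                      prev_states: tuple[str, str] | None = None,
                      ) -> CrossingGroundTruth:
    """Simulate one crossing with known ground truth.

    Parameters
    ----------
    trial_state:
        "stable" or "unstable" — the state of the center steps.
    direction:
        "LR" (left-to-right) or "RL".
    prev_states:
        States of the two preceding trials, used only in history mode.

    Returns
    -------
    CrossingGroundTruth
        Deterministic given ``seed``.
    """
    if trial_state not in ("stable", "unstable"):
        raise ValueError(f"unknown trial_state {trial_state!r}")
    if direction not in (LR, RL):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    dirsign = 1 if direction == LR else -1
    L = geometry.course_length

    def fwd(x_cm: float) -> float:
        """Distance travelled from the start side."""
        return x_cm if dirsign > 0 else L - x_cm

    strategy = "jump" if rng.random() < style.p_jump else "walk"
    offset = _resolve_offset(style, trial_state, prev_states, rng)
    prog_off, height_off = offset

    first_manip = geometry.first_center_step(dirsign)
    f_trig = fwd(geometry.near_edge(first_manip, dirsign))
    trigger_f = f_trig + style.nose_lead + prog_off

    # -- nose trajectory: piecewise-constant speed ------------------------
    dt = 1.0 / geometry.frame_rate
    speed = style.base_speed * float(rng.lognormal(0.0, style.speed_jitter_sd))
    slow = (style.unstable_speed_factor
            if (trial_state == "unstable" and strategy == "walk") else 1.0)
    f_start, f_end = 0.5, L - 0.5
    fs = [f_start]
    while fs[-1] < f_end:
        v = speed * (slow if fs[-1] >= f_trig else 1.0)
        fs.append(fs[-1] + v * dt)
    f = np.asarray(fs)
    f[-1] = min(f[-1], f_end)
    times = np.arange(len(f)) * dt

    x = f if dirsign > 0 else L - f
    height = style.base_nose_height + height_off * np.exp(
        -((f - trigger_f) / style.bump_sigma) ** 2)
    if style.path_noise_sd > 0:
        height = height + rng.normal(0.0, style.path_noise_sd, len(f))
    nose_path = np.column_stack([x, height])

    def time_at(f_target: float) -> float | None:
        """Linearly interpolated time at which the nose passes f_target."""
        if f_target <= f[0] or f_target > f[-1]:
            return None
        i = int(np.searchsorted(f, f_target))
        t0, t1 = times[i - 1], times[i]
        return float(t0 + (t1 - t0) * (f_target - f[i - 1]) / (f[i] - f[i - 1]))

    # -- paw contacts -----------------------------------------------------
    center = set(geometry.center_step_indices)
    side = "left" if rng.random() < 0.5 else "right"
    contacts: list[ContactEvent] = []
    step_order = (range(geometry.n_steps) if dirsign > 0
                  else range(geometry.n_steps - 1, -1, -1))
    for k in step_order:
        if strategy == "jump" and k in center:
            continue
        lead = style.nose_lead + (prog_off if k == first_manip else 0.0)
        t_fore = time_at(fwd(geometry.near_edge(k, dirsign)) + lead)
        if t_fore is not None:
            contacts.append(ContactEvent(t_fore, k, "fore", side))
            side = "right" if side == "left" else "left"
        if style.include_hind:
            t_hind = time_at(fwd(geometry.near_edge(k, dirsign))
                             + style.hind_lag)
            if t_hind is not None:
                contacts.append(ContactEvent(t_hind, k, "hind",
                                             "left" if side == "right"
                                             else "right"))
    contacts.sort(key=lambda e: e.time_s)

    # -- slips ------------------------------------------------------------
    slips: list[SlipGroundTruth] = []
    for g in range(geometry.n_steps - 1):
        if strategy == "jump" and (g + 1 in center or g in center):
            continue
        if rng.random() < style.p_slip:
            gl, gr = geometry.gap_edges(g)
            t_slip = time_at(fwd((gl + gr) / 2.0) + style.nose_lead)
            if t_slip is not None:
                limb = ("hind" if rng.random() < style.hind_slip_frac
                        else "fore")
                slips.append(SlipGroundTruth(t_slip, g, limb))
    slips.sort(key=lambda e: e.time_s)

    return CrossingGroundTruth(
        direction=direction,
        strategy=strategy,
        times=times,
        nose_path=nose_path,
        contact_events=tuple(contacts),
        slip_events=tuple(slips),
        posture_offset=offset,
        trial_state=trial_state,
        frame_rate=geometry.frame_rate,
    )
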