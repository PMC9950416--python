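"""Behavior-protocol scheduler.

The study protocol spans a month of daily sessions with graded levels of
environmental uncertainty about the two manipulated center steps:

====  =======================  =====================================
day   condition                center-step state per trial
====  =======================  =====================================
0     habituation              stable (no rewards, short session)
1-4   stable                   stable
5     transition_to_unstable   20 stable trials, then unstable
6-10  unstable                 unstable
11    transition_to_stable     20 unstable trials, then stable
12    stable                   stable
13-16 randomized               i.i.d. Bernoulli draw per trial
17    challenge                unstable (all steps free to rotate)
====  =======================  =====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STABLE = "stable"
UNSTABLE = "unstable"

#: (condition_label, number of consecutive days) in protocol order.
_DAY_PLAN: tuple[tuple[str, int], ...] = (
    ("habituation", 1),
    ("stable", 4),
    ("transition_to_unstable", 1),
    ("unstable", 5),
    ("transition_to_stable", 1),
    ("stable", 1),
    ("randomized", 4),
    ("challenge", 1),
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of the session schedule.

    trials_per_session:
        Trials simulated per daily session.
    transition_pre_trials:
        Number of trials of the pre-change state at the start of a
        transition session (the protocol uses 20).
    p_unstable_random:
        Per-trial probability of the unstable state on randomized days.
    include_challenge:
        Whether to append the final all-steps-released session.
    """

    trials_per_session: int = 60
    transition_pre_trials: int = 20
    p_unstable_random: float = 0.5
    include_challenge: bool = True

    def __post_init__(self) -> None:
        if self.trials_per_session <= 0:
            raise ValueError("trials_per_session must be positive")
        if self.transition_pre_trials <= 0:
            raise ValueError("transition_pre_trials must be positive")
        if not 0.0 <= self.p_unstable_random <= 1.0:
            raise ValueError("p_unstable_random must be in [0, 1]")


@dataclass(frozen=True)
class SessionSpec:
    """One daily session: its condition and the state of the center steps
    on every trial."""

    day_index: int
    condition_label: str
    trial_states: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trial_states)

    @property
    def change_trial(self) -> int | None:
        """1-based ordinal of the first trial after the state change on
        transition sessions, else None."""
        if not self.condition_label.startswith("transition"):
            return None
        first = self.trial_states[0]
        for i, s in enumerate(self.trial_states):
            if s != first:
                return i + 1
        return None


def generate_protocol(config: ProtocolConfig | None = None,
                      seed: int = 0) -> list[SessionSpec]:
    """Build the full day-by-day schedule.

    Deterministic given ``seed``; only the randomized days consume
    randomness (one i.i.d. Bernoulli draw per trial).
    """
    config = config or ProtocolConfig()
    rng = np.random.default_rng(seed)
    n = config.trials_per_session
    pre = config.transition_pre_trials
    if pre >= n:
        raise ValueError(
            "transition_pre_trials must be smaller than trials_per_session")

    sessions: list[SessionSpec] = []
    day = 0
    for label, n_days in _DAY_PLAN:
        if label == "challenge" and not config.include_challenge:
            continue
        for _ in range(n_days):
            if label in ("habituation", "stable"):
                states = (STABLE,) * n
            elif label == "unstable" or label == "challenge":
                states = (UNSTABLE,) * n
            elif label == "transition_to_unstable":
                states = (STABLE,) * pre + (UNSTABLE,) * (n - pre)
            elif label == "transition_to_stable":
                states = (UNSTABLE,) * pre + (STABLE,) * (n - pre)
            elif label == "randomized":
                draws = rng.random(n) < config.p_unstable_random
                states = tuple(UNSTABLE if d else STABLE for d in draws)
            else:  # pragma: no cover - exhaustive over _DAY_PLAN
                raise AssertionError(label)
            sessions.append(SessionSpec(day, label, states))
            day += 1
    return sessions
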