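"""Generate the day-by-day training schedule.

The protocol ramps up environmental uncertainty: stable days, a
mid-session switch to unstable center steps, unstable days, a switch
back, then days where the state is randomized on every trial.
"""

from rungwalk.synth.protocol import ProtocolConfig, generate_protocol

sessions = generate_protocol(ProtocolConfig(trials_per_session=60), seed=1)

for s in sessions:
    n_unstable = sum(st == "unstable" for st in s.trial_states)
    change = f", change at trial {s.change_trial}" if s.change_trial else ""
    print(f"day {s.day_index:2d}  {s.condition_label:<24s} "
          f"{n_unstable:2d}/{s.n_trials} unstable trials{change}")

# The two transition days each present exactly 20 trials of the old
# state before the switch; randomized days draw each trial's state
# independently (about half unstable).
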