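"""Generate the braille attention-switching trial schedule.

Builds the default 80-trial schedule (5 stimuli per trial, target
probability 0.2) and prints the exact target bookkeeping plus the first few
rows of the BIDS-style event table sampled at the OPM rate (375 Hz).
"""

from megfingerprint import generate_schedule, schedule_to_events

schedule = generate_schedule(n_trials=80, seed=1)
print(f"trials: {schedule.n_trials}, stimulus slots: {schedule.n_slots}")
print(f"targets: {schedule.n_targets}, non-targets: {schedule.n_nontargets}")
sides = [t.cue_side for t in schedule.trials]
print(f"attend-left trials: {sides.count('left')}, attend-right: {sides.count('right')}")

events = schedule_to_events(schedule, sampling_rate_hz=375.0)
print("\nfirst events of trial 1 (sample = round(onset x 375 Hz)):")
print(events.head(7).to_string(index=False))
# The schedule always contains exactly 20% targets (80 of 400 slots here);
# onsets within a trial are 1.17 + k*1.37 s after the cue ends.
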