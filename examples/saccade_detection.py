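"""Detect saccades and decompose search time in a synthetic gaze trace.

Generates one session with millisecond gaze traces, then runs the
signal-level pipeline on a single search trial: velocity-threshold saccade
detection (1-ms resampling, 15-ms smoothing, 0.025 deg/ms threshold, 1-deg
amplitude floor), classification of the initial saccade as direct or not,
and the four-way decomposition of search time into gaze at environmental
fractals, the target, the start position, and everything else.
"""

from patchforage import GeneratorParams, generate_session
from patchforage.gaze_processing import (
    TaskGeometry,
    assign_gaze_components,
    classify_initial_saccade,
    count_inspected_fractals,
    detect_saccades,
)

geometry = TaskGeometry()
params = GeneratorParams(n_trials=40, blink_prob=0.0)
trials, gaze, truth = generate_session(params, seed=11)

search = trials[(trials.task == "search") & (trials.outcome == "correct")]
merged = search.merge(truth.per_trial, on="trial_id")
trial = merged[merged.n_env_fixations >= 2].iloc[0]  # an exploratory trial
trace = gaze[gaze.trial_id == trial.trial_id]

saccades = detect_saccades(trace)
print(f"trial {trial.trial_id}: {len(saccades)} saccades in "
      f"{trial.search_dur_s:.2f} s of search")
for s in saccades:
    print(f"  t={s.t_start:7.0f} ms  amplitude={s.amplitude:5.2f} deg  "
          f"peak velocity={s.peak_velocity:.3f} deg/ms")

first = classify_initial_saccade(trial, saccades, geometry)
print(f"initial saccade direct to target: {first.direct} "
      f"(angle to target {first.angle_to_target:.1f} deg)")

comps = assign_gaze_components(trace, trial, geometry)
print(f"components (s): environmental={comps.environmental:.3f} "
      f"target={comps.target:.3f} start={comps.start:.3f} "
      f"other={comps.other:.3f} (sum={comps.total:.3f})")
print(f"environmental fractals inspected (>=50 ms): "
      f"{count_inspected_fractals(trace, geometry, trial=trial)}")
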