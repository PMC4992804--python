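"""Wrong-recognition accumulation under fatigue, and trajectory comparison.

The fatigue curve tracks where in a session the wrong recognitions pile up:
a late steep rise of the accumulation rate Er = En/Et means errors cluster
at the end (fatigue).  The trajectory metric compares a walked path against
the desired one via arc-length resampling: correlation of the lateral
deviation profiles plus the total-length difference.
"""

import numpy as np

import p300bci as p

train_session = p.simulate_session(
    p.SimulationConfig(target_sequence=p.blocked_targets(160, 5, seed=50), seed=50)
)
model, _ = p.train_pipeline(train_session, p.TrainingConfig(seed=51))

# a fatiguing operator: amplitude decays and jitter grows over the session
tired = p.simulate_session(
    p.SimulationConfig(target_sequence=p.blocked_targets(100, 5, seed=60),
                       seed=60, fatigue_rate=0.008)
)
run = p.run_mode(tired, model, "avg1")
flags = [o == "wrong" for o in run.outcomes]
curve = p.fatigue_curve(flags)
if curve.defined:
    half = len(flags) // 2
    print(f"wrong recognitions: {curve.et} of {len(flags)} trials; "
          f"accumulation rate at mid-session Er[50] = {curve.er[half]:.2f} "
          f"(< 0.5 means errors cluster late)")
else:
    print("no wrong recognitions in this session")

# trajectory comparison: a wobbly walk along a 400 cm S-shaped path
x = np.linspace(0, 400, 200)
desired = np.column_stack([x, 40 * np.sin(2 * np.pi * x / 400)])
actual = np.column_stack([x, 44 * np.sin(2 * np.pi * x / 400)
                          + 3 * np.sin(2 * np.pi * x / 60)])
r, dlen = p.compare_trajectories(actual, desired)
print(f"trajectory vs desired: PPMCC = {r:.3f}, length difference = {dlen:+.1f}%")
# A PPMCC near 1 with a small length difference means the robot tracked the
# taped path closely without detours.
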