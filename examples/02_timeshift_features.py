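"""Time-shift correlation features: the bell-shaped signature of a P300.

A 70-sample epoch is correlated with the subject's P300 template at 31
temporal shifts (-60..+60 ms in 4 ms steps).  A matched epoch produces a
bell-shaped correlation curve whose peak position reveals the latency
offset; a mismatched epoch produces an irregular low curve.
"""

import numpy as np

import p300bci as p


def single_trial(latency_offset_ms):
    cfg = p.SimulationConfig(
        target_sequence=(1,), noise_sd=0.0, latency_jitter=0.0,
        amplitude_variability=0.0, p300_peak_latency=300.0 + latency_offset_ms,
    )
    return p.simulate_session(cfg)


template = p.template_from_session(single_trial(0), n_epochs=1)

for delta in (0, 24):
    trial = p.session_epochs(single_trial(delta))[0]
    fv = p.timeshift_features(trial[1], template)  # attended interval
    print(f"P300 delayed by {delta:+d} ms -> feature peak at "
          f"{fv.peak_shift_ms:+.0f} ms shift, r_max = {fv.r.max():.3f}")

# a non-target interval of the same trial: no bell, low correlations
trial = p.session_epochs(single_trial(0))[0]
fv_nt = p.timeshift_features(trial[3], template)
print(f"non-target interval -> r_max = {fv_nt.r.max():.3f} "
      f"(constant window correlates at 0 by convention)")
print("feature curve around the peak (matched, 0 ms):",
      np.round(p.timeshift_features(trial[1], template).r[13:18], 3).tolist())
# The peak shift equals the injected latency exactly: the feature vector
# converts latency uncertainty into the *position* of its maximum.
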