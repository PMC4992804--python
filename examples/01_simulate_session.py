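"""Generate a labeled synthetic EEG session under the oddball paradigm.

Each 1050 ms trial flashes four stimuli (100 ms flash + 100 ms gap, then a
250 ms pause); the attended stimulus elicits a P300-like deflection ~300 ms
after its flash.
"""

import numpy as np

import p300bci as p

config = p.SimulationConfig(
    target_sequence=p.blocked_targets(20, block_length=5, seed=0), seed=0
)
session = p.simulate_session(config)

rec = session.recording
print(f"recording: {rec.n_samples} samples x {rec.n_channels} channels "
      f"({rec.channel_labels}) at {rec.sampling_rate:g} Hz "
      f"= {rec.duration_ms / 1000:.2f} s")
print(f"trials: {session.schedule.n_trials}, each "
      f"{session.schedule.trial_length_ms:g} ms")
print(f"truth sequence (attended stimulus per trial): {session.truth}")
print(f"injected latency jitter, first 5 trials (ms): "
      f"{np.round(session.injected_latencies[:5], 1).tolist()}")
print(f"signal scale: P300 amplitude {config.p300_amplitude:g} uV over "
      f"background noise sd {config.noise_sd:g} uV ({config.noise_band[0]:g}-"
      f"{config.noise_band[1]:g} Hz band)")
# The jitter values are the ground truth the time-shift features must absorb;
# each stays within the +/-60 ms search range of the feature extractor.
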