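"""Train the 31-15-1 network and classify single trials.

The training session provides 4 feature vectors per trial (one per stimulus
interval), labeled 1 for the attended interval and 0 otherwise.  The trained
network scores each interval; a trial is *legal* when exactly one score
exceeds the 0.6 threshold.
"""

import numpy as np

import p300bci as p

train_session = p.simulate_session(
    p.SimulationConfig(target_sequence=p.blocked_targets(160, 5, seed=10), seed=10)
)
model, report = p.train_pipeline(train_session, p.TrainingConfig(seed=11))
print(f"trained {model.n_parameters}-parameter network in {report.epochs_run} "
      f"epochs ({report.stop_reason}); MSE train/test/stop = "
      f"{report.mse_train:.4f}/{report.mse_test:.4f}/{report.mse_stop:.4f}")

X, T = p.training_matrix(train_session, model.template)
diag = p.threshold_diagnostic(model, X, T, n_trials=20, seed=12)
print(f"threshold diagnostic on 20 random trials: target median "
      f"{diag['target_median']:.2f}, non-target median "
      f"{diag['nontarget_median']:.2f} -> operating threshold "
      f"{diag['configured_threshold']:.1f}")

test_session = p.simulate_session(
    p.SimulationConfig(target_sequence=p.blocked_targets(20, 5, seed=20), seed=20)
)
trials = p.session_epochs(test_session)
for i in (0, 1, 2):
    from p300bci.decision import score_epochs

    scores = score_epochs(model, trials[i])
    d = p.judge_trial(scores, model.threshold, i)
    print(f"trial {i}: scores {np.round(scores, 3).tolist()} -> {d.status}"
          + (f", stimulus {d.selected_ordinal} ({d.command})" if d.is_legal else ""))
acc = p.single_epoch_accuracy(trials, test_session.truth, model)
print(f"single-epoch accuracy over {len(trials)} held-out trials: {acc:.0%}")
# Scores near 1 mark the attended interval; the legality rule rejects trials
# where zero or several intervals cross the threshold.
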