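"""Train the SSA-variant classifier end to end on a simulated cohort.

Simulates train and held-out cohorts, fits the full pipeline
(decomposition -> 15 base learners -> LSTM/attention meta-network) with
reduced hyperparameter grids for speed, and reports held-out metrics.
"""

from emdeepsd import (
    PipelineConfig,
    SimulationConfig,
    auc_ci,
    confusion_metrics,
    predict_pipeline,
    simulate_profiles,
    train_pipeline,
)

train = simulate_profiles(SimulationConfig(n_cancer=60, n_control=60,
                                           effect_size=0.5, seed=1))
test = simulate_profiles(SimulationConfig(n_cancer=20, n_control=20,
                                          effect_size=0.5, seed=101))

cfg = PipelineConfig(variant="ssa", fast_grids=True, seed=0)
bundle = train_pipeline(train, variant="ssa", config=cfg)
print(f"base learners fitted: {len(bundle.stack.columns)}")
print(f"meta-network loss: {bundle.net.first_epoch_loss:.3f} (epoch 1) "
      f"-> {bundle.net.final_loss:.3f} (epoch {cfg.epochs})")

preds = predict_pipeline(bundle, test)
y = preds["label"].to_numpy()
p = preds["probability"].to_numpy()
auc, (lo, hi) = auc_ci(y, p)
report = confusion_metrics(y, p, threshold=0.5)
print(f"held-out AUC = {auc:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"sensitivity = {report.sensitivity:.3f}, "
      f"specificity = {report.specificity:.3f}, "
      f"accuracy = {report.accuracy:.3f}, F1 = {report.f1:.3f}")
print("An AUC near 1 on this strong-effect cohort means the stacked "
      "pipeline recovered the planted cancer signal on unseen samples.")
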