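"""Train the cascade on synthetic data and evaluate it (a few minutes on CPU).

A scaled-down run: 20 train / 8 test images at 64x64, channel schedule
(16, 32, 64), 15 epochs.  The reference full-scale recipe is 200 epochs at
(32, 64, 128) with learning-rate decay at epochs 150 and 190.
"""

from vesselseg import NetworkConfig, SyntheticSpec, TrainConfig, evaluate, generate_dataset, train

spec = SyntheticSpec(height=64, width=64, seed=20)
train_set, test_set = generate_dataset(spec, 20, 8)

net_cfg = NetworkConfig(channel_schedule=(16, 32, 64), seed=0)
train_cfg = TrainConfig(epochs=15, lr_decay_epochs=(), seed=0)

model, state = train(net_cfg, train_cfg, train_set, test_set, verbose=True)
pooled, per_image = evaluate(model, test_set)

print(f"\nbest epoch {state.best_epoch} (test AUC {state.best_metric:.4f})")
print(f"pooled test metrics: SE {pooled.se:.4f}  SP {pooled.sp:.4f}  "
      f"ACC {pooled.acc:.4f}  F1 {pooled.f1:.4f}  AUC {pooled.auc:.4f}")
# SE is the fraction of vessel pixels found, SP the fraction of background
# kept clean; AUC summarises the probability map across all thresholds.
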