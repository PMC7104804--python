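"""Train the regression network on a synthetic phantom cohort.

Generates 240 phantom subjects (32×40×32 voxels, two signal spheres whose
intensity tracks the BMI-like target), splits them 160/40/40, trains for
six epochs and prints held-out metrics.  With the default couplings the
held-out Pearson r climbs above 0.9 within those epochs; the MAE keeps
improving with longer training as the output scale calibrates.  Takes a
few minutes on one CPU.
"""

import braincam as bc

spec = bc.PhantomSpec(seed=0)
cohort, truth = bc.generate_cohort(spec, 240)
train_set, val_set, test_set = bc.split_cohort(cohort, (160 / 240, 40 / 240, 40 / 240), seed=0)

net = bc.build_model(bc.reference_config(input_shape=spec.volume_shape), seed=0)
total, trainable = net.count_parameters()
print(f"network: {total} parameters ({trainable} trainable)")

config = bc.TrainConfig(epochs=6, learning_rate=5e-3, seed=0, standardize_covariates=True)
result = bc.train(net, train_set, val_set, config)

print("\nepoch  train_loss  val_mae")
for h in result.history:
    print(f"{h['epoch']:>5}  {h['train_loss']:>10.2f}  {h['val_mae']:>7.2f}")
print(f"best epoch: {result.best_epoch}")

metrics = bc.evaluate(result.best_net, test_set)
print(f"\nheld-out: MAE {metrics.mae:.2f} kg/m²,  Pearson r {metrics.pearson_r:.3f},  R² {metrics.r_squared:.3f}")
print("r measures whether the net reads the planted signal; MAE also needs the output scale calibrated.")
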