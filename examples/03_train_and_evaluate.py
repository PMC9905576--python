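"""Train the network unsupervised on a small N01 problem and score it.

A short demonstration run: 120 spectra, 400 epochs (the benchmark default
is 5000).  Training sees only the measured spectra; the stored
concentrations are used afterwards, for scoring only.  Expect a mean
relative error of several percent at this scale — the printed least-squares
row is the noise-floor comparison for a constant background.
"""

import pinncal as pc

train_ds = pc.synthesize_dataset(pc.ScenarioConfig("N01", n_samples=120, seed=5))
test_ds = pc.synthesize_dataset(pc.ScenarioConfig("N01", n_samples=120, seed=6))

model = pc.build_model(pc.ModelConfig(), seed=5)
model, history = pc.train(
    model, train_ds, config=pc.TrainingConfig(epochs=400, seed=5), log_every=100
)
print(f"\nalpha = {history.alpha:.3f}, final L_tot = {history.total[-1]:.1f}")

result = pc.predict(model, test_ds.measured, test_ds.references)
report = pc.evaluate_predictions(test_ds.concentrations, result.concentrations)
print("network   ", report.summary())

c_ls, _ = pc.least_squares_constant_background(test_ds.measured, test_ds.references)
ls_report = pc.evaluate_predictions(test_ds.concentrations, c_ls)
print("least sq. ", ls_report.summary())
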