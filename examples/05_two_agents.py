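"""Quantify two co-emitting agents simultaneously (scenario N06).

The two-agent network has the same body and a width-2 output; the loss uses
both reference spectra.  Each agent's concentration is drawn independently,
so the model must attribute overlapping emission (the 486 nm and 480 nm
lines sit 6 nm apart) to the right species while the shaped background
wanders underneath.
"""

import pinncal as pc

train_ds = pc.synthesize_dataset(pc.ScenarioConfig("N06", n_samples=100, seed=21))
test_ds = pc.synthesize_dataset(pc.ScenarioConfig("N06", n_samples=100, seed=22))

model = pc.build_model(pc.ModelConfig(n_outputs=2), seed=21)
model, history = pc.train(
    model, train_ds, config=pc.TrainingConfig(epochs=1000, seed=21)
)
print(f"alpha = {history.alpha:.3f} (mean of the two per-agent weights)")

result = pc.predict(model, test_ds.measured, test_ds.references)
report = pc.evaluate_predictions(test_ds.concentrations, result.concentrations)
print(report.summary())
print(
    "\nper-class R2 close to one means both species' concentrations are"
    "\nrecovered on held-out spectra despite the overlapping lines and the"
    "\nrandomly scaled, randomly shifted background."
)
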