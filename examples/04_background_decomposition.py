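"""Decompose one spectrum into agent + background after a short training run.

Uses the shaped-background scenario (N03) without noise so the quality of
the background reconstruction is visible directly: the printed RMS compares
the predicted background with the true generating one, and the agent
spectrum is rebuilt from the predicted concentration and the reference.
"""

import numpy as np

import pinncal as pc

train_ds = pc.synthesize_dataset(
    pc.ScenarioConfig("N03", n_samples=150, seed=9, noise_sd=0.0)
)
model = pc.build_model(pc.ModelConfig(), seed=9)
pc.train(model, train_ds, config=pc.TrainingConfig(epochs=500, seed=9))

sample = train_ds.sample(0)
result = pc.predict(model, sample.measured, train_ds.references)

true_bg = sample.components["background"].intensities
pred_bg = result.background.intensities
rms = np.sqrt(np.mean((pred_bg - true_bg) ** 2))
print(f"true concentration      : {sample.concentrations[0]:.4f}")
print(f"predicted concentration : {result.concentrations[0]:.4f}")
print(f"background RMS error    : {rms:.2f} a.u. (true peak {true_bg.max():.1f} a.u.)")
print(
    "\nthe predicted background tracks the 75 nm-wide bump while the sharp"
    "\nemission lines stay in the agent term - the separation the smoothness"
    "\nprior is designed to enforce"
)
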