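# pinncal — unsupervised physics-informed calibration of spectra

`pinncal` extracts analyte concentrations from emission spectra that are
contaminated by a *non-stationary* background and noise, without any
labelled calibration measurements.  It is aimed at spectroscopy settings —
laser-induced fluorescence, Raman, LIBS and similar — where controlled
experiments with known concentrations are impractical, but the physics is
known: the unit-concentration **reference spectrum** `I0_j(λ)` of each
agent, and the expectation that the background is spectrally smooth.

## The method

A measurement is modelled as a linear mixture plus nuisance terms,

    I(λ) = Σ_j c_j · I0_j(λ) + I_b(λ) + I_n(λ),

and a two-part convolutional network is trained *unsupervised*: an
autoencoder (with max-pool indices mirrored by max-unpool layers) predicts
the background `I_pb`, the predicted background is subtracted, and a small
convolutional + dense head predicts the concentrations `c_p`.  The training
loss encodes the physics instead of labels:

    L_tot = Σ_λ (I − Σ_j c_pj·I0_j − I_pb)²  +  α · Σ_λ (dI_pb/dλ)²

— reconstruction fidelity plus background smoothness.  The weight α is
estimated from the reference spectrum alone as α = ℓ², where
ℓ = ΣI0 / Σ|dI0/dλ| is the characteristic wavelength scale of the
reference's features.  Six seeded synthetic benchmark scenarios (N01–N06:
constant, randomly scaled, shaped and randomly wandering backgrounds; sharp
and broad references; one and two agents) are part of the package, so every
claim is reproducible from code alone.  See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
import pinncal as pc

train = pc.synthesize_dataset(pc.ScenarioConfig("N01", n_samples=120, seed=5))
test  = pc.synthesize_dataset(pc.ScenarioConfig("N01", n_samples=120, seed=6))

model = pc.build_model(pc.ModelConfig(), seed=5)
model, hist = pc.train(model, train, config=pc.TrainingConfig(epochs=400, seed=5))

result = pc.predict(model, test.measured, test.references)
report = pc.evaluate_predictions(test.concentrations, result.concentrations)
print(report.summary())
```

Running `python examples/03_train_and_evaluate.py` (the same computation
with a least-squares comparison) prints:

```
alpha = 12.677, final L_tot = 17310.6
network    agent 1: R2=0.9981  mean relative error=3.441% (n=117 with c>=0.1)  mean |error|=0.02211
least sq.  agent 1: R2=0.9996  mean relative error=1.561% (n=117 with c>=0.1)  mean |error|=0.01055
```

Read: after a short 400-epoch run on 120 spectra the network recovers the
held-out concentrations to ~3.4% mean relative error (targets ≥ 0.1 on the
0–2 range) with no labels ever seen; the per-spectrum least-squares row is
the noise floor of this constant-background scenario (~1.6% — the best any
estimator can do at noise sd 5 under this metric).  Longer training at the
benchmark scale closes most of the remaining gap; the `examples/` scripts
cover dataset generation, the α heuristic and background decomposition.

There is also a small CLI for shell use:

```bash
pinncal simulate --scenario N04 --n 1000 --seed 7 --out data/
pinncal train --config train.cfg
pinncal predict --model model.npz --in data/ --out pred.tsv
pinncal evaluate --pred pred.tsv --truth data/samples.tsv
```

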