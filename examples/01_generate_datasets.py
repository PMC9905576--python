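"""Generate one of each synthetic benchmark scenario and describe it.

Each scenario pairs a known reference spectrum with a background family of
increasing difficulty (constant, randomly scaled, shaped, randomly shaped
and shifted) plus white noise of sd 5.  The printed numbers are the exact
decomposition of the first sample: measured = agent + background + noise.
"""

import numpy as np

import pinncal as pc

for scenario in pc.SCENARIO_IDS:
    ds = pc.synthesize_dataset(pc.ScenarioConfig(scenario, n_samples=5, seed=42))
    s = ds.sample(0)
    peak = ds.grid.values[np.argmax(s.measured.intensities)]
    print(
        f"{scenario}: {ds.references.n_agents} agent(s), c = {np.round(s.concentrations, 3)}, "
        f"background peak {s.components['background'].intensities.max():7.2f} a.u., "
        f"brightest wavelength {peak:.0f} nm"
    )
    total = (
        s.components["agent"].intensities
        + s.components["background"].intensities
        + s.components["noise"].intensities
    )
    assert np.array_equal(total, s.measured.intensities)
print("\nevery measured spectrum is the exact sum of its stored components")
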