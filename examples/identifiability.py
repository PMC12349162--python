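"""How well can each circuit parameter be determined from one sweep?

Computes the first-order (Fisher/Jacobian) relative standard deviation
of every parameter at the generating truth, under the default noise
model, for the three-segment circuit and for the single-time-constant
baseline. This is a property of the measurement design (band, grid,
noise), not of any particular fit: it bounds what ANY estimator can do.
"""

import zskin
from zskin.fitting import linearized_stddevs
from zskin.synth import NoiseModel

profile = zskin.default_profiles()["gold"]
spectrum = zskin.generate_spectrum(profile, 0.0, noise=NoiseModel.none())

print("three-segment circuit (model3), default dry-electrode truth:")
sig3 = linearized_stddevs(spectrum, profile.model, profile.truth)
for name, s in sig3.items():
    flag = "   <-- not identifiable from this sweep" if s > 0.25 else ""
    print(f"  {name:>7}: {s:7.1%}{flag}")

model0 = zskin.make_model("model0")
fit0 = zskin.fit_multistart(spectrum, model0, zskin.FitConfig(n_starts=40, rng_seed=0))
sig0 = linearized_stddevs(spectrum, model0, fit0.parameters)
print("\nsingle time constant (model0), at its own best fit of the same sweep:")
for name, s in sig0.items():
    print(f"  {name:>7}: {s:7.1%}")

print("\nThe 20 Hz-1 kHz band (1.7 decades) pins the dominant interface pair")
print("(R0, C0) to within ~10%, but not the nine-parameter fine structure --")
print("which is why trend tracking uses the parsimonious model by default.")
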