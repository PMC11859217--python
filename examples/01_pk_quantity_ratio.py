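"""Fit single-compartment profiles and derive an in-vivo quantity ratio.

Builds noiseless concentration-time profiles for two hypothetical
components, fits the biexponential model to each, and prints the fitted
parameters together with the implied in-vivo drug quantity ratio — the
bridge from plasma profiles to administered-dose ratios.
"""

from comboratio import pk

SAMPLING_TIMES = [0.17, 0.5, 1, 1.5, 4, 7, 12, 24]

truth_a = pk.PKFit("A", Kc=5.2, ka=11.5, ke=0.07)
truth_b = pk.PKFit("B", Kc=0.41, ka=11.4, ke=0.20)

fits = {}
for truth in (truth_a, truth_b):
    points = [
        pk.ProfilePoint(time=t, concentration=pk.predict_concentration(truth, t))
        for t in SAMPLING_TIMES
    ]
    fits[truth.component] = pk.fit_profile(points, component=truth.component)

for name, fit in fits.items():
    print(f"{name}: Kc={fit.Kc:.3f} mg/L  ka={fit.ka:.3f}/h  ke={fit.ke:.3f}/h  "
          f"R^2={fit.r_squared:.4f}")

q = pk.quantity_ratio(fits["A"], fits["B"])
print(f"\nin-vivo quantity ratio A:B = {q:.2f}:1")
print("(the amount of A in the body per unit of B implied by the two profiles)")
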