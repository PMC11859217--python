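"""Median-effect fits and the Chou-Talalay Combination Index.

Fits the median-effect equation to monotherapy dose-response data for two
drugs, then scores a combination at one effect level: CI < 1 means the
combination needed less total (dose-fraction) drug than additivity
predicts — synergy.
"""

import numpy as np

from comboratio import synergy

# monotherapy data generated from known median-effect curves
doses = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
fa_a = (doses / 2.0) ** 1.5 / (1 + (doses / 2.0) ** 1.5)   # Dm=2, m=1.5
fa_b = (doses / 3.0) ** 1.0 / (1 + (doses / 3.0) ** 1.0)   # Dm=3, m=1.0

fit_a = synergy.fit_median_effect(doses, fa_a, drug="A")
fit_b = synergy.fit_median_effect(doses, fa_b, drug="B")
print(f"A: Dm={fit_a.Dm:.3f}, m={fit_a.m:.3f}")
print(f"B: Dm={fit_b.Dm:.3f}, m={fit_b.m:.3f}")

effect = 0.75  # observed combination effect (fraction affected)
alone = {d: synergy.equipotent_dose(f, effect) for d, f in (("A", fit_a), ("B", fit_b))}
combo = {"A": 1.2, "B": 1.5}  # doses actually used in combination
ci = synergy.combination_index(combo, alone)
print(f"\nequipotent monotherapy doses at fa={effect}: "
      + ", ".join(f"{k}={v:.2f}" for k, v in alone.items()))
print(f"CI = {ci:.3f} -> {synergy.classify_interaction(ci)}")
print("(CI sums each drug's combination dose as a fraction of its "
      "same-effect monotherapy dose)")
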