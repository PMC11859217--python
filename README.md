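# comboratio

Compartment-model and neural-network analysis of combination-medication
component ratios.

Fixed-ratio drug combinations — such as the *Cynanchum otophyllum* saponins
M1 and M2 given alongside phenobarbital (PHB) against epilepsy, or the
*Erigeron breviscapus* flavonoids breviscapine (Bre) and scutellarin (Scu)
against ischemic stroke — pose a recurring question: if we want a stronger
overall effect, how should the administered ratio of the active components
change?  `comboratio` implements a desk-scale answer built from four pieces:

1. **Single-compartment pharmacokinetics.**  Each component's plasma
   profile after extravascular dosing follows
   C(t) = K_c (e^(−k_e t) − e^(−k_a t)), with absorption rate k_a (1/h),
   elimination rate k_e (1/h), and lumped scale
   K_c = k_a F Y₀ / [V_d (k_a − k_e)] (mg/L).  Fitting two components by
   nonlinear least squares yields the **in-vivo drug quantity ratio**

       Q_i : Q_j = K_c,i (k_a,i − k_e,i) k_a,j / [K_c,j (k_a,j − k_e,j) k_a,i],

   the bridge between plasma concentrations and administered doses: when
   the quantity ratio moves from q_old to q_new, the administered-dose
   ratio scales by q_new / q_old.
2. **Chou–Talalay Combination Index.**  Monotherapy dose–response data are
   fitted with the median-effect equation f_a/(1−f_a) = (D/D_m)^m; the CI
   at an observed combination effect is Σ (D_drug)combo / (D_drug)alone,
   with CI < 1 synergy, = 1 additivity, > 1 antagonism.
3. **A 1-D convolutional dose–effect classifier** mapping per-record
   component concentrations to P(effective), thresholded by a dynamically
   adjusted Desired Effect Threshold (DET).  Normalized input-gradient
   contribution weights drive a bounded multiplicative concentration
   adjustment that raises the classified effective fraction by a target
   amount (default 5%).  Learning rate and epoch count can be tuned with
   the **Hippopotamus Optimization** metaheuristic.
4. **A correlation-preserving record generator** (Gaussian copula with
   zero-truncated-normal marginals) that expands the packaged study tables
   to classifier-scale datasets.

## Worked example

```python
from comboratio import data, pk

params = data.load_fitted_params("cynanchum_initial")
m1 = pk.PKFit("M1", *params["M1"])   # Kc=5.186, ka=11.457, ke=0.072
m2 = pk.PKFit("M2", *params["M2"])   # Kc=0.409, ka=11.398, ke=0.198

q0 = pk.quantity_ratio(m1, m2)
print(round(q0, 2))                  # 12.82  (in-vivo M1:M2 quantity ratio)

# after the 5% efficacy gain the refitted profiles give q1 = 15.34;
# the administered-dose ratio scales accordingly:
print(round(pk.dose_ratio_update(2.0, 12.83, 15.39), 2))   # 2.4
```

The initial M1:M2 administered ratio is 12 mg/kg : 6 mg/kg = 2:1; raising
the target efficacy by 5 percentage points moves the in-vivo quantity
ratio from 12.83:1 to 15.39:1, hence an updated administered ratio of
about 2.40:1 — more M1 per unit M2.  The Erigeron case runs the same
chain with Bre:Scu (40 : 24.8 mg/kg = 1.61:1 → 0.992:1).

The `examples/` directory holds one short script per capability
(PK fitting and ratios, CI, the classifier, the optimizer, the record
generator, and the full pipeline); each prints the numbers it computes and
a line on what they mean.  A thin CLI wraps the same library calls:

```bash
comboratio ratio --fit-a Kc=5.186,ka=11.457,ke=0.072 --fit-b Kc=0.409,ka=11.398,ke=0.198
# 12.82
comboratio run-all --config demo.yaml --seed 11
```

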