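"""Train the dose-effect classifier on generated records.

Generates records emulating the augmented combination table with the
response coupled to the concentrations, trains the 1-D CNN, and prints the
held-out metrics, the DET-based classification of one state, and the
normalized per-component contribution weights.
"""

import warnings

import numpy as np

from comboratio import data, net

warnings.filterwarnings("ignore", category=RuntimeWarning)

spec = data.load_fixture("cynanchum_augmented")
records = data.generate_records(
    spec, data.GenConfig(records_per_timepoint=100, seed=1, response_mode="logistic")
)
rng = np.random.default_rng(1)
idx = rng.permutation(len(records))
n_test = int(round(0.15 * len(records)))
test, train = [records[i] for i in idx[:n_test]], [records[i] for i in idx[n_test:]]

config = net.NetConfig(input_components=spec.components, epochs=400, seed=1)
model, history = net.train(net.build_net(config), train, config)
det = net.DETState(value=0.5, step=0.01)

metrics = net.evaluate(model, test, det)
print(f"held-out ({len(test)} records): accuracy={metrics.accuracy:.3f} "
      f"precision={metrics.precision:.3f} recall={metrics.recall:.3f} "
      f"f1={metrics.f1:.3f}")

x, _ = net.design_matrix(test[:1], config)
p = float(model.predict_proba(x)[0])
print(f"one state: P(effective)={p:.3f} -> DET({det.value}) classifies as "
      f"{net.apply_det(p, det)}")

weights = net.contribution_weights(model, records)
print("contribution weights (sum to 1):",
      {k: round(v, 3) for k, v in weights.weights.items()})
print("(the weights rank how strongly each component's concentration "
      "drives the predicted efficacy)")
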