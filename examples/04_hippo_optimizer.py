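"""Bound-constrained minimization with the hippopotamus optimizer.

Minimizes a 5-D sphere and a shifted parabola, then tunes the classifier's
(learning rate, epochs) on an analytic toy score whose optimum is known.
"""

import numpy as np

from comboratio import hippo

config = hippo.HOConfig(lower_bounds=(-5.0,) * 5, upper_bounds=(5.0,) * 5,
                        population=30, iterations=200, seed=42)
result = hippo.optimize(lambda x: float(np.sum(x * x)), config)
print(f"5-D sphere: best fitness {result.best_fitness:.3e} "
      f"after {result.evaluations} evaluations")

config1 = hippo.HOConfig(lower_bounds=(0.0,), upper_bounds=(10.0,),
                         population=30, iterations=100, seed=3)
res1 = hippo.optimize(lambda x: float((x[0] - 3.0) ** 2), config1)
print(f"(x-3)^2 on [0,10]: best position {res1.best_position[0]:.4f} (true optimum 3)")


def toy_score(lr: float, epochs: int) -> float:
    # analytic stand-in for a validation loss, minimized at lr=1e-4, epochs=200
    return (np.log10(lr) + 4.0) ** 2 + ((epochs - 200) / 1000.0) ** 2


lr, epochs, tune_result = hippo.tune_hyperparameters(toy_score, population=10,
                                                     iterations=50, seed=0)
print(f"tuned hyperparameters: learning rate {lr:.2e}, epochs {epochs} "
      f"(optimum 1e-4, 200)")
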