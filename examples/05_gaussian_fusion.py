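"""Gaussian-mixture fusion of component classifiers by EM.

First recovers a known two-component 1-D mixture (a correctness check of the
EM core), then fuses three synthetic classifiers of different quality and
shows that the learned weights favour the reliable one.
"""

import numpy as np

from grainrisk import fit_fusion, fuse_predict

rng = np.random.default_rng(0)

# -- mixture recovery ------------------------------------------------------
m = 5000
comp = rng.integers(0, 2, m)
y = np.where(comp == 0, rng.normal(0, 1, m), rng.normal(3, 1, m))
params = fit_fusion([y[:, None], y[:, None]], np.zeros(m, dtype=int),
                    max_iter=200, standardize=False)
print("true means 0 / 3, weights 0.5 / 0.5")
print(f"recovered means {np.round(np.sort(params.means[:, 0]), 3)}, "
      f"weights {np.round(params.weights, 3)} after {params.n_iter} iterations")

# -- classifier fusion -----------------------------------------------------
P, n = 4, 600
labels = rng.integers(0, P, n)


def classifier(accuracy):
    pred = np.where(rng.random(n) < accuracy, labels, rng.integers(0, P, n))
    scores = np.full((n, P), 0.1 / (P - 1))
    scores[np.arange(n), pred] = 0.9
    return scores


scores = [classifier(0.95), classifier(0.7), classifier(0.4)]
params = fit_fusion(scores, labels, max_iter=100)
fused = fuse_predict(scores, params)
print("\ncomponent accuracies:",
      [round(float((s.argmax(1) == labels).mean()), 3) for s in scores])
print("learned weights:", np.round(params.weights, 3))
print("fused accuracy:", round(float((fused.argmax(1) == labels).mean()), 3))
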