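"""Sweep one hyperparameter and print the accuracy curve.

Varies the stacking fold count K on a small dataset under a fixed seed.
The curve is the tool behind fold-count/batch/epoch selection; on this small
problem differences are modest.
"""

from grainrisk import DSNConfig, GeneratorConfig, ScanConfig, generate, sweep

records, labels = generate(GeneratorConfig(seed=3).scaled(800))
base = DSNConfig(
    max_layers=1,
    scan=ScanConfig(windows=(2, 4), stride=4, n_estimators=5, max_depth=6),
    n_estimators=10,
    gb_max_iter=5,
    lr_max_iter=20,
)
curve = sweep("K", [2, 3, 5], records, labels, base_config=base, seed=3)
print(curve.to_string(index=False))
print("\nheld-out accuracy per fold count; a fixed seed makes the curve "
      "reproducible run to run.")
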