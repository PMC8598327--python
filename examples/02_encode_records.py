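"""Encode mixed-type records into a standardized feature matrix.

Fits the encoding schema (vocabularies + training statistics) on a small
dataset and shows the resulting width: each categorical column expands to a
one-hot block, numeric columns are standardized, and the content field is
split into mass / microbial-count / hazard-quotient features.
"""

import numpy as np

from grainrisk import GeneratorConfig, encode, fit_schema, generate

records, labels = generate(GeneratorConfig(seed=1).scaled(1000))
schema = fit_schema(records)
X = encode(records, schema)

print(f"raw attributes: {records.shape[1]}  ->  encoded width M = {X.shape[1]}")
print(f"categorical columns: {len(schema.categorical_columns)} "
      f"(one-hot width {sum(len(v) for v in schema.vocabularies.values())})")
print(f"numeric columns: {len(schema.numeric_columns)} (incl. derived)")
print("derived columns:", [c for c in schema.numeric_columns if c not in records.columns])

n_cat = sum(len(schema.vocabularies[c]) for c in schema.categorical_columns)
numeric = X[:, n_cat:]
print("max |column mean| of standardized block:", float(np.abs(numeric.mean(0)).max()))
print("max |column std - 1|:", float(np.abs(numeric.std(0) - 1).max()))
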