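"""Generate a synthetic mixed/incomplete dataset and profile it.

Builds an imbalanced binary dataset with 4 numeric and 3 nominal
attributes and 5% missing cells, then prints its profile: the imbalance
ratio (majority/minority count, displayed truncated to 2 decimals — the
convention of published dataset tables) and whether any cell is missing.
"""

import json

from aisac import GeneratorSpec, generate, profile

spec = GeneratorSpec(
    n_instances=300,
    class_proportions=(0.7, 0.3),
    n_numeric=4,
    n_nominal=3,
    class_separation=2.0,
    missing_rate=0.05,
    seed=42,
)
dataset = generate(spec)
prof = profile(dataset)

print(json.dumps(prof.to_json_dict(), indent=2, sort_keys=True))
print()
print(
    f"An imbalance ratio of {prof.imbalance_ratio_display} means the "
    "majority class has about that many instances per minority instance; "
    "ratios above 1.5 are conventionally called imbalanced."
)
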