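"""HEOM dissimilarity on mixed, incomplete instances.

Shows the three per-attribute rules — range-normalised difference for
numerics, 0/1 overlap for nominals, distance 1 when either value is
missing — and the root-sum-of-squares aggregation.
"""

from aisac import (
    AttributeSchema,
    MixedDataset,
    RangeTable,
    attribute_distance,
    heom,
)

schema = (
    AttributeSchema("age", "numeric", 0),
    AttributeSchema("mass", "nominal", 1, ("yes", "no")),
)
train = MixedDataset.from_rows(
    schema,
    [(30.0, "yes"), (70.0, "no"), (50.0, "yes")],
    ["benign", "malignant", "benign"],
)
ranges = RangeTable.from_dataset(train)  # age range observed: [30, 70]

print("numeric, |42-58|/40      :",
      attribute_distance(42.0, 58.0, schema[0], ranges))
print("nominal, yes vs no       :",
      attribute_distance("yes", "no", schema[1], ranges))
print("missing vs anything      :",
      attribute_distance(None, 55.0, schema[0], ranges))

x = (42.0, "yes")
y = (58.0, None)
print(f"heom({x}, {y}) = {heom(x, y, schema, ranges):.4f}")
print("  = sqrt(0.4^2 + 1^2): the missing nominal contributes the "
      "maximal per-attribute distance of 1.")
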