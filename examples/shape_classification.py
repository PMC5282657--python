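"""Three-way leaf-shape classification on a synthetic trait table.

Builds a 3-class Gaussian trait table (classes separated on form factor FF
and area convexity AC only), runs stepwise discriminant analysis with
Wilks' Lambda, and evaluates SDA, a polynomial-kernel SVM and a random
forest by leave-one-out cross-validation.
"""

import numpy as np

from stereoleaf import classify, synth

table = synth.make_feature_dataset(n_per_class=50, separation=4.0,
                                   informative_traits=("FF", "AC"), seed=1)

model = classify.stepwise_select(table)
print("stepwise discriminant analysis")
print(f"  selected traits (entry order): {model.selected_traits}")
print(f"  Wilks' Lambda after each entry: "
      f"{[round(v, 4) for v in model.wilks_path]}")
print()

for method in ("sda", "svm", "rf"):
    report = classify.evaluate(method, table, mode="loo",
                               n_trees=300 if method == "rf" else 1000)
    print(f"{method.upper():>3s} leave-one-out accuracy: "
          f"{report.accuracy:.1f}%")
print()
print("The informative traits (FF, AC) should be selected first with a")
print("monotonically shrinking Lambda; at 4-sigma class separation all")
print("three classifiers land in the mid-to-high 90s.")
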