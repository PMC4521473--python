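"""Ward clustering of per-dose phenotypes into classes with signed signatures.

Uses the direct feature-table simulator: five planted phenotype classes in
six informative features plus noise columns, clustered after choosing the
cluster count from the Davies-Bouldin and Calinski-Harabasz indices.
"""

import pandas as pd

from organoscreen import simulate_feature_table
from organoscreen.clustering import choose_k, fit_cluster_model
from organoscreen.synthetic import default_class_templates

table, truth = simulate_feature_table(default_class_templates(),
                                      n_per_class=20, n_noise_features=0,
                                      seed=4)
k, curves = choose_k(table)
print("index curves (Davies-Bouldin minimised, Calinski-Harabasz maximised):")
print(curves.round(2).to_string())
print(f"chosen cluster count: {k} (true: 5)")

table.index = pd.MultiIndex.from_tuples(
    [(f"ab{i // 5:02d}", float(i % 5 + 1)) for i in range(len(table))],
    names=["treatment", "dose"])
model = fit_cluster_model(table, k=k)
print(f"cross-half stability of the clustering: {model.stability:.2f}")
for letter, (f, pct) in model.signatures.items():
    if pct is not None:
        desc = ", ".join(f"{name}={v:+.0f}%" for name, v in pct.items())
        print(f"  class {letter}: {desc}  (sum {pct.sum():.0f}%)")
# Partition sizes %(i) = F_i / sum_j F_j are signed; values outside
# [0, 100%] are legitimate when features pull in opposite directions.
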