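"""Comparing tree-statistic distributions between population types.

Simulates a desk-scale baseline dataset (standard rates, shrunk tip counts),
then runs the Kolmogorov-Smirnov, Cucconi and Podgor-Gastwirth tests on every
statistic.  Large D / C / S with tiny p-values mean the statistic separates
structured from non-structured populations.
"""

import numpy as np

from phylostruct import (baseline_design, compare_populations,
                         simulate_dataset, statistics_table)

design = baseline_design(seed=3, n_unstructured=60, n_structured=60)
# shrink tip targets so the example runs in a couple of seconds
design["n_tips_1"] = np.where(design.label == "non-structured", 70, 50)
design.loc[design.label == "structured", "n_tips_2"] = 30

dataset = simulate_dataset(design)
table = statistics_table(dataset.trees)
report = compare_populations(table, mode="asymptotic")

cols = ["statistic", "ks_D", "ks_p", "cucconi_C", "cucconi_p", "pg_S", "pg_p"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# The depth-type statistics (Sackin, cophenetic, ladder) separate the two
# populations sharply because migration unifurcations deepen structured
# trees; the normalised balance statistics overlap more, giving intermediate
# D values.
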