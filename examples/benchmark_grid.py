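"""Run a small simulate -> learn -> score benchmark grid.

Compares the two-phase learner against the hill-climbing baseline over
replicated settings and reports medians plus paired t-tests per metric.
"""

from bicnet import SearchConfig, SimulationConfig, run_benchmark

grid = [
    SimulationConfig(p=8, n=100, mean_parents=1.2, seed=0),
    SimulationConfig(p=8, n=400, mean_parents=1.2, seed=0),
]
result = run_benchmark(grid, search=SearchConfig(max_parents=3),
                       replicates=5, base_seed=42)

cols = ["config", "learner", "tpr_median", "precision_median", "fpr_median"]
print(result.aggregates[cols].to_string(index=False))
print()
tt = result.ttests
print(tt[["config", "metric", "t", "p", "p_holm"]].to_string(index=False))
# Rows pair two_phase vs hill_climb per replicate; positive t favours the
# learner listed first (alphabetically: hill_climb), negative the second.
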