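"""Simulate a ground-truth network and a dataset from its linear SEM.

Each continuous child is drawn as X_i ~ Normal(sum_j beta_ji X_j, sigma_i^2)
with beta magnitudes ~ N(2, 0.8), random signs, and sigma^2 ~ N(1, 0.01);
column order is shuffled so learners cannot read the generative order.
"""

from bicnet import SimulationConfig, simulate

config = SimulationConfig(
    network_kind="continuous", topology="random", p=10, n=200,
    mean_parents=1.5, seed=7,
)
instance = simulate(config)

dag = instance.truth.dag
print(f"true network: {dag.p} nodes, {len(dag.edges)} directed edges")
print("example edges with structural coefficients:")
for (u, v) in sorted(dag.edges)[:5]:
    beta = instance.truth.cpds[v].betas[u]
    print(f"  {u} -> {v}   beta = {beta:+.3f}")
print(f"dataset: {instance.data.n} rows x {instance.data.p} columns "
      f"(columns shuffled by permutation {instance.column_permutation})")
# The betas are the causal effect sizes the learner must recover; the shuffle
# only reorders columns and is invertible via instance.unshuffled().
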