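"""Score a learned structure against the truth, directed and skeleton-wise.

A learned edge is a true positive only if both endpoints AND direction
match; a reversed true edge counts as a false positive. The skeleton panel
ignores direction.
"""

from bicnet import (
    SearchConfig, SimulationConfig, compare_skeletons, compare_structures,
    learn, simulate,
)

instance = simulate(SimulationConfig(p=12, n=800, mean_parents=1.5, seed=11))
result = learn(instance.data, SearchConfig())

strict = compare_structures(instance.truth.dag, result.dag)
skeleton = compare_skeletons(instance.truth.dag, result.dag)
print(f"directed:  TP={strict.tp} FP={strict.fp} FN={strict.fn}  "
      f"TPR={strict.tpr:.3f} precision={strict.precision:.3f} FPR={strict.fpr:.4f}")
print(f"skeleton:  TP={skeleton.tp} FP={skeleton.fp} FN={skeleton.fn}  "
      f"TPR={skeleton.tpr:.3f} precision={skeleton.precision:.3f}")
# A gap between the panels means some adjacencies were found but oriented
# the wrong way -- expected for edges that are not compelled by the data.
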