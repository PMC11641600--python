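"""Determine (alpha, C) by grid search and inspect the trade-offs.

alpha rewards the gap between each class's inner and outer ellipsoid
radius; C penalizes slack (classification errors). Too-small alpha or
too-large C collapses the LP to the trivial all-zero solution. The default
rule keeps non-trivial cells and prefers the largest C, then the smallest
alpha.
"""

from edgemarker.pipeline import grid_select
from edgemarker.simulate import SimulationDesign, simulate_dataset

expr, network, _ = simulate_dataset(SimulationDesign(seed=0))
result, cells = grid_select(expr, network)

print("alpha   C      trivial  n_biomarkers  total_slack")
for c in cells:
    print(f"{c.alpha:<7g} {c.penalty_C:<6g} {str(c.trivial):<8s} "
          f"{c.n_biomarkers:<13d} {c.total_slack:.3f}")
print(f"\nchosen pair: alpha={result.params.alpha}, "
      f"C={result.params.penalty_C}")
print(f"selected {result.biomarkers.n_selected} biomarkers at that pair")
print("(biomarker count grows with alpha; slack shrinks as C grows)")
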