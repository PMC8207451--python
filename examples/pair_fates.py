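"""Joint fate distributions for a mated pair and their correlation bounds.

For two Bernoulli fates with given marginals, the admissible linear
correlation is limited by the Frechet-Hoeffding bounds, written here via
the odds product and odds ratio of the marginals.
"""

from pairbond_cjs import (
    correlation_bounds,
    joint_fate_distribution,
    survival_transition_matrix,
)

phi = (0.7, 0.7)  # female and male survival probabilities
bounds = correlation_bounds(phi)
print(f"survival marginals {phi}: admissible gamma in "
      f"[{bounds.lower:.4f}, {bounds.upper:.4f}]")
# [-0.4286, 1.0000]: the grid of a study at phi=0.7 can span -0.4..1.0

for gamma in (0.0, 0.5, 1.0):
    d = joint_fate_distribution(phi, gamma, together=True)
    print(f"gamma={gamma:4.1f}  both={d.both:.3f}  female_only={d.female_only:.3f}  "
          f"male_only={d.male_only:.3f}  neither={d.neither:.3f}")
# gamma=0 is the independence product; gamma=1 forces identical fates.

print("\nSurvival transition matrix at gamma=0.5 (rows: pair state):")
print(survival_transition_matrix(phi, 0.5))
# Rows 2-4: a lone survivor follows an independent Bernoulli; death absorbs.
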