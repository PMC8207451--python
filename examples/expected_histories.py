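"""Analytic encounter-history cell probabilities for the reference design.

Under a constant-parameter CJS model (phi=0.7, p=0.8, T=4, single cohort)
the 8 observable histories have closed-form probabilities; scaling by the
cohort size gives the expected multinomial cell counts.
"""

from pairbond_cjs import reproduce_expected_histories

frame = reproduce_expected_histories(phi=0.7, p=0.8, n_occasions=4)
print(frame.round(3).to_string(index=False))
print(f"\nprobabilities sum to {frame['probability'].sum():.3f}")
# Every expected cell count exceeds 0.5 even at n=100, so sparsity alone
# cannot explain deviance-statistic deflation in the correlated study.
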