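"""Calibration of the sex-effect likelihood-ratio test under correlation.

Under independent fates the LRT of (phiG,p) against (phi,p) rejects at
its nominal 5% level and its p-values are uniform.  As within-pair
survival correlation rises, the deviance statistic deflates and the test
becomes overly conservative.  (K=200 replicates here for speed; the full
study uses 1000.)
"""

from pairbond_cjs import SimulationConfig, StudyGrid, run_lrt_study

grid = StudyGrid(
    gamma_values=(0.0, 0.6, 1.0),
    rho_values=(0.0,),
    base_config=SimulationConfig(n_replicates=200, seed=7),
)
summary = run_lrt_study(grid).summary
cols = ["test", "gamma", "rejection_rate", "mean_deviance"]
print(summary[cols].to_string(index=False))
# survival_sex_effect: rejection falls well below 0.05 and the mean
# deviance drops below the chi-square(1) mean of 1 as gamma -> 1;
# recapture_sex_effect: stays near nominal at every gamma.
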