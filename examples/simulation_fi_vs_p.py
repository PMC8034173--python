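"""How the fragility index relates to the p-value, by simulation.

Simulates 500 two-arm 1:1 trials (100 patients/arm, event rates 0.5 vs
0.3), keeps the ones significant at alpha = 0.05 and computes the Spearman
rank correlation between each trial's FI and its baseline Fisher p.  The
correlation is strongly negative: trials that are barely significant are
also the ones a handful of outcome flips would overturn, so the FI mostly
re-expresses the p-value on a patient-count scale.
"""

from trialfragility import SimulationConfig, fi_p_correlation_experiment

config = SimulationConfig(
    n_per_arm=100,
    event_rate_experimental=0.5,
    event_rate_control=0.3,
    n_trials=500,
    seed=1,
)
rho, n_significant = fi_p_correlation_experiment(config)

print(f"simulated trials          : {config.n_trials}")
print(f"significant at alpha=0.05 : {n_significant}")
print(f"Spearman rho(FI, p)       : {rho:.3f}")
print("-> higher baseline p goes with lower FI (more fragile result)")
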