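"""Simulation study of estimator bias (reduced scale for a quick demo).

For each true variance fraction, phenotypes are simulated conditional on a
causal locus and the variance explained is re-estimated by the fixed-effects
delta-R^2 and by REML with different similarity estimators. Bias is
mean(estimate) - truth, tested by a one-sample Wilcoxon signed-rank test.
At full scale (n=2600, 100 replicates) the centered-and-scaled estimator
shows significant downward shrinkage of large effects while the centered
estimator does not.
"""

from admixvar import BiasGridConfig, aric_like_config, run_bias_grid, simulate_panel

panel = simulate_panel(aric_like_config(n_individuals=400, seed=7))
cfg = BiasGridConfig(
    true_variances=(0.0, 0.05, 0.193),
    n_replicates=30,
    estimators=("fixed_effects", "centered_scaled", "centered"),
    partitions=("genome",),
    seed=8,
)
result = run_bias_grid(cfg, panel, causal_locus=panel.n_loci // 2)
table = result.table()
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nbias = mean(estimate) - truth per cell; small Wilcoxon p flags a"
      " systematic bias. The zero-truth rows show the boundary inflation"
      " (estimates cannot go below 0).")
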