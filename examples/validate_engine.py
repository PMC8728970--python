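"""Check the analytic engine against Monte-Carlo simulation.

Datasets are drawn from the exact beta-binomial generative model (a 3%
vs 5% rare cell type, 1000 cells per sample), a one-sided Welch t-test is
run on each, and the empirical false-negative rate is compared with both
the finite-cell analytic prediction and the legacy infinite-cell one.
"""

from cytopower import GroupSpec, TestSpec, grid_validation

g0 = GroupSpec(m=2, n=1000, mu=0.03, sigma=0.015)
g1 = GroupSpec(m=2, n=1000, mu=0.05, sigma=0.01)
pairs = [(m, m) for m in (5, 8, 11)]
err_model, err_legacy, table = grid_validation(
    pairs, g0, g1, TestSpec(), replicates=5000, seed=1
)

print(table[["m0", "m1", "empirical_fnr", "sensei_fnr", "legacy_fnr"]]
      .round(4).to_string(index=False))
print(f"\nMean |analytic - empirical| / empirical: "
      f"finite-cell {err_model:.1%}, infinite-cell {err_legacy:.1%}")
print("The infinite-cell prediction is systematically below the empirical "
      "rate: ignoring sampling noise overstates power for rare cell types.")
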