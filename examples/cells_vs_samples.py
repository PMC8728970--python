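"""Trade sequencing depth against cohort size for a rare cell type.

For a 1% -> 2% abundance change, finite cell counts inflate the observed
variance well beyond the biological SD, so shallow profiling demands many
more subjects.  The legacy (infinite-cell) calculation is the floor.
"""

from cytopower import GroupSpec, TestSpec, cells_tradeoff

g0 = GroupSpec(m=2, n=1000, mu=0.01, sigma=0.005)
g1 = GroupSpec(m=2, n=1000, mu=0.02, sigma=0.005)
res = cells_tradeoff(g0, g1, TestSpec(), power_target=0.9,
                     n_values=[100, 384, 1000, None])

print("cells/sample   min samples per group (90% power)")
for n, m in res.items():
    label = "infinite" if n is None else str(n)
    print(f"{label:>12}   {m}")
print("\nProfiling only 100 cells per sample costs extra subjects; the "
      "infinite-cell row is what a classical power calculation would claim.")
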