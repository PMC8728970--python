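"""Power gain from pairing samples across conditions.

When the same subjects are profiled before and after treatment, the
between-condition correlation rho of their true cell-type proportions
cancels part of the biological variance.  Here a 10% -> 14% shift with
SD 3 points and 10 subject pairs: the paired test's false-negative rate
falls steeply as rho grows.
"""

from cytopower import GroupSpec, TestSpec, fnr_paired

g_before = GroupSpec(m=10, n=1000, mu=0.10, sigma=0.03)
g_after = GroupSpec(m=10, n=1000, mu=0.14, sigma=0.03)

print("rho    beta    power")
for rho in (0.0, 0.3, 0.6, 0.9):
    res = fnr_paired(g_before, g_after, TestSpec(design="paired", rho=rho))
    print(f"{rho:.1f}  {res.beta:6.3f}  {res.power:6.3f}")

print("\nAt rho=0 the paired test matches the unpaired noncentrality but "
      "pays M-1 degrees of freedom; positive correlation repays it quickly.")
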