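"""Sequencing cost model and investment levels.

The cost of sequencing one individual combines a 40 MU library preparation
with 80 MU per x of coverage up to 5x, then flattens to fixed anchors of
500 MU at 15x and 850 MU at 30x.  Investment levels are expressed as the
cost-equivalent of sequencing a fraction of the population at 2x; levels
below 10,000 MU are considered too small to be worth optimizing and are
skipped.
"""

from peelsim import investment_levels, n_affordable, sequencing_cost

print("coverage (x) -> combined cost (MU)")
for x in (0.25, 0.5, 1, 2, 5, 15, 30):
    print(f"  {x:>5} -> {sequencing_cost(float(x)):7.0f}")

print("\ninvestment levels for a population of 30,000 individuals:")
for frac, budget in investment_levels(30_000).items():
    print(f"  {frac:.1%} at 2x -> {budget:10,.0f} MU "
          f"({n_affordable(budget, 2.0):5d} individuals at 2x)")

print("\ninvestment levels for a population of 1,000 (small levels dropped):")
print(" ", investment_levels(1_000))

# The printed costs are the anchors of the piecewise-linear model; the
# investment lines show how many individuals each budget buys at the
# recommended uniform 2x coverage.
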