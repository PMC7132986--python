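"""Whom to sequence: the selection strategies side by side.

Runs every budget-allocation method on the same small population and the
same budget, and prints the resulting plans: how many individuals each
method sequences, at which coverages, and what it spends.  Pedigree-based
methods concentrate high coverage on few ancestors; the combined and
random methods spread low coverage over many individuals.
"""

from peelsim import (assign_panels_and_genotyping, generate_base_haplotypes,
                     simulate_discrete_population)
from peelsim.strategies import (alphaseqopt_like, combined, key_ancestors,
                                ped_gen_rel, random_plans, top_sires_and_dams)

pool = generate_base_haplotypes(
    n_hap=100, n_chromosomes=2, seq_per_chr=400, hd_per_chr=40,
    ld_per_chr=4, chrom_length_bp=2e6, mu=1e-7, rec=5e-7, seed=1)
pop = simulate_discrete_population(pool, n_generations=4,
                                   generation_size=120, n_qtn=200, seed=2)
ped, panel = pop.pedigree, pop.haplotypes
genotyped = assign_panels_and_genotyping(ped, seed=3).genotyped()

BUDGET = 10_000.0
plans = [
    top_sires_and_dams(ped, genotyped, BUDGET),
    key_ancestors(ped, BUDGET),
    ped_gen_rel(ped, BUDGET),
    alphaseqopt_like(ped, panel, BUDGET, window_size=10),
    combined(ped, panel, genotyped, BUDGET, window_size=10),
    random_plans(ped, BUDGET, mode="uniform", seed=4),
]
plans.append(random_plans(ped, BUDGET, mode="variable",
                          reference_histogram=plans[4].histogram(), seed=5))

print(f"budget {BUDGET:,.0f} MU, population {ped.n}")
print(f"{'method':<18} {'n':>4} {'cost':>8}  coverage histogram")
for plan in plans:
    hist = ", ".join(f"{int(c)}@{x:g}x" for x, c in sorted(plan.histogram().items()))
    print(f"{plan.method:<18} {plan.n_sequenced:>4} {plan.cost():>8,.0f}  {hist}")
# KeyAncestors/PedGenRel buy few individuals at 15x; TopSiresAndDams and
# the random controls buy many at 1-2x for the same money.
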