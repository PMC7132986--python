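"""Simulate a pedigreed population with genomes and marker data.

Generates coalescent founder haplotypes (a deliberately small pool so the
example runs in seconds), drops them through a discrete-generation
pedigree under truncation selection, and assigns marker-array genotyping
the way breeding programs do: most individuals on a low-density array,
the heaviest-used parents on the high-density array.
"""

import numpy as np

from peelsim import (assign_panels_and_genotyping, generate_base_haplotypes,
                     simulate_discrete_population)

pool = generate_base_haplotypes(
    n_hap=100, n_chromosomes=2, seq_per_chr=500, hd_per_chr=50,
    ld_per_chr=5, chrom_length_bp=2e6, mu=1e-7, rec=5e-7, seed=1)
print(f"founder pool: {pool.n_hap} haplotypes x {pool.map.n_loci} SEQ loci "
      f"({pool.is_hd.sum()} HD, {pool.is_ld.sum()} LD)")

pop = simulate_discrete_population(pool, n_generations=5,
                                   generation_size=100, n_qtn=200, seed=2)
ped = pop.pedigree
print(f"pedigree: {ped.n} individuals, generations 0-{ped.generation.max()} "
      f"(generation 0 = base parents)")
for g in range(int(ped.generation.max()) + 1):
    sel = ped.generation == g
    print(f"  generation {g}: n={sel.sum():4d} mean TBV={pop.tbv[sel].mean():7.1f}")
# mean true breeding value rises generation on generation: the footprint
# of truncation selection (5% of sires, 25% of dams)

asg = assign_panels_and_genotyping(ped, seed=3)
print("\ngenotyping assignment:", asg.counts())
base = ped.generation == 0
print(f"  base generation genotyped: "
      f"{np.sum(asg.status[base] > 0)}/{base.sum()} (target 75%)")
later = ped.generation > 0
print(f"  later generations genotyped: "
      f"{np.sum(asg.status[later] > 0)}/{later.sum()} (target 95%)")
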