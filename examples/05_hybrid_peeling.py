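"""Hybrid peeling end to end on a toy population.

Sequences 10% of a small population at 2x, builds genotype likelihoods
from the simulated reads and marker-array calls, estimates segregation
probabilities by multi-locus peeling on the array loci, imputes a subset
of sequence loci by segregation-aware single-locus peeling, and scores
the MAF-corrected dosage correlation for sequenced and unsequenced
individuals.
"""

import numpy as np

from peelsim import ScenarioConfig, run_scenario
from peelsim.simulate import generate_base_haplotypes

pool = generate_base_haplotypes(
    n_hap=120, n_chromosomes=2, seq_per_chr=600, hd_per_chr=60,
    ld_per_chr=6, chrom_length_bp=3e6, mu=1e-7, rec=3.3e-7, seed=1)

cfg = ScenarioConfig(n_generations=5, generation_size=120,
                     method="RandomUnif", budget=12_000.0,
                     n_eval_loci=120, exclusion="none",
                     enforce_min_investment=False, seed=7)
res = run_scenario(cfg, pool=pool)

rep, plan, ped = res.report, res.plan, None
print(f"sequenced {plan.n_sequenced} individuals at 2x "
      f"({plan.cost():,.0f} of {res.investment:,.0f} MU)")
print(f"population mean accuracy: corrected {res.mean_corrected:.3f}, "
      f"raw {res.mean_raw:.3f}")

seq = plan.coverage > 0
corr = rep.corrected
print(f"  sequenced individuals:   {np.nanmean(corr[seq]):.3f}")
print(f"  unsequenced individuals: {np.nanmean(corr[~seq]):.3f}")
# Sequenced individuals are imputed almost perfectly; their unsequenced
# relatives follow closely because peeling pools the low-coverage reads
# across the pedigree through the segregation probabilities.
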