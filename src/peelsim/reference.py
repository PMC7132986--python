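"""Reference variable-coverage plans for three deep commercial pig
pedigrees of roughly 15,000, 30,000 and 65,000 individuals.

These coverage histograms are the published outputs of the combined
(pedigree + haplotype) selection strategy at the highest investment level
(5% of the population at 2x); they serve as worked inputs for the plan
arithmetic: realized investment, total coverage, and the three
uniform-coverage transforms are all derived from them at run time.
"""

from __future__ import annotations

#: population label -> (population size, {coverage: number of individuals})
REFERENCE_VARIABLE_PLANS: dict[str, tuple[int, dict[float, int]]] = {
    "real_15k": (15_187, {1.0: 632, 2.0: 182, 5.0: 3, 15.0: 50, 30.0: 10}),
    "real_30k": (29_974, {1.0: 1245, 2.0: 281, 5.0: 9, 15.0: 76, 30.0: 31}),
    "real_65k": (64_598, {1.0: 2711, 2.0: 773, 5.0: 37, 15.0: 156, 30.0: 65}),
}
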