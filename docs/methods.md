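# Methods

This note documents the models implemented in `peelsim`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not capture.

## 1. Pedigrees and genomes

### Founder haplotypes

Founder haplotypes are sampled from a neutral coalescent (the msprime
backend) with per-bp mutation rate µ = 2.5×10⁻⁸ and recombination rate
r = 10⁻⁸ on 10⁸ bp chromosomes of 100 cM — i.e. 1 cM/Mb.  The effective
population size follows a piecewise-constant history

    Ne = 100 (present) → 1,000 (100 gens ago) → 4,000 (500) → 10,000 (≥1,000),

a stand-in for a typical livestock demography: small recent Ne produces
the long-range LD and low haplotype diversity of a breeding line, while
the large ancestral Ne supplies segregating variation.  No published
trajectory was available for this choice, so it is exposed as the
`ne_trajectory` argument; absolute imputation accuracies shift with it,
the comparisons between strategies do not (they share the founders).

Segregating biallelic sites are thinned evenly to the target number of
whole-genome-sequence (SEQ) loci.  Marker arrays are nested subsets of
SEQ: the high-density (HD) panel takes loci evenly spaced in cM among
sites with founder MAF ≥ 0.05 (the standard array-design convention —
common, evenly spread markers), and the low-density (LD) panel is every
10th HD locus.  Full scale is 20 chromosomes × 150,000 SEQ / 3,000 HD /
300 LD.

### Desk scale

All experiment grids default to a scaled-down genome chosen once and used
everywhere (`DeskScale`): 3 chromosomes of 10⁷ bp, still 100 cM each
(r = 10⁻⁷), with 2,000 SEQ / 200 HD / 20 LD loci per chromosome, a
400-haplotype founder pool, 500 trait loci, and populations up to a few
thousand individuals.  Genetic length, panel nesting, selection and
genotyping regimes are preserved; only counts shrink.  Accuracy is
evaluated on a random subset of SEQ loci (default 300), mirroring the
practice of estimating accuracy from a few thousand non-consecutive SNPs
on a few chromosomes.

### Pedigree simulation

*Discrete generations.*  Ten unselected burn-in generations precede the
retained pedigree; the truncation-selected parents of generation 1 form
the retained "base generation" (generation 0, parents unknown).  In each
subsequent generation the top 5% of males and 25% of females by true
breeding value are selected, each selected parent contributes the same
number of progeny, and dams are nested within sires in equal shares.  The
polygenic trait is additive with normal QTN effects (h² = 0.3 nominal;
selection acts on the true breeding value, so the heritability never
enters the simulation directly).  Population size for investment
purposes is the number of individuals in generations 1..G (depth ×
generation size); base parents are part of the pedigree but not of the
size used to set budgets.

*Overlapping generations.*  A continuous birth order stands in for deep
commercial pedigrees.  For each birth a parental cohort is placed at an
offset drawn uniformly in [W/4, W] positions back (W = 12% of the
population), and the parent is truncation-selected within that cohort
(top 5% males / 25% females by TBV).  Drawing the cohort offset uniformly
— rather than truncation-selecting over the whole window — keeps the
parent-offspring age gap uniform; bounding it below by W/4 bounds the
longest ancestral path.  With these defaults the realized
generation-equivalent depth (mean longest ancestral path of the last-born
5%) is ≈ 20, matching the ~20 overlapping generations the design
emulates; this was fixed by a one-time calibration run over window
fractions and is tested at [15, 25].

*Meiosis.*  Crossovers per chromosome are Poisson with mean 1 per Morgan,
positions uniform in cM, no interference, random start phase; the map is
sex-averaged.

### Genotyping assignment

Base generation: 75% genotyped, of whom 67% HD / 33% LD.  All later
generations: 95% genotyped, 15% HD / 85% LD (counts are rounded targets,
applied per generation).  Genotyped status is random; the HD array goes
to the genotyped individuals with the most genotyped progeny +
grandprogeny (ties by pedigree position), except in the final generation,
where HD is random — progeny counts cannot yet identify the important
parents there.  In overlapping pedigrees the founders play the role of
the base generation and the last 10% of positions that of the final
generation; the later-generation rates apply to all non-founders.

## 2. Costs and budgets

Sequencing one individual at coverage x costs 0 at x = 0 and 40 + 80·x MU
for 0 < x ≤ 5 (40 MU library preparation, 80 MU per x), with fixed
combined anchors 500 MU at 15x and 850 MU at 30x and linear interpolation
between anchors.  Investment levels are fraction × population size ×
200 MU for fractions 0.5/1/2/5%; levels under 10,000 MU are skipped.
Budgets are hard caps: leftover MU smaller than the cheapest unit stays
unspent, so realized plan costs sit at or just under the level.

## 3. Selection strategies

* **TopSiresAndDams** — rank sires and dams by genotyped progeny +
  grandprogeny (summed); half the budget buys top sires at 2x, half top
  dams at 1x.
* **KeyAncestors** — greedy marginal-contribution selection at 15x.  A
  candidate's score is its expected genetic contribution to all
  individuals not yet covered: contributions propagate down the pedigree
  halving per meiosis, and any path through an already-selected
  individual is blocked (its genome is known).  This reproduces the
  classic key-ancestor logic from the pedigree alone.
* **PedGenRel** — stepwise maximization of the relationship between the
  sequenced set s and the rest, at 15x.  The first pick maximizes the
  average relationship a; each later candidate c maximizes
  1ᵀ A_{s∪c}⁻¹ a_{s∪c}.  Scoring the candidate *inside* the set is the
  only reading of the criterion under which candidates are
  distinguishable, and it is what the stepwise description implies.
* **AlphaSeqOptLike** — an explicit simplified stand-in for the two-part
  haplotype-coverage optimiser (the original's internals are out of
  scope).  Stage 1 (half budget): the haplotype library is the set of
  distinct alleles of non-overlapping 50-HD-marker windows; focal
  individuals are chosen greedily to maximize newly covered
  population-frequency-weighted haplotypes; each focal family (focal +
  parents + grandparents, nominal 1,400 MU ≡ seven members at 2x)
  receives coverages from {1, 2, 5, 15, 30} assigned greedily by
  Δproxy/Δcost, proxy = Σ ω_m(1 − 2^(−x_m)) with weights 2/1/0.5 for
  focal/parent/grandparent (the 2^(−x) term is the chance a site is
  entirely missed at coverage x, so the proxy saturates like phasing
  information does).  Stage 2 (other half): window haplotypes whose
  carriers' summed coverage (per copy) is below 10x define under-covered
  carriers; unsequenced carriers get 1x, most under-covered first, by a
  single static ranking.
* **Combined** — quarter budgets for top sires (2x), top dams (1x),
  stage 1, stage 2, merged in that order.  On overlap the maximum
  coverage wins and only the increment is charged, so the cheaper pick's
  cost remains available to its own sub-plan.
* **RandomVar / RandomUnif** — random individuals, with the Combined
  method's coverage histogram or uniformly at 2x.
* **Concentrated / UniformSweep / uniformize** — the transforms behind
  the generation-concentration, coverage-sweep and variable-vs-uniform
  comparisons.  `uniformize(equal_total_coverage)` accounts its cost as
  n×40 + total×80 (the linear per-x price applied to the average
  coverage); `equal_investment` solves X = (investment/n − 40)/80 from
  the variable plan's *realized* cost; `fixed_2x` keeps the first
  ⌊investment/200⌋ individuals in original selection order.

Ties are always broken by ascending pedigree position, making every plan
deterministic given its seed.  All individuals are candidates for the
pedigree-based methods whether or not they have array data (the selection
criteria are pedigree functionals).

## 4. Read model

Per scenario one sequenceability vector s_j ~ Gamma(4, 4) (mean 1,
variance 0.25) is drawn and shared by all individuals; read counts are
n_ij ~ Poisson(x_i s_j), split Binomial(n, ½) between the two true
chromosomes, each read reporting its chromosome's true allele.  At x = 2
the total-read mean is 2 and the variance 2 + 4·0.25 = 3 (law of total
variance) — both are tested.  Sequencing error enters only downstream, as
the per-read error ε in the genotype likelihood; the read simulator
itself is error-free.

## 5. Peeling engine

Genotypes are 4-vectors over ordered (paternal, maternal) allele pairs.
Observations become penetrances: reads give P(n_alt, n_ref | G) with
per-read alt probability ε, 0.5, 0.5, 1−ε (ε default 0.001); array calls
give 1−δ on consistent states (split across the two het orderings) and δ
spread over inconsistent ones (δ default 0.01).  Defaults are
conventional error magnitudes for the two assay types and are exposed as
arguments.

Single-locus peeling is belief propagation on the family factor graph:
one factor per (sire, dam) mating covering all its children jointly, so
full-sib families introduce no loops.  The anterior of an individual is
the message from its parents' family; each family an individual parents
returns a posterior message.  Updates run as a down pass (anteriors, in
family order) and an up pass (posterior messages, reverse order) per
iteration; on loop-free pedigrees the fixed point is the exact posterior,
which the tests verify against exhaustive enumeration over all 4ⁿ phased
configurations (n ≤ 8, random penetrances, agreement < 10⁻⁶).  Pedigree
loops (inbreeding) are handled by simply iterating the same updates, as
is standard for iterative peeling; exactness is claimed only on trees.
Individuals with one known parent get an implicit unrelated
Hardy-Weinberg founder on the missing side.

Segregation probabilities are 4-vectors over which grandparental
haplotype the paternal and maternal alleles came from.  The
segregation-conditioned transmission kernel replaces the ½-per-allele
Mendelian kernel; multi-locus peeling alternates (i) segregation-aware
genotype peeling at every array locus with (ii) a per-individual
forward–backward pass along the chromosome, transitions factorizing per
parent with Haldane switch probability r = ½(1 − e^(−2d/100)) for d cM.
The 3-member 2-locus case is verified against a hand-built 4-state HMM.
Hybrid peeling linearly interpolates the segregation probabilities in cM
to every evaluation locus (constant beyond the mapped ends) and runs
segregation-aware single-locus peeling there.  LD-genotyped individuals
enter multi-locus peeling with penetrance only at their LD loci — no
prior imputation to HD.

Numerics: linear-space probabilities with a 10⁻³⁰ floor and per-step
renormalization (4-state vectors cannot underflow catastrophically once
floored); allele frequencies are re-estimated each iteration from mean
dosages, clamped to [10⁻⁴, 1−10⁻⁴], and refresh the founder priors.
Convergence is declared when the largest genotype-probability change
drops below `tol` (default 10⁻⁶); heterozygote phase orderings can
oscillate without affecting dosages, so scenario runs simply cap the
iterations.  Engine defaults are 20 iterations in double precision; the
scenario runner uses 8 multi-locus and 6 hybrid iterations in single
precision with tol 10⁻⁴ — accuracy at the test scales changes by < 0.001
relative to the defaults while the runtime halves.

## 6. Accuracy

Per individual, the dosage correlation across evaluated loci, raw and
MAF-corrected (both vectors centered by 2p_j before the Pearson
correlation; the centering is per locus, which is what distinguishes the
two).  p_j comes from the true genotypes of the whole population — in a
simulation there is no reason to inject estimator noise into the metric.
Loci with p outside (0.001, 0.999) are dropped; individuals with zero
variance in either vector are undefined and excluded from means, as are
the early-generation individuals under the standard exclusions (discrete:
evaluate generation ≥ 4, base = generation 0; overlapping: drop the first
20% of positions).  Population means include sequenced individuals.

## 7. Experiment grids and problem sizes

`run_scenario` is deterministic given its root seed (named child streams
for founders, pedigree, genotyping, plan, sequenceability, reads and
evaluation loci).  The grids reproduce the study designs at desk scale:
pedigree structure × investment, seven methods × investment, generation
concentration, variable vs uniform coverage, and the coverage sweep; two
replicates by default, reported per replicate and averaged.

The trend runs used by the acceptance tests are paired (arms within a
seed share the founder pool and, where the design allows, the
population): depth 2/5/10 × 200 per generation at the 5% level;
generation 1 vs generation 5 concentration in a 10 × 200 pedigree at 5%;
and coverage 0.25/2/5x in a 10 × 250 pedigree at the 2% level (the lowest
admissible level for a 2,500-individual population), three seeds each.
These sizes were chosen so the full trend battery runs in minutes on one
CPU while each comparison's effect (0.05–0.4 in corrected accuracy)
stays an order of magnitude above the seed-to-seed spread.

## 8. What the simulations do and do not show

The generator reproduces the *structure* that drives the method
comparisons — pedigree depth, relatedness, nested marker panels, budget
arithmetic, coverage variability — and the desk-scale trends match the
full-scale findings qualitatively (and, for deep pedigrees, numerically
closely).  It does not reproduce: real linkage-disequilibrium detail
(the true Ne history is unknown), genotyping error on arrays beyond the
δ model, alignment/mapping artefacts in reads (no mapping bias,
duplicates, indels or base qualities), sex-specific recombination, sex
chromosomes, non-additive traits, selection on estimated rather than
true breeding values, or the exact behaviour of the original production
implementations of the haplotype optimiser and peeling software.
Absolute accuracies should therefore be read as desk-scale analogues,
not predictions for any particular population.
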