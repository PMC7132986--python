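"""Shared independent oracles and random-structure generators for the tests.

Everything here is deliberately written without reusing the package's own
message-passing or matrix code paths, so that agreement between the two is
a real cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from peelsim.pedigree import UNKNOWN, make_pedigree
from peelsim.peeling import KERNEL, hw_prior


def exhaustive_posteriors(ped, pen, p):
    """Exact single-locus genotype posteriors by enumerating all 4^n
    ordered-genotype configurations (founders under a Hardy-Weinberg prior,
    one-unknown-parent individuals marginalized over a phantom founder)."""
    n = ped.n
    prior = hw_prior(np.array([p]))[0]
    post = np.zeros((n, 4))
    total = 0.0
    for cfg in itertools.product(range(4), repeat=n):
        w = 1.0
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                w *= prior[cfg[i]]
            elif s != UNKNOWN and d != UNKNOWN:
                w *= KERNEL[cfg[s], cfg[d], cfg[i]]
            elif s != UNKNOWN:
                w *= sum(prior[gd] * KERNEL[cfg[s], gd, cfg[i]]
                         for gd in range(4))
            else:
                w *= sum(prior[gs] * KERNEL[gs, cfg[d], cfg[i]]
                         for gs in range(4))
            w *= pen[i, 0, cfg[i]]
            if w == 0.0:
                break
        if w > 0.0:
            total += w
            for i in range(n):
                post[i, cfg[i]] += w
    return post / total


def random_tree_pedigree(rng, n):
    """Random loop-free pedigree of n individuals.

    New matings are only formed between individuals with disjoint
    ancestries (union-find components), so the family factor graph is a
    tree; full-sib families (repeat children of an existing mating) are
    allowed because a family is a single factor.
    """
    sire, dam, sex = [], [], []
    comp: list[int] = []

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    fams: list[tuple[int, int]] = []
    for i in range(n):
        males = [j for j in range(i) if sex[j] == 0]
        females = [j for j in range(i) if sex[j] == 1]
        new_pairs = [(s, d) for s in males for d in females
                     if find(s) != find(d)]
        choices = ["founder"] + (["old_fam"] if fams else []) \
            + (["new_fam"] if new_pairs else [])
        c = choices[rng.integers(len(choices))]
        if c == "founder":
            sire.append(None)
            dam.append(None)
        elif c == "old_fam":
            s, d = fams[rng.integers(len(fams))]
            sire.append(s)
            dam.append(d)
        else:
            s, d = new_pairs[rng.integers(len(new_pairs))]
            comp[find(s)] = find(d)
            fams.append((s, d))
            sire.append(s)
            dam.append(d)
        sex.append(int(rng.integers(2)))
        comp.append(i)
        if sire[-1] is not None:
            comp[find(i)] = find(sire[-1])
    ids = list(range(1, n + 1))
    return make_pedigree(
        ids,
        [None if s is None else s + 1 for s in sire],
        [None if d is None else d + 1 for d in dam],
        sex=["M" if x == 0 else "F" for x in sex])


def gene_drop_relationships(ped, n_rep, rng):
    """Monte-Carlo numerator relationships: drop two unique founder alleles
    per founder through the pedigree and estimate A_ij = 2 * P(IBD) from
    allele-sharing frequencies."""
    n = ped.n
    alleles = np.zeros((n_rep, n, 2), dtype=np.int64)
    next_allele = 0
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN:
            pick = rng.integers(2, size=n_rep)
            alleles[:, i, 0] = alleles[np.arange(n_rep), s, pick]
        else:
            alleles[:, i, 0] = next_allele
            next_allele += 1
        if d != UNKNOWN:
            pick = rng.integers(2, size=n_rep)
            alleles[:, i, 1] = alleles[np.arange(n_rep), d, pick]
        else:
            alleles[:, i, 1] = next_allele
            next_allele += 1
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            share = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    share += alleles[:, i, a] == alleles[:, j, b]
            A[i, j] = share.mean() / 2.0
    return A


def direct_maf_corrected_correlation(truth, dosage, p):
    """Direct, index-by-index evaluation of the MAF-corrected dosage
    correlation for one individual."""
    t = np.asarray(truth, dtype=float) - 2.0 * p
    d = np.asarray(dosage, dtype=float) - 2.0 * p
    t = t - t.mean()
    d = d - d.mean()
    return float((t * d).sum() / np.sqrt((t * t).sum() * (d * d).sum()))
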