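"""Poisson-gamma sequencing read simulator.

Read depth at a locus varies both with the individual's target coverage x
and with a per-locus "sequenceability" s_j ~ Gamma(shape=4, rate=4)
(mean 1, variance 0.25): the read count is n_ij ~ Poisson(x_i * s_j) and
reads fall on the two chromosomes of an individual with equal probability.
Reads report the true allele of the chromosome they came from; sequencing
error is modelled downstream, in the genotype-likelihood (penetrance)
construction of the peeling engine, not by flipping reads here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budget import SequencingPlan

GAMMA_SHAPE = 4.0
GAMMA_RATE = 4.0


@dataclass
class ReadCounts:
    """Per individual x locus counts of alternative/reference reads."""

    n_alt: np.ndarray  # (n_ind, n_loci) int32
    n_ref: np.ndarray
    sequenceability: np.ndarray  # (n_loci,)

    @property
    def total(self) -> np.ndarray:
        return self.n_alt + self.n_ref

    def to_frame(self) -> pd.DataFrame:
        """Sparse triplet representation (id, locus, n_ref, n_alt)."""
        i, j = np.nonzero(self.n_alt + self.n_ref)
        return pd.DataFrame({"id": i, "locus": j,
                             "n_ref": self.n_ref[i, j], "n_alt": self.n_alt[i, j]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_sequenceability(n_loci: int, shape: float = GAMMA_SHAPE,
                           rate: float = GAMMA_RATE, seed=None) -> np.ndarray:
    """i.i.d. Gamma(shape, rate) sequenceability draws, one per locus."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, 1.0 / rate, size=n_loci)


def simulate_reads(plan: SequencingPlan, alleles: np.ndarray,
                   s: np.ndarray, seed=None) -> ReadCounts:
    """Simulate read counts for every individual in ``plan``.

    Parameters
    ----------
    plan : coverage x_i per individual (0 = unsequenced).
    alleles : (n_ind, n_loci, 2) {0,1} true phased alleles.
    s : per-locus sequenceability vector (one draw per scenario, shared by
        all individuals).
    """
    rng = np.random.default_rng(seed)
    n_ind, n_loci, _ = alleles.shape
    s = np.asarray(s, dtype=float)
    if s.shape != (n_loci,):
        raise ValueError("sequenceability vector not aligned to loci")
    n_alt = np.zeros((n_ind, n_loci), dtype=np.int32)
    n_ref = np.zeros((n_ind, n_loci), dtype=np.int32)
    seq = plan.sequenced
    for i in seq:
        lam = plan.coverage[i] * s
        n = rng.poisson(lam)
        n1 = rng.binomial(n, 0.5)  # reads from the paternal chromosome
        n2 = n - n1
        a = n1 * alleles[i, :, 0] + n2 * alleles[i, :, 1]
        n_alt[i] = a
        n_ref[i] = n - a
    return ReadCounts(n_alt=n_alt, n_ref=n_ref, sequenceability=s)
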