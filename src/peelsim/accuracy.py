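"""Imputation-accuracy metrics: per-individual dosage correlations with and
without the minor-allele-frequency correction, plus the early-generation
exclusion rules used when summarizing population-wide accuracy.

The MAF-corrected correlation is the Pearson correlation, across loci,
between true genotypes and imputed dosages after centering both by twice
the allele frequency (2 p_j); because the centering varies per locus it
down-weights the trivially predictable part of the genotype and is the
standard way to keep accuracies comparable across allele-frequency
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


def _row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row pair; NaN where either has zero
    variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


@dataclass
class AccuracyReport:
    """Per-individual raw and MAF-corrected dosage correlations."""

    raw: np.ndarray         # (n,) per-individual, NaN where undefined
    corrected: np.ndarray   # (n,)
    excluded: np.ndarray    # (n,) bool exclusion mask applied to the means
    n_loci_used: int

    @property
    def mean_corrected(self) -> float:
        keep = ~self.excluded & ~np.isnan(self.corrected)
        return float(self.corrected[keep].mean()) if keep.any() else np.nan

    @property
    def mean_raw(self) -> float:
        keep = ~self.excluded & ~np.isnan(self.raw)
        return float(self.raw[keep].mean()) if keep.any() else np.nan

    def group_means(self, groups: np.ndarray) -> pd.DataFrame:
        """Mean accuracies per group label (e.g. generation or decile)."""
        keep = ~self.excluded & ~np.isnan(self.corrected)
        df = pd.DataFrame({"group": groups, "raw": self.raw,
                           "corrected": self.corrected})[keep]
        return df.groupby("group").mean().reset_index()

    def to_frame(self, ped: Pedigree | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "position": np.arange(len(self.raw)),
            "raw": self.raw, "corrected": self.corrected,
            "excluded": self.excluded,
        })
        if ped is not None:
            df.insert(0, "id", ped.ids)
            df["generation"] = ped.generation
        return df


def accuracy(truth: np.ndarray, dosage: np.ndarray, p: np.ndarray,
             excluded: np.ndarray | None = None,
             freq_bounds: tuple[float, float] = (0.001, 0.999)
             ) -> AccuracyReport:
    """Per-individual dosage correlations between truth and imputation.

    Parameters
    ----------
    truth : (n, L) true genotypes 0/1/2.
    dosage : (n, L) imputed expected allele counts.
    p : (L,) allele frequencies computed from the true genotypes of the
        whole population; loci with p outside ``freq_bounds`` are dropped.
    excluded : optional (n,) mask of individuals left out of the means
        (they still get individual correlations).
    """
    truth = np.asarray(truth, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    p = np.asarray(p, dtype=float)
    if truth.shape != dosage.shape or truth.shape[1] != p.size:
        raise ValueError("truth, dosage and p shapes do not match")
    keep = (p > freq_bounds[0]) & (p < freq_bounds[1])
    t, d, pk = truth[:, keep], dosage[:, keep], p[keep]
    raw = _row_correlations(t, d)
    corrected = _row_correlations(t - 2 * pk, d - 2 * pk)
    if excluded is None:
        excluded = np.zeros(truth.shape[0], dtype=bool)
    return AccuracyReport(raw=raw, corrected=corrected,
                          excluded=np.asarray(excluded, dtype=bool),
                          n_loci_used=int(keep.sum()))


def apply_exclusions(ped: Pedigree, mode: str) -> np.ndarray:
    """Exclusion mask for population-wide accuracy summaries.

    ``discrete``: evaluate only generation >= 4 (the base generation
    counts as generation 0); ``overlapping``: drop the first 20% of
    pedigree positions; ``none``: keep everybody.
    """
    n = ped.n
    mask = np.zeros(n, dtype=bool)
    if mode == "none":
        return mask
    if mode == "discrete":
        if np.any(ped.generation < 0):
            raise ValueError("discrete exclusions need generation labels")
        mask[ped.generation < 4] = True
        return mask
    if mode == "overlapping":
        mask[: int(np.floor(0.2 * n))] = True
        return mask
    raise ValueError(f"unknown exclusion mode {mode!r}")
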