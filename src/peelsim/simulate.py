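"""Synthetic population generator: coalescent founder haplotypes, pedigree
simulation with truncation selection, gene dropping, and marker panels.

Two pedigree generators are provided:

* :func:`simulate_discrete_population` — discrete, non-overlapping
  generations produced by truncation selection on true breeding values
  (default 5% of males and 25% of females selected, each selected parent
  contributing equally), preceded by ten unselected burn-in generations
  whose selected parents form the retained "base generation";
* :func:`simulate_overlapping_population` — a continuous birth order where
  parents are truncation-selected from a sliding window of recent
  candidates, standing in for deep commercial pedigrees with overlapping
  generations.

Founder haplotypes come from a neutral coalescent (msprime backend) under a
piecewise-constant effective-population-size history; segregating sites are
thinned to the target whole-genome-sequence (SEQ) density, and nested
high-density (HD) and low-density (LD) marker panels are chosen evenly
spaced in cM among founder-common variants (LD = every 10th HD locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, MALE, UNKNOWN

#: piecewise-constant Ne history: (generations ago, Ne); small at present,
#: growing to a large ancestral size, as estimated for livestock populations
DEFAULT_NE_TRAJECTORY = ((0, 100), (100, 1000), (500, 4000), (1000, 10000))


@dataclass(frozen=True)
class DeskScale:
    """Scaled-down defaults used by the experiment grids.

    Full-scale studies use 20 chromosomes of 1e8 bp with 150,000 SEQ /
    3,000 HD / 300 LD loci each; the desk scale keeps the genetic length
    (100 cM per chromosome), the 10:1 HD:LD nesting and the selection and
    genotyping regimes, while shrinking the locus counts and population
    sizes so a whole scenario grid runs on one CPU in minutes.
    """

    n_chromosomes: int = 3
    seq_per_chr: int = 2000
    hd_per_chr: int = 200
    ld_per_chr: int = 20
    n_hap: int = 400
    chrom_length_bp: float = 1e7
    mu: float = 2.5e-8
    #: per-bp recombination rate; chosen so each chromosome spans 1 Morgan
    rec: float = 1e-7
    n_qtn: int = 500
    h2: float = 0.3

    def founder_pool(self, seed=None) -> "FounderPool":
        return generate_base_haplotypes(
            n_hap=self.n_hap, n_chromosomes=self.n_chromosomes,
            seq_per_chr=self.seq_per_chr, hd_per_chr=self.hd_per_chr,
            ld_per_chr=self.ld_per_chr, chrom_length_bp=self.chrom_length_bp,
            mu=self.mu, rec=self.rec, seed=seed)


#: the study-scale parameters (kept available; heavy to simulate)
FULL_SCALE = dict(n_chromosomes=20, seq_per_chr=150_000, hd_per_chr=3000,
                  ld_per_chr=300, n_hap=1000, chrom_length_bp=1e8,
                  mu=2.5e-8, rec=1e-8, n_qtn=20_000, h2=0.3)


@dataclass
class GeneticMap:
    """Locus coordinates: chromosome index, bp position, cM position."""

    chrom: np.ndarray  # (L,) int
    bp: np.ndarray     # (L,) float
    cm: np.ndarray     # (L,) float, within-chromosome, in [0, length_cm]

    def __post_init__(self):
        for c in np.unique(self.chrom):
            cc = self.cm[self.chrom == c]
            if np.any(np.diff(cc) <= 0):
                raise ValueError("map positions must be strictly increasing")

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    def chromosomes(self):
        return np.unique(self.chrom)

    def chrom_slice(self, c) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)


@dataclass
class HaplotypePanel:
    """Phased biallelic alleles per individual with map and panel masks."""

    alleles: np.ndarray  # (n, L, 2) int8, [:, :, 0]=paternal, 1=maternal
    map: GeneticMap
    is_hd: np.ndarray    # (L,) bool
    is_ld: np.ndarray    # (L,) bool, subset of is_hd

    def __post_init__(self):
        if np.any(self.is_ld & ~self.is_hd):
            raise ValueError("LD panel must be nested within HD")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        return self.alleles.sum(axis=2)

    def allele_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=(0, 2))

    def hd_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_hd)

    def ld_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_ld)


@dataclass
class FounderPool:
    """Pool of phased founder haplotypes with panel annotations."""

    haplotypes: np.ndarray  # (n_hap, L) int8
    map: GeneticMap
    is_hd: np.ndarray
    is_ld: np.ndarray

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class TraitModel:
    """Additive polygenic trait: QTN subset of SEQ loci, normal effects."""

    qtn_indices: np.ndarray
    effects: np.ndarray
    h2: float = 0.3

    def breeding_values(self, alleles: np.ndarray) -> np.ndarray:
        g = alleles[:, self.qtn_indices, :].sum(axis=2)
        return g @ self.effects


NOT_GENOTYPED, LD, HD = 0, 1, 2


@dataclass
class GenotypingAssignment:
    """Per-individual marker-array status: NOT_GENOTYPED / LD / HD."""

    status: np.ndarray  # (n,) int8

    def genotyped(self) -> np.ndarray:
        return self.status != NOT_GENOTYPED

    def counts(self) -> dict[str, int]:
        return {"none": int(np.sum(self.status == NOT_GENOTYPED)),
                "ld": int(np.sum(self.status == LD)),
                "hd": int(np.sum(self.status == HD))}


@dataclass
class Population:
    """A simulated pedigreed population with its genomes and trait."""

    pedigree: Pedigree
    haplotypes: HaplotypePanel
    tbv: np.ndarray
    trait: TraitModel

    def __iter__(self):  # allow (ped, panel) unpacking
        return iter((self.pedigree, self.haplotypes))


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _demography(ne_trajectory):
    import msprime

    demog = msprime.Demography()
    traj = sorted(ne_trajectory)
    demog.add_population(name="pop", initial_size=traj[0][1])
    for t, ne in traj[1:]:
        demog.add_population_parameters_change(time=t, initial_size=ne)
    return demog


def coalescent_segregating_sites(n_hap: int, chrom_length_bp: float,
                                 mu: float, rec: float,
                                 ne_trajectory=DEFAULT_NE_TRAJECTORY,
                                 seed=None) -> int:
    """Number of segregating biallelic sites in one coalescent chromosome
    sample (before any thinning); handy for diversity calibration."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_hap // 2, demography=_demography(ne_trajectory), ploidy=2,
        sequence_length=chrom_length_bp, recombination_rate=rec,
        random_seed=None if seed is None else int(seed) + 1)
    ts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(),
        random_seed=None if seed is None else int(seed) + 2)
    G = ts.genotype_matrix()
    freq = G.mean(axis=1)
    return int(np.sum((freq > 0) & (freq < 1)))


def generate_base_haplotypes(n_hap: int = 1000, n_chromosomes: int = 20,
                             seq_per_chr: int = 150_000,
                             hd_per_chr: int = 3000, ld_per_chr: int = 300,
                             chrom_length_bp: float = 1e8,
                             mu: float = 2.5e-8, rec: float = 1e-8,
                             ne_trajectory=DEFAULT_NE_TRAJECTORY,
                             maf_min_array: float = 0.05,
                             seed=None) -> FounderPool:
    """Simulate a founder haplotype pool under a neutral coalescent.

    Each chromosome is an independent coalescent simulation with the given
    per-bp mutation and recombination rates under piecewise-constant Ne;
    segregating biallelic sites are thinned evenly to ``seq_per_chr`` SEQ
    loci.  HD loci are picked evenly spaced in cM among SEQ loci with
    founder MAF >= ``maf_min_array``; the LD panel nests inside HD (every
    ``hd_per_chr/ld_per_chr``-th HD locus).

    Raises a ValueError when a chromosome yields fewer segregating sites
    than requested (advice: longer chromosome or higher mutation rate).
    """
    import msprime

    if n_hap % 2:
        raise ValueError("n_hap must be even")
    if ld_per_chr and hd_per_chr % ld_per_chr:
        raise ValueError("hd_per_chr must be a multiple of ld_per_chr")
    rng = np.random.default_rng(seed)
    demog = _demography(ne_trajectory)
    haps, chroms, bps, cms, hd_mask, ld_mask = [], [], [], [], [], []
    for c in range(n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_hap // 2, demography=demog, ploidy=2,
            sequence_length=chrom_length_bp, recombination_rate=rec,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        ts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31 - 1)))
        G = ts.genotype_matrix().astype(np.int8)  # (sites, n_hap)
        pos = ts.tables.sites.position
        freq = G.mean(axis=1)
        seg = (freq > 0) & (freq < 1)
        G, pos = G[seg], pos[seg]
        if G.shape[0] < seq_per_chr:
            raise ValueError(
                f"chromosome {c}: only {G.shape[0]} segregating sites for "
                f"{seq_per_chr} requested; use a longer chromosome or a "
                f"higher mutation rate")
        keep = np.unique(np.linspace(0, G.shape[0] - 1, seq_per_chr).round()
                         .astype(int))
        # linspace rounding can collide; top up with unused sites
        if keep.size < seq_per_chr:
            unused = np.setdiff1d(np.arange(G.shape[0]), keep)
            extra = rng.choice(unused, seq_per_chr - keep.size, replace=False)
            keep = np.sort(np.concatenate([keep, extra]))
        G, pos = G[keep], pos[keep]
        cm = pos * rec * 100.0
        hd = _pick_even(cm, G.mean(axis=1), hd_per_chr, maf_min_array)
        ld = np.zeros(seq_per_chr, dtype=bool)
        if ld_per_chr:
            hd_idx = np.flatnonzero(hd)
            ld[hd_idx[::hd_per_chr // ld_per_chr][:ld_per_chr]] = True
        haps.append(G.T)
        chroms.append(np.full(seq_per_chr, c))
        bps.append(pos)
        cms.append(cm)
        hd_mask.append(hd)
        ld_mask.append(ld)
    gmap = GeneticMap(chrom=np.concatenate(chroms), bp=np.concatenate(bps),
                      cm=np.concatenate(cms))
    return FounderPool(haplotypes=np.concatenate(haps, axis=1), map=gmap,
                       is_hd=np.concatenate(hd_mask),
                       is_ld=np.concatenate(ld_mask))


def _pick_even(cm: np.ndarray, freq: np.ndarray, k: int, maf_min: float
               ) -> np.ndarray:
    """Pick k loci evenly spaced in cM among those with MAF >= maf_min."""
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf >= maf_min)
    if eligible.size < k:  # fall back to the k most common variants
        eligible = np.sort(np.argsort(-maf, kind="stable")[:max(k, 1)])
    targets = np.linspace(cm.min(), cm.max(), k)
    used = np.zeros(len(cm), dtype=bool)
    chosen: list[int] = []
    elig_cm = cm[eligible]
    for t in targets:
        order = np.argsort(np.abs(elig_cm - t), kind="stable")
        for j in order:
            if not used[eligible[j]]:
                used[eligible[j]] = True
                chosen.append(int(eligible[j]))
                break
    mask = np.zeros(len(cm), dtype=bool)
    mask[chosen] = True
    return mask


# ---------------------------------------------------------------------------
# meiosis / gene dropping
# ---------------------------------------------------------------------------

def _chrom_bounds(gmap: GeneticMap):
    bounds = []
    for c in gmap.chromosomes():
        idx = gmap.chrom_slice(c)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        bounds.append((lo, hi, 0.0, float(max(gmap.cm[lo:hi].max(), 1e-9))))
    return bounds


def _gamete(parent_alleles: np.ndarray, gmap: GeneticMap, rng,
            chrom_bounds) -> np.ndarray:
    """One recombinant gamete: Poisson crossovers (1 per Morgan, no
    interference), crossover points uniform in cM, random start phase."""
    out = np.empty(parent_alleles.shape[0], dtype=np.int8)
    for lo, hi, cm0, cm1 in chrom_bounds:
        n_x = rng.poisson((cm1 - cm0) / 100.0)
        cm = gmap.cm[lo:hi]
        phase = np.full(hi - lo, rng.integers(2), dtype=np.int64)
        if n_x:
            points = np.sort(rng.uniform(cm0, cm1, n_x))
            phase = (phase + np.searchsorted(points, cm)) % 2
        seg = parent_alleles[lo:hi]
        out[lo:hi] = np.where(phase == 0, seg[:, 0], seg[:, 1])
    return out


def _sample_trait(pool: FounderPool, n_qtn: int, h2: float, rng) -> TraitModel:
    qtn = np.sort(rng.choice(pool.map.n_loci, size=min(n_qtn, pool.map.n_loci),
                             replace=False))
    eff = rng.normal(0.0, 1.0, size=qtn.size)
    return TraitModel(qtn_indices=qtn, effects=eff, h2=h2)


def _founder_alleles(pool: FounderPool, n: int, rng) -> np.ndarray:
    """Draw 2n haplotypes from the pool (without replacement while they
    last, topping up with replacement for very large base populations)."""
    need = 2 * n
    if need <= pool.n_hap:
        take = rng.choice(pool.n_hap, size=need, replace=False)
    else:
        take = np.concatenate([
            rng.permutation(pool.n_hap),
            rng.choice(pool.n_hap, size=need - pool.n_hap, replace=True)])
    return pool.haplotypes[take].reshape(n, 2, -1).transpose(0, 2, 1).copy()


# ---------------------------------------------------------------------------
# discrete generations
# ---------------------------------------------------------------------------

def _equal_contributions(n_parents: int, n_children: int, rng) -> np.ndarray:
    """Parent index per child with counts differing by at most one."""
    base = np.repeat(np.arange(n_parents), n_children // n_parents)
    rem = n_children - base.size
    extra = (rng.choice(n_parents, size=rem, replace=False) if rem
             else np.empty(0, dtype=int))
    out = np.concatenate([base, extra]).astype(int)
    rng.shuffle(out)
    return out


def _balanced_sexes(n: int, rng) -> np.ndarray:
    sex = np.empty(n, dtype=np.int32)
    sex[: n // 2] = MALE
    sex[n // 2:] = 1 - MALE
    rng.shuffle(sex)
    return sex


def simulate_discrete_population(pool: FounderPool, n_generations: int,
                                 generation_size: int,
                                 sire_prop: float = 0.05,
                                 dam_prop: float = 0.25,
                                 n_qtn: int = 20_000, h2: float = 0.3,
                                 n_burnin: int = 10,
                                 seed=None) -> Population:
    """Discrete-generation population under truncation selection on TBV.

    ``n_burnin`` unselected generations are simulated first and discarded;
    the parents of generation 1 (truncation-selected from the last burn-in
    generation) are retained as the base generation (generation 0).  Each
    retained generation has ``generation_size`` individuals; each selected
    parent contributes the same number of progeny, dams nested within
    sires in equal shares.
    """
    n_sires = int(np.floor(sire_prop * generation_size / 2))
    n_dams = int(np.floor(dam_prop * generation_size / 2))
    if n_sires < 1 or n_dams < 1:
        raise ValueError("selection proportions yield no sires or dams")
    rng = np.random.default_rng(seed)
    trait = _sample_trait(pool, n_qtn, h2, rng)
    bounds = _chrom_bounds(pool.map)

    # burn-in: unselected random mating
    cur = _founder_alleles(pool, generation_size, rng)
    cur_sex = _balanced_sexes(generation_size, rng)
    for _ in range(n_burnin):
        males = np.flatnonzero(cur_sex == MALE)
        females = np.flatnonzero(cur_sex != MALE)
        nxt = np.empty_like(cur)
        for i in range(generation_size):
            s = males[rng.integers(males.size)]
            d = females[rng.integers(females.size)]
            nxt[i, :, 0] = _gamete(cur[s], pool.map, rng, bounds)
            nxt[i, :, 1] = _gamete(cur[d], pool.map, rng, bounds)
        cur = nxt
        cur_sex = _balanced_sexes(generation_size, rng)

    # selection generations; base = selected parents of generation 1
    cand_alleles, cand_sex = cur, cur_sex
    cand_tbv = trait.breeding_values(cand_alleles)
    records: list[tuple[int, int, int, int]] = []
    all_alleles: list[np.ndarray] = []
    pos_of_cand: dict[int, int] = {}
    for g in range(1, n_generations + 1):
        males = np.flatnonzero(cand_sex == MALE)
        females = np.flatnonzero(cand_sex != MALE)
        sel_s = males[np.argsort(-cand_tbv[males], kind="stable")[:n_sires]]
        sel_d = females[np.argsort(-cand_tbv[females], kind="stable")[:n_dams]]
        if g == 1:
            base = np.concatenate([sel_s, sel_d])
            for b in base:
                records.append((UNKNOWN, UNKNOWN, int(cand_sex[b]), 0))
                all_alleles.append(cand_alleles[b])
            pos_of_cand = {int(b): k for k, b in enumerate(base)}
        dam_of_child = _equal_contributions(sel_d.size, generation_size, rng)
        sire_of_dam = _equal_contributions(sel_s.size, sel_d.size, rng)
        child_sex = _balanced_sexes(generation_size, rng)
        new_pos: dict[int, int] = {}
        child_alleles = np.empty((generation_size, pool.map.n_loci, 2),
                                 dtype=np.int8)
        for i in range(generation_size):
            d = int(sel_d[dam_of_child[i]])
            s = int(sel_s[sire_of_dam[dam_of_child[i]]])
            child_alleles[i, :, 0] = _gamete(cand_alleles[s], pool.map, rng, bounds)
            child_alleles[i, :, 1] = _gamete(cand_alleles[d], pool.map, rng, bounds)
            records.append((pos_of_cand[s], pos_of_cand[d], int(child_sex[i]), g))
            all_alleles.append(child_alleles[i])
            new_pos[i] = len(records) - 1
        cand_alleles, cand_sex = child_alleles, child_sex
        cand_tbv = trait.breeding_values(cand_alleles)
        pos_of_cand = new_pos

    return _assemble(records, all_alleles, pool, trait)


def _assemble(records, all_alleles, pool: FounderPool, trait: TraitModel
              ) -> Population:
    n = len(records)
    ped = Pedigree(
        ids=np.arange(1, n + 1).astype(object),
        sire=np.array([r[0] for r in records], dtype=np.int32),
        dam=np.array([r[1] for r in records], dtype=np.int32),
        sex=np.array([r[2] for r in records], dtype=np.int32),
        generation=np.array([r[3] for r in records], dtype=np.int32))
    alleles = np.stack(all_alleles)
    panel = HaplotypePanel(alleles=alleles, map=pool.map,
                           is_hd=pool.is_hd, is_ld=pool.is_ld)
    return Population(pedigree=ped, haplotypes=panel,
                      tbv=trait.breeding_values(alleles), trait=trait)


# ---------------------------------------------------------------------------
# overlapping generations
# ---------------------------------------------------------------------------

def simulate_overlapping_population(pool: FounderPool, n_individuals: int,
                                    window_frac: float = 0.12,
                                    sire_prop: float = 0.05,
                                    dam_prop: float = 0.25,
                                    founder_frac: float = 0.05,
                                    n_qtn: int = 20_000, h2: float = 0.3,
                                    seed=None) -> Population:
    """Overlapping-generation population: continuous birth order, parents
    truncation-selected from a sliding window of recent candidates.

    For each birth, a parental cohort is placed at an offset drawn
    uniformly within the sliding window, and the sire (dam) is then
    truncation-selected from the top ``sire_prop`` (``dam_prop``) of that
    cohort's males (females) by TBV.  Sampling the cohort offset uniformly
    keeps the parent-offspring age gap uniform over the window (truncation
    selection alone would concentrate parents at the window's recent edge);
    the default window fraction is calibrated so the realized
    generation-equivalent depth (mean longest ancestral path of the
    last-born individuals) is about 20 generations, emulating deep
    commercial pedigrees.
    """
    if n_individuals < 100:
        raise ValueError("n_individuals must be >= 100")
    rng = np.random.default_rng(seed)
    trait = _sample_trait(pool, n_qtn, h2, rng)
    bounds = _chrom_bounds(pool.map)
    n_found = max(30, int(round(founder_frac * n_individuals)))
    W = max(30, int(round(window_frac * n_individuals)))
    C = max(20, W // 4)  # cohort width

    alleles = np.empty((n_individuals, pool.map.n_loci, 2), dtype=np.int8)
    alleles[:n_found] = _founder_alleles(pool, n_found, rng)
    sex = np.empty(n_individuals, dtype=np.int32)
    sex[:n_found] = _balanced_sexes(n_found, rng)
    sire = np.full(n_individuals, UNKNOWN, dtype=np.int32)
    dam = np.full(n_individuals, UNKNOWN, dtype=np.int32)
    tbv = np.empty(n_individuals)
    tbv[:n_found] = trait.breeding_values(alleles[:n_found])

    def _pick(i: int, want_male: bool, prop: float) -> int:
        for _ in range(20):  # retry until the cohort has the needed sex
            # offset in [W/4, W]: a minimum parent-offspring age gap keeps
            # the longest ancestral path (hence pedigree depth) bounded
            centre = i - 1 - int(rng.integers(W // 4, W))
            lo, hi = max(0, centre - C // 2), min(i, centre + C // 2 + 1)
            cohort = np.arange(max(0, lo), hi)
            pool_ = cohort[(sex[cohort] == MALE) == want_male]
            if pool_.size:
                top = pool_[np.argsort(-tbv[pool_], kind="stable")
                            [:max(1, int(np.ceil(prop * pool_.size)))]]
                return int(top[rng.integers(top.size)])
        # degenerate cohort draws (e.g. near the founder boundary): fall
        # back to the whole window
        window = np.arange(max(0, i - W), i)
        pool_ = window[(sex[window] == MALE) == want_male]
        top = pool_[np.argsort(-tbv[pool_], kind="stable")
                    [:max(1, int(np.ceil(prop * pool_.size)))]]
        return int(top[rng.integers(top.size)])

    for i in range(n_found, n_individuals):
        s = _pick(i, True, sire_prop)
        d = _pick(i, False, dam_prop)
        sire[i], dam[i] = s, d
        alleles[i, :, 0] = _gamete(alleles[s], pool.map, rng, bounds)
        alleles[i, :, 1] = _gamete(alleles[d], pool.map, rng, bounds)
        tbv[i] = float(trait.breeding_values(alleles[i:i + 1])[0])
        sex[i] = int(rng.integers(2))

    ped = Pedigree(ids=np.arange(1, n_individuals + 1).astype(object),
                   sire=sire, dam=dam, sex=sex)
    panel = HaplotypePanel(alleles=alleles, map=pool.map,
                           is_hd=pool.is_hd, is_ld=pool.is_ld)
    return Population(pedigree=ped, haplotypes=panel, tbv=tbv, trait=trait)


def generation_depth(ped: Pedigree, last_frac: float = 0.05) -> float:
    """Mean longest ancestral path of the last-born ``last_frac`` of the
    pedigree (generation-equivalent depth of an overlapping pedigree)."""
    g = np.zeros(ped.n)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        gs = g[s] if s != UNKNOWN else 0.0
        gd = g[d] if d != UNKNOWN else 0.0
        g[i] = max(gs, gd) + (0.0 if s == UNKNOWN and d == UNKNOWN else 1.0)
    k = max(1, int(round(last_frac * ped.n)))
    return float(g[-k:].mean())


# ---------------------------------------------------------------------------
# genotyping assignment
# ---------------------------------------------------------------------------

def assign_panels_and_genotyping(ped: Pedigree, seed=None,
                                 base_rate: float = 0.75,
                                 base_hd_frac: float = 0.67,
                                 later_rate: float = 0.95,
                                 later_hd_frac: float = 0.15,
                                 ) -> GenotypingAssignment:
    """Assign marker-array genotyping status.

    In the base generation 75% of individuals are genotyped, of which 67%
    on HD; in the remaining generations 95% are genotyped, of which 15% on
    HD (counts rounded).  Genotyped status is drawn at random; within each
    generation the HD array is prioritised for the individuals with the
    most genotyped progeny and grandprogeny (ties broken by pedigree
    position), except in the final generation where HD is assigned at
    random.

    For overlapping pedigrees (no generation labels) the founders take the
    base-generation rates, everybody else the later rates, and the last
    10% of positions play the role of the final generation.
    """
    from .pedigree import count_progeny

    rng = np.random.default_rng(seed)
    status = np.zeros(ped.n, dtype=np.int8)
    discrete = bool(np.all(ped.generation >= 0))

    if discrete:
        groups = [(np.flatnonzero(ped.generation == g), g == 0,
                   g == ped.generation.max())
                  for g in np.unique(ped.generation)]
    else:
        founders = ped.is_founder()
        last = np.zeros(ped.n, dtype=bool)
        last[int(np.ceil(0.9 * ped.n)):] = True
        groups = [(np.flatnonzero(founders & ~last), True, False),
                  (np.flatnonzero(~founders & ~last), False, False),
                  (np.flatnonzero(last), False, True)]

    # first pass: draw genotyped/non-genotyped per group
    geno_flag = np.zeros(ped.n, dtype=bool)
    draws = []
    for members, is_base, _ in groups:
        rate = base_rate if is_base else later_rate
        g = (rng.choice(members, size=int(round(rate * members.size)),
                        replace=False) if members.size else
             np.empty(0, dtype=int))
        geno_flag[g] = True
        draws.append(g)
    prog, grand = count_progeny(ped, geno_flag)
    priority = prog + grand

    # second pass: split each group's genotyped into HD/LD
    for (members, is_base, is_final), geno in zip(groups, draws):
        if geno.size == 0:
            continue
        hd_frac = base_hd_frac if is_base else later_hd_frac
        n_hd = int(round(hd_frac * geno.size))
        if is_final:
            hd = rng.choice(geno, size=n_hd, replace=False)
        else:
            order = geno[np.lexsort((geno, -priority[geno]))]
            hd = order[:n_hd]
        status[geno] = LD
        status[hd] = HD
    return GenotypingAssignment(status=status)


def array_calls(panel: HaplotypePanel, assignment: GenotypingAssignment
                ) -> np.ndarray:
    """Observed marker-array genotypes (0/1/2; -1 where unobserved).

    HD individuals are observed at all HD loci, LD individuals only at LD
    loci, ungenotyped individuals nowhere; SEQ-only loci are never on an
    array.
    """
    n, L = panel.n_individuals, panel.n_loci
    calls = np.full((n, L), -1, dtype=np.int8)
    g = panel.genotypes().astype(np.int8)
    hd_ind = assignment.status == HD
    ld_ind = assignment.status == LD
    if hd_ind.any():
        calls[np.ix_(hd_ind, panel.is_hd)] = g[np.ix_(hd_ind, panel.is_hd)]
    if ld_ind.any():
        calls[np.ix_(ld_ind, panel.is_ld)] = g[np.ix_(ld_ind, panel.is_ld)]
    return calls


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_panel(panel: HaplotypePanel, path) -> None:
    """Persist a haplotype panel (alleles, map, panel masks) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("alleles", data=panel.alleles, compression="gzip")
        f.create_dataset("chrom", data=panel.map.chrom)
        f.create_dataset("bp", data=panel.map.bp)
        f.create_dataset("cm", data=panel.map.cm)
        f.create_dataset("is_hd", data=panel.is_hd)
        f.create_dataset("is_ld", data=panel.is_ld)


def load_panel(path) -> HaplotypePanel:
    import h5py

    with h5py.File(path, "r") as f:
        gmap = GeneticMap(chrom=f["chrom"][:], bp=f["bp"][:], cm=f["cm"][:])
        return HaplotypePanel(alleles=f["alleles"][:], map=gmap,
                              is_hd=f["is_hd"][:].astype(bool),
                              is_ld=f["is_ld"][:].astype(bool))


def panel_to_vcf(panel: HaplotypePanel, path, ids=None) -> None:
    """Export the true phased SEQ genotypes as a minimal VCF (GT field)."""
    n, L = panel.n_individuals, panel.n_loci
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.map.chromosomes():
            fh.write(f"##contig=<ID=chr{int(c) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in ids) + "\n")
        a = panel.alleles
        for j in range(L):
            gts = "\t".join(f"{a[i, j, 0]}|{a[i, j, 1]}" for i in range(n))
            tag = "HD" if panel.is_hd[j] else "SEQ"
            if panel.is_ld[j]:
                tag = "LD"
            fh.write(f"chr{int(panel.map.chrom[j]) + 1}\t"
                     f"{int(panel.map.bp[j]) + 1}\t.\tA\tB\t.\tPASS\t"
                     f"PANEL={tag}\tGT\t{gts}\n")
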