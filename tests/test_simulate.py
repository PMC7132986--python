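import numpy as np
import pytest

from peelsim.pedigree import UNKNOWN, MALE, count_progeny
from peelsim.simulate import (
    HD, LD, NOT_GENOTYPED,
    assign_panels_and_genotyping, array_calls, generate_base_haplotypes,
    generation_depth, simulate_discrete_population,
    simulate_overlapping_population,
)
from peelsim.pedigree import make_pedigree


class TestFounderPool:
    def test_panel_nesting_and_counts(self, tiny_pool):
        assert tiny_pool.haplotypes.shape == (60, 120)
        assert tiny_pool.is_hd.sum() == 40 and tiny_pool.is_ld.sum() == 20
        assert not np.any(tiny_pool.is_ld & ~tiny_pool.is_hd)
        freq = tiny_pool.haplotypes.mean(axis=0)
        assert np.all((freq > 0) & (freq < 1))  # all sites segregate

    def test_map_monotone_within_chromosome(self, tiny_pool):
        for c in tiny_pool.map.chromosomes():
            cm = tiny_pool.map.cm[tiny_pool.map.chrom == c]
            assert np.all(np.diff(cm) > 0)

    def test_same_seed_reproduces_haplotypes(self):
        kw = dict(n_hap=10, n_chromosomes=1, seq_per_chr=20, hd_per_chr=4,
                  ld_per_chr=2, chrom_length_bp=2e5, mu=2e-6, rec=5e-6,
                  ne_trajectory=((0, 200),), seed=3)
        a = generate_base_haplotypes(**kw)
        b = generate_base_haplotypes(**kw)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.map.bp, b.map.bp)

    def test_zero_mutation_rate_raises_helpful_error(self):
        with pytest.raises(ValueError, match="segregating sites"):
            generate_base_haplotypes(n_hap=10, n_chromosomes=1,
                                     seq_per_chr=20, hd_per_chr=4,
                                     ld_per_chr=2, chrom_length_bp=1e5,
                                     mu=0.0, rec=1e-6,
                                     ne_trajectory=((0, 200),), seed=1)

    def test_odd_haplotype_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_base_haplotypes(n_hap=9)

    def test_watterson_expectation_constant_ne(self):
        """Mean segregating-site count over seeds matches theta * a_{n-1}."""
        from peelsim.simulate import coalescent_segregating_sites
        ne, mu, L, n_hap = 500.0, 1e-6, 1e5, 4
        theta = 4 * ne * mu * L
        expect = theta * (1 + 1 / 2 + 1 / 3)
        counts = np.array([
            coalescent_segregating_sites(n_hap, L, mu, 1e-8,
                                         ne_trajectory=((0, ne),), seed=s)
            for s in range(60)], dtype=float)
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_ld_decays_with_distance(self, desk_pool):
        """Founder r^2 at 0-1 cM exceeds r^2 at 10-11 cM."""
        c0 = desk_pool.map.chrom == 0
        H = desk_pool.haplotypes[:, c0].astype(float)
        cm = desk_pool.map.cm[c0]
        freq = H.mean(axis=0)
        common = (freq > 0.1) & (freq < 0.9)
        H, cm = H[:, common], cm[common]
        rng = np.random.default_rng(0)
        pick = rng.choice(H.shape[1], size=min(250, H.shape[1]), replace=False)
        corr = np.corrcoef(H[:, pick].T) ** 2
        d = np.abs(cm[pick][:, None] - cm[pick][None, :])
        iu = np.triu_indices_from(corr, k=1)
        r2, dd = corr[iu], d[iu]
        assert np.nanmean(r2[dd < 1.0]) > np.nanmean(r2[(dd > 10) & (dd < 11)])


class TestDiscretePopulation:
    def test_structure_and_sizes(self, tiny_pool):
        pop = simulate_discrete_population(tiny_pool, 2, 60, n_qtn=30, seed=1)
        ped = pop.pedigree
        assert int(np.sum(ped.generation > 0)) == 120  # 2 x 60 genotyped
        base = ped.generation == 0
        assert np.all(ped.is_founder() == base)
        nonbase = ~base
        assert np.all(ped.sire[nonbase] != UNKNOWN)
        assert np.all(ped.dam[nonbase] != UNKNOWN)

    def test_gene_drop_conserves_parental_alleles(self, tiny_pool):
        pop = simulate_discrete_population(tiny_pool, 2, 40, n_qtn=30, seed=2)
        ped, panel = pop.pedigree, pop.haplotypes
        for i in np.flatnonzero(~ped.is_founder())[:20]:
            s = panel.alleles[ped.sire[i]]
            ok = (panel.alleles[i, :, 0] == s[:, 0]) | \
                 (panel.alleles[i, :, 0] == s[:, 1])
            assert ok.all()

    def test_selection_increases_breeding_values(self, tiny_pool):
        means = np.zeros(6)
        for seed in (1, 2, 3):
            pop = simulate_discrete_population(tiny_pool, 5, 60, n_qtn=30,
                                               seed=seed)
            for g in range(6):
                means[g] += pop.tbv[pop.pedigree.generation == g].mean()
        assert np.all(np.diff(means) > 0)

    def test_no_selection_no_trend(self, tiny_pool):
        """With 100% selection proportions the mean TBV drifts but has no
        systematic direction."""
        deltas = []
        for seed in range(6):
            pop = simulate_discrete_population(
                tiny_pool, 4, 60, sire_prop=1.0, dam_prop=1.0, n_qtn=30,
                seed=seed)
            tbv, gen = pop.tbv, pop.pedigree.generation
            deltas.append(tbv[gen == 4].mean() - tbv[gen == 1].mean())
        deltas = np.asarray(deltas)
        assert abs(deltas.mean()) < 3 * deltas.std(ddof=1) / np.sqrt(len(deltas))

    def test_invalid_selection_proportions(self, tiny_pool):
        with pytest.raises(ValueError):
            simulate_discrete_population(tiny_pool, 2, 10, sire_prop=0.01,
                                         n_qtn=10, seed=1)

    def test_same_seed_reproduces_population(self, tiny_pool):
        a = simulate_discrete_population(tiny_pool, 2, 60, n_qtn=20, seed=9)
        b = simulate_discrete_population(tiny_pool, 2, 60, n_qtn=20, seed=9)
        assert np.array_equal(a.pedigree.sire, b.pedigree.sire)
        assert np.array_equal(a.haplotypes.alleles, b.haplotypes.alleles)


class TestOverlappingPopulation:
    def test_parents_precede_progeny_and_determinism(self, tiny_pool):
        a = simulate_overlapping_population(tiny_pool, 400, n_qtn=20, seed=4)
        b = simulate_overlapping_population(tiny_pool, 400, n_qtn=20, seed=4)
        ped = a.pedigree
        nonf = ~ped.is_founder()
        assert np.all(ped.sire[nonf] < np.flatnonzero(nonf))
        assert np.array_equal(a.pedigree.sire, b.pedigree.sire)

    def test_generation_equivalent_depth_near_twenty(self, tiny_pool):
        depths = [generation_depth(
            simulate_overlapping_population(tiny_pool, 1500, n_qtn=20,
                                            seed=s).pedigree)
            for s in range(5)]
        assert 15.0 <= np.mean(depths) <= 25.0

    def test_minimum_size(self, tiny_pool):
        with pytest.raises(ValueError):
            simulate_overlapping_population(tiny_pool, 50, n_qtn=10, seed=1)


class TestGenotypingAssignment:
    def _three_generation_ped(self):
        """100 founders (gen 0), 100 gen 1, 100 gen 2 (final)."""
        ids = list(range(1, 301))
        sire, dam, gen = [], [], []
        for i in range(100):
            sire.append(None); dam.append(None); gen.append(0)
        for g in (1, 2):
            lo = (g - 1) * 100
            for i in range(100):
                sire.append(lo + 1)       # id of a male in previous gen
                dam.append(lo + 2)        # id of a female in previous gen
                gen.append(g)
        sex = (["M", "F"] * 50) * 3
        return make_pedigree(ids, sire, dam, sex=sex, generation=gen)

    def test_rates_per_group(self):
        ped = self._three_generation_ped()
        asg = assign_panels_and_genotyping(ped, seed=1)
        base = ped.generation == 0
        later = ped.generation == 1
        st = asg.status
        assert np.sum(st[base] != NOT_GENOTYPED) == 75
        assert np.sum(st[base] == HD) == 50      # round(0.67 * 75)
        assert np.sum(st[base] == LD) == 25
        assert np.sum(st[later] != NOT_GENOTYPED) == 95
        assert np.sum(st[later] == HD) == 14     # round(0.15 * 95)
        assert np.sum(st[later] == LD) == 81

    def test_hd_prioritises_big_contributors_outside_final_generation(self):
        ped = self._three_generation_ped()
        prog, grand = count_progeny(ped)
        big = prog + grand
        for seed in range(5):
            asg = assign_panels_and_genotyping(ped, seed=seed)
            mid = ped.generation == 1
            geno_mid = mid & (asg.status != NOT_GENOTYPED)
            childless = geno_mid & (big == 0)
            producers = geno_mid & (big >= 10)
            if childless.any() and producers.any():
                # no childless individual gets HD while a 10+-grandprogeny
                # producer is stuck on LD
                if np.any(asg.status[childless] == HD):
                    assert np.all(asg.status[producers] == HD)

    def test_array_calls_masking(self, tiny_pool):
        pop = simulate_discrete_population(tiny_pool, 2, 40, n_qtn=20, seed=3)
        asg = assign_panels_and_genotyping(pop.pedigree, seed=2)
        calls = array_calls(pop.haplotypes, asg)
        st = asg.status
        panel = pop.haplotypes
        assert np.all(calls[st == NOT_GENOTYPED] == -1)
        ld_rows = calls[st == LD]
        assert np.all(ld_rows[:, ~panel.is_ld] == -1)
        hd_rows = calls[st == HD]
        assert np.all(hd_rows[:, panel.is_hd] >= 0)
        obs = calls[st == HD][:, panel.is_hd]
        truth = panel.genotypes()[st == HD][:, panel.is_hd]
        assert np.array_equal(obs, truth)


class TestPersistence:
    def test_hdf5_roundtrip(self, tiny_pool, tmp_path):
        from peelsim.simulate import load_panel, save_panel
        pop = simulate_discrete_population(tiny_pool, 2, 40, n_qtn=20, seed=8)
        path = tmp_path / "panel.h5"
        save_panel(pop.haplotypes, path)
        again = load_panel(path)
        assert np.array_equal(again.alleles, pop.haplotypes.alleles)
        assert np.array_equal(again.is_ld, pop.haplotypes.is_ld)
        assert np.allclose(again.map.cm, pop.haplotypes.map.cm)

    def test_vcf_export_parses_and_matches(self, tiny_pool, tmp_path):
        from cyvcf2 import VCF
        from peelsim.simulate import panel_to_vcf
        pop = simulate_discrete_population(tiny_pool, 2, 40, n_qtn=20, seed=8)
        path = str(tmp_path / "truth.vcf")
        panel_to_vcf(pop.haplotypes, path)
        vcf = VCF(path)
        var = next(iter(vcf))
        gt = np.array(var.genotypes)
        assert np.array_equal(gt[:, 0], pop.haplotypes.alleles[:, 0, 0])
        assert np.array_equal(gt[:, 1], pop.haplotypes.alleles[:, 0, 1])
        assert bool(gt[:, 2].all())  # phased
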