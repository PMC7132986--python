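import numpy as np
import pytest

from peelsim.budget import plan_from_histogram, sequencing_cost
from peelsim.pedigree import additive_matrix, make_pedigree
from peelsim.simulate import (GeneticMap, HaplotypePanel,
                              assign_panels_and_genotyping,
                              simulate_discrete_population)
from peelsim.strategies import (
    _marginal_contributions, alphaseqopt_like, combined, concentrated_plan,
    key_ancestors, ped_gen_rel, random_plans, top_sires_and_dams,
    uniform_sweep_plan, uniformize,
)


def _breeding_ped(n_sires=2, progeny_per_sire=(10, 2)):
    """Sires with different progeny counts, one dam each."""
    ids, sire, dam, sex = [], [], [], []
    nid = 0
    for k, np_ in enumerate(progeny_per_sire):
        for lab, sx in ((f"s{k}", "M"), (f"d{k}", "F")):
            ids.append(lab); sire.append(None); dam.append(None); sex.append(sx)
        for j in range(np_):
            ids.append(f"c{k}_{j}"); sire.append(f"s{k}")
            dam.append(f"d{k}"); sex.append("M" if j % 2 else "F")
    return make_pedigree(ids, sire, dam, sex=sex)


class TestTopSiresAndDams:
    def test_budget_split_and_floor_arithmetic(self):
        ped = _breeding_ped(progeny_per_sire=(6, 6, 6, 6, 6, 6))
        geno = np.ones(ped.n, dtype=bool)
        plan = top_sires_and_dams(ped, geno, budget=1000.0)
        hist = plan.histogram()
        # 500 MU per sex: 2 sires at 2x (400), 4 dams at 1x (480)
        assert hist == {2.0: 2, 1.0: 4}
        assert plan.cost() <= 1000.0

    def test_bigger_sire_ranked_first(self):
        ped = _breeding_ped(progeny_per_sire=(10, 2))
        geno = np.ones(ped.n, dtype=bool)
        plan = top_sires_and_dams(ped, geno, budget=520.0)  # 1 sire + 1 dam
        s0 = int(np.flatnonzero(ped.ids == "s0")[0])
        s1 = int(np.flatnonzero(ped.ids == "s1")[0])
        assert plan.coverage[s0] == 2.0 and plan.coverage[s1] == 0.0

    def test_tie_breaks_by_pedigree_position(self):
        ped = _breeding_ped(progeny_per_sire=(4, 4))
        geno = np.ones(ped.n, dtype=bool)
        plan = top_sires_and_dams(ped, geno, budget=520.0)
        first_sire = int(np.flatnonzero(ped.sex == 0)[0])
        assert plan.coverage[first_sire] == 2.0

    def test_budget_too_small(self):
        ped = _breeding_ped()
        with pytest.raises(ValueError):
            top_sires_and_dams(ped, np.ones(ped.n, dtype=bool), budget=300.0)


class TestKeyAncestors:
    def test_star_sire_selected_first(self):
        ids = ["s"] + [f"d{i}" for i in range(20)] + [f"c{i}" for i in range(20)]
        sire = [None] * 21 + ["s"] * 20
        dam = [None] * 21 + [f"d{i}" for i in range(20)]
        sex = ["M"] + ["F"] * 20 + ["M"] * 20
        ped = make_pedigree(ids, sire, dam, sex=sex)
        plan = key_ancestors(ped, budget=500.0)
        s = int(np.flatnonzero(ped.ids == "s")[0])
        assert plan.coverage[s] == 15.0

    def test_count_follows_floor_of_budget(self):
        ped = _breeding_ped(progeny_per_sire=(5, 5))
        plan = key_ancestors(ped, budget=1000.0)
        assert plan.n_sequenced == 2

    def test_grandsire_blocked_after_only_son(self):
        # grandsire g -> son s (only child) -> grandchildren
        ids = ["g", "gd", "s", "d", "c1", "c2"]
        sire = [None, None, "g", None, "s", "s"]
        dam = [None, None, "gd", None, "d", "d"]
        sex = ["M", "F", "M", "F", "M", "F"]
        ped = make_pedigree(ids, sire, dam, sex=sex)
        sel = np.zeros(ped.n, dtype=bool)
        sel[int(np.flatnonzero(ped.ids == "s")[0])] = True
        contrib = _marginal_contributions(ped, sel)
        g = int(np.flatnonzero(ped.ids == "g")[0])
        # g's only descent path runs through the selected son: blocked,
        # and the contribution to the son itself does not count
        assert contrib[g] == pytest.approx(0.0)


class TestPedGenRel:
    def test_unrelated_founders_identity_score(self):
        ped = make_pedigree(list(range(1, 6)), [None] * 5, [None] * 5)
        plan = ped_gen_rel(ped, budget=1000.0)
        # a_s = 0 everywhere, so the first pick is position 0 by tie-break
        assert plan.coverage[0] == 15.0 and plan.n_sequenced == 2

    def test_first_pick_is_argmax_average_relationship(self, two_family_ped):
        plan = ped_gen_rel(two_family_ped, budget=500.0)
        A = additive_matrix(two_family_ped)
        a = (A.sum(axis=1) - np.diag(A)) / (A.shape[0] - 1)
        assert plan.coverage[int(np.argmax(a))] == 15.0

    def test_matches_brute_force_greedy(self, two_family_ped):
        """The stepwise pick order equals an independent dense-matrix greedy
        evaluation of the score over all candidates at each step."""
        n = two_family_ped.n
        A = additive_matrix(two_family_ped)
        rowsum = A.sum(axis=1)
        sel: list[int] = []
        a_all = (rowsum - np.diag(A)) / (n - 1)
        sel.append(int(np.argmax(a_all)))
        while len(sel) < 3:
            best, best_score = None, -np.inf
            for c in range(n):
                if c in sel:
                    continue
                sub = sel + [c]
                A_s = A[np.ix_(sub, sub)]
                a_s = np.array([(rowsum[i] - A[i, sub].sum()) / (n - len(sub))
                                for i in sub])
                score = float(np.ones(len(sub)) @ np.linalg.inv(A_s) @ a_s)
                if score > best_score:
                    best, best_score = c, score
            sel.append(best)
        plan = ped_gen_rel(two_family_ped, budget=1500.0)
        assert list(plan.order) == sel

    def test_redundant_relative_not_preferred(self, two_family_ped):
        """After selecting one full sib, the other full sib (identical
        relationship profile) scores no better than the other family's
        representative."""
        plan = ped_gen_rel(two_family_ped, budget=1000.0)
        picked = set(plan.order)
        assert picked != {2, 3}  # never both full sibs first


def _toy_panel(rng, n, n_loci=40, n_chr=2):
    per = n_loci // n_chr
    gmap = GeneticMap(chrom=np.repeat(np.arange(n_chr), per),
                      bp=np.tile(np.arange(per) * 1000.0, n_chr),
                      cm=np.tile(np.linspace(0.1, 50.0, per), n_chr))
    alleles = rng.integers(0, 2, size=(n, n_loci, 2), dtype=np.int8)
    is_hd = np.ones(n_loci, dtype=bool)
    is_ld = np.zeros(n_loci, dtype=bool)
    is_ld[::10] = True
    return HaplotypePanel(alleles=alleles, map=gmap, is_hd=is_hd, is_ld=is_ld)


class TestAlphaSeqOptLike:
    def test_carrier_of_top_haplotypes_is_first_focal(self):
        rng = np.random.default_rng(0)
        n = 30
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n,
                            sex=["M", "F"] * 15)
        panel = _toy_panel(rng, n)
        # individual 0 carries the two most frequent haplotypes everywhere:
        # copy the two commonest rows into it
        panel.alleles[0, :, 0] = panel.alleles[1, :, 0]
        panel.alleles[0, :, 1] = panel.alleles[2, :, 0]
        for i in range(3, 12):  # make those haplotypes genuinely common
            panel.alleles[i, :, 0] = panel.alleles[1, :, 0]
            panel.alleles[i, :, 1] = panel.alleles[2, :, 0]
        plan = alphaseqopt_like(ped, panel, budget=2800.0, window_size=10)
        assert plan.order[0] in {0, 1, 3}  # a carrier of the common pair
        assert plan.coverage[plan.order[0]] > 0

    def test_stage2_budget_buys_1x_individuals(self):
        rng = np.random.default_rng(1)
        n = 40
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n,
                            sex=["M", "F"] * 20)
        panel = _toy_panel(rng, n)
        # budget 2400: stage 1 gets 1200 (< 1400 -> no family), stage 2
        # gets 1200 -> exactly 10 individuals at 1x
        plan = alphaseqopt_like(ped, panel, budget=2400.0, window_size=10)
        assert plan.histogram() == {1.0: 10}

    def test_under_covered_windows_non_increasing(self):
        from peelsim.strategies import _window_haplotypes
        rng = np.random.default_rng(2)
        n = 40
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n,
                            sex=["M", "F"] * 20)
        panel = _toy_panel(rng, n)
        codes, freqs = _window_haplotypes(panel, 10)

        def n_under(cov):
            cnt = 0
            for w in range(codes.shape[1]):
                cum: dict[int, float] = {}
                for i in np.flatnonzero(cov > 0):
                    for h in codes[i, w]:
                        cum[int(h)] = cum.get(int(h), 0.0) + cov[i]
                all_h = {int(h) for i in range(n) for h in codes[i, w]}
                cnt += sum(1 for h in all_h if cum.get(h, 0.0) < 10.0)
            return cnt

        before = alphaseqopt_like(ped, panel, budget=5600.0, window_size=10)
        cov_stage1 = before.coverage.copy()
        cov_stage1[[i for i in before.order
                    if before.coverage[i] == 1.0]] = 0.0  # undo stage-2 1x
        assert n_under(before.coverage) <= n_under(cov_stage1)


@pytest.fixture(scope="module")
def small_pop(tiny_pool):
    pop = simulate_discrete_population(tiny_pool, 3, 60, n_qtn=30, seed=6)
    asg = assign_panels_and_genotyping(pop.pedigree, seed=6)
    return pop, asg


class TestCombinedAndControls:
    def test_combined_within_budget_and_overlap_max_rule(self, small_pop):
        pop, asg = small_pop
        plan = combined(pop.pedigree, pop.haplotypes, asg.genotyped(),
                        budget=8000.0, window_size=10)
        assert plan.cost() <= 8000.0
        assert plan.n_sequenced > 0

    def test_random_var_replicates_histogram(self, small_pop):
        pop, _ = small_pop
        hist = {15.0: 2, 2.0: 5, 1.0: 7}
        plan = random_plans(pop.pedigree, budget=4000.0, mode="variable",
                            reference_histogram=hist, seed=3)
        assert plan.histogram() == hist

    def test_random_unif_counts_and_determinism(self, small_pop):
        pop, _ = small_pop
        a = random_plans(pop.pedigree, budget=10_000.0, seed=5)
        b = random_plans(pop.pedigree, budget=10_000.0, seed=5)
        assert a.histogram() == {2.0: 50}
        assert np.array_equal(a.coverage, b.coverage)

    def test_random_draws_exceeding_population(self):
        ped = make_pedigree([1, 2], [None] * 2, [None] * 2)
        with pytest.raises(ValueError):
            random_plans(ped, budget=10_000.0, seed=1)

    def test_all_plans_respect_budget(self, small_pop):
        pop, asg = small_pop
        ped, panel = pop.pedigree, pop.haplotypes
        budget = 6000.0
        plans = [
            top_sires_and_dams(ped, asg.genotyped(), budget),
            key_ancestors(ped, budget),
            ped_gen_rel(ped, budget),
            alphaseqopt_like(ped, panel, budget, window_size=10),
            combined(ped, panel, asg.genotyped(), budget, window_size=10),
            random_plans(ped, budget, seed=1),
            uniform_sweep_plan(ped, budget, 0.5, seed=1),
        ]
        for plan in plans:
            assert plan.cost() <= budget + 1e-9, plan.method


class TestConcentratedAndSweep:
    def test_decile_bounds(self, small_pop_ped=None):
        n = 1000
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n)
        plan = concentrated_plan(ped, budget=20_000.0, decile=(0.4, 0.5),
                                 seed=2)
        assert plan.n_sequenced == 100
        assert np.all((plan.sequenced >= 400) & (plan.sequenced < 500))

    def test_generation_filter(self, tiny_pool):
        pop = simulate_discrete_population(tiny_pool, 3, 60, n_qtn=30, seed=7)
        plan = concentrated_plan(pop.pedigree, budget=4000.0, generation=2,
                                 seed=2)
        assert np.all(pop.pedigree.generation[plan.sequenced] == 2)

    def test_range_too_small(self):
        ped = make_pedigree(list(range(1, 51)), [None] * 50, [None] * 50)
        with pytest.raises(ValueError):
            concentrated_plan(ped, budget=20_000.0, decile=(0.0, 0.1), seed=1)

    @pytest.mark.parametrize("x,expected", [(0.25, 2500), (5.0, 340)])
    def test_sweep_counts(self, x, expected):
        n = 3000
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n)
        plan = uniform_sweep_plan(ped, budget=150_000.0, x=x, seed=1)
        assert plan.n_sequenced == expected

    def test_sweep_at_2x_matches_random_uniform_count(self):
        n = 500
        ped = make_pedigree(list(range(1, n + 1)), [None] * n, [None] * n)
        a = uniform_sweep_plan(ped, budget=30_000.0, x=2.0, seed=1)
        b = random_plans(ped, budget=30_000.0, mode="uniform", seed=1)
        assert a.n_sequenced == b.n_sequenced == 150


class TestUniformize:
    @pytest.mark.parametrize("hist,n,xbar,inv_u,x_eq,n2", [
        ({1.0: 632, 2.0: 182, 5.0: 3, 15.0: 50, 30.0: 10},
         877, 2.35, 199_960.0, 1.60, 735),
        ({1.0: 1245, 2.0: 281, 5.0: 9, 15.0: 76, 30.0: 31},
         1642, 2.39, 379_440.0, 1.59, 1369),
        ({1.0: 2711, 2.0: 773, 5.0: 37, 15.0: 156, 30.0: 65},
         3742, 2.33, 848_240.0, 1.60, 3147),
    ])
    def test_reference_plan_columns(self, hist, n, xbar, inv_u, x_eq, n2):
        plan = plan_from_histogram(hist, n=4000)
        r1 = uniformize(plan, "equal_total_coverage")
        assert r1.n_sequenced == n
        assert round(r1.coverage, 2) == xbar
        assert r1.investment == inv_u
        r2 = uniformize(plan, "equal_investment")
        assert round(r2.coverage, 2) == x_eq
        r3 = uniformize(plan, "fixed_2x")
        assert r3.n_sequenced == n2

    def test_uniform_plan_is_fixed_point(self):
        plan = plan_from_histogram({2.0: 100}, n=200)
        r1 = uniformize(plan, "equal_total_coverage")
        r2 = uniformize(plan, "equal_investment")
        r3 = uniformize(plan, "fixed_2x")
        for r in (r1, r2, r3):
            assert r.n_sequenced == 100
            assert r.coverage == pytest.approx(2.0)

    def test_empty_plan_rejected(self):
        from peelsim.budget import SequencingPlan
        empty = SequencingPlan(np.zeros(10), budget=0.0)
        with pytest.raises(ValueError):
            uniformize(empty, "equal_total_coverage")
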