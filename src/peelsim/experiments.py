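"""Scenario runner: end-to-end pipelines and the four experiment grids.

A scenario is: simulate (or reuse) a pedigreed population with genomes and
marker data -> allocate a sequencing budget to individuals with one of the
selection strategies -> simulate reads -> impute everybody by hybrid
peeling -> score MAF-corrected imputation accuracy.  Everything is
deterministic given the scenario seed: one root seed spawns named child
streams (founders, pedigree, genotyping, plan, sequenceability, reads,
evaluation loci).

The grids reproduce, at desk scale, the study designs: pedigree structure
x investment (``structure``), selection method x investment (``test1``),
generation concentration (``test2``), variable vs uniform coverage
(``test3``) and the number-vs-coverage trade-off (``test4``).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import strategies
from .accuracy import AccuracyReport, accuracy, apply_exclusions
from .budget import (MIN_INVESTMENT, SequencingPlan, investment_budget,
                     plan_cost)
from .peeling import (array_to_penetrance, combine_penetrance, dosages,
                      hybrid_peel, multi_locus_peel, reads_to_penetrance)
from .reads import sample_sequenceability, simulate_reads
from .simulate import (DeskScale, FounderPool, Population, array_calls,
                       assign_panels_and_genotyping,
                       simulate_discrete_population,
                       simulate_overlapping_population)

_STREAMS = ("founders", "pedigree", "genotyping", "plan",
            "sequenceability", "reads", "eval_loci")


def _child_seeds(root_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(_STREAMS, children)}


@dataclass
class ScenarioConfig:
    """Everything needed to run one scenario deterministically."""

    population: str = "discrete"        # "discrete" | "overlapping"
    n_generations: int = 10
    generation_size: int = 250
    n_individuals: int = 2000           # overlapping pedigrees only
    investment_fraction: float | None = 0.02
    budget: float | None = None         # explicit budget overrides fraction
    method: str = "Combined"
    method_params: dict = field(default_factory=dict)
    n_eval_loci: int = 300
    err_seq: float = 0.001
    err_array: float = 0.01
    multi_iters: int = 8
    hybrid_iters: int = 6
    #: convergence tolerance and float precision of the scenario peels;
    #: single precision with a 1e-4 genotype-probability tolerance is far
    #: below the Monte-Carlo noise of any scenario comparison
    peel_tol: float = 1e-4
    peel_dtype: str = "float32"
    exclusion: str = "auto"             # "auto" | "discrete" | "overlapping" | "none"
    enforce_min_investment: bool = True
    seed: int = 0
    scale: DeskScale = field(default_factory=DeskScale)

    def describe(self) -> dict:
        d = asdict(self)
        d["scale"] = asdict(self.scale)
        return d


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    plan: SequencingPlan | None
    report: AccuracyReport | None
    population_size: int
    investment: float
    skipped: bool = False
    reason: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def mean_corrected(self) -> float:
        return self.report.mean_corrected if self.report else np.nan

    @property
    def mean_raw(self) -> float:
        return self.report.mean_raw if self.report else np.nan


def simulate_population(cfg: ScenarioConfig, pool: FounderPool | None = None
                        ) -> tuple[Population, FounderPool]:
    seeds = _child_seeds(cfg.seed)
    if pool is None:
        pool = cfg.scale.founder_pool(seed=seeds["founders"])
    if cfg.population == "discrete":
        pop = simulate_discrete_population(
            pool, cfg.n_generations, cfg.generation_size,
            n_qtn=cfg.scale.n_qtn, h2=cfg.scale.h2, seed=seeds["pedigree"])
    elif cfg.population == "overlapping":
        pop = simulate_overlapping_population(
            pool, cfg.n_individuals, n_qtn=cfg.scale.n_qtn, h2=cfg.scale.h2,
            seed=seeds["pedigree"])
    else:
        raise ValueError(f"unknown population kind {cfg.population!r}")
    return pop, pool


def population_size_for_investment(cfg: ScenarioConfig, pop: Population) -> int:
    """Size used for the investment levels: the genotyped generations of a
    discrete pedigree (depth x generation size, excluding the base
    parents), or the whole overlapping pedigree."""
    if cfg.population == "discrete":
        return int(np.sum(pop.pedigree.generation > 0))
    return pop.pedigree.n


def build_plan(cfg: ScenarioConfig, pop: Population, genotyped: np.ndarray,
               budget: float) -> SequencingPlan:
    """Dispatch to the configured selection strategy."""
    seeds = _child_seeds(cfg.seed)
    ped, panel = pop.pedigree, pop.haplotypes
    m, prm = cfg.method, cfg.method_params
    if m == "TopSiresAndDams":
        return strategies.top_sires_and_dams(ped, genotyped, budget)
    if m == "KeyAncestors":
        return strategies.key_ancestors(ped, budget)
    if m == "PedGenRel":
        return strategies.ped_gen_rel(ped, budget)
    if m == "AlphaSeqOptLike":
        return strategies.alphaseqopt_like(ped, panel, budget, **prm)
    if m == "Combined":
        return strategies.combined(ped, panel, genotyped, budget, **prm)
    if m == "RandomUnif":
        return strategies.random_plans(ped, budget, mode="uniform",
                                       seed=seeds["plan"])
    if m == "RandomVar":
        hist = prm.get("reference_histogram")
        if hist is None:
            hist = strategies.combined(ped, panel, genotyped, budget
                                       ).histogram()
        return strategies.random_plans(ped, budget, mode="variable",
                                       reference_histogram=hist,
                                       seed=seeds["plan"])
    if m == "Concentrated":
        return strategies.concentrated_plan(ped, budget, seed=seeds["plan"],
                                            **prm)
    if m == "UniformSweep":
        return strategies.uniform_sweep_plan(ped, budget, prm["x"],
                                             seed=seeds["plan"])
    if m.startswith("Combined+"):  # uniformized variants, Test 3
        base = strategies.combined(ped, panel, genotyped, budget)
        mode = m.split("+", 1)[1]
        return strategies.uniformize(base, mode).plan
    raise ValueError(f"unknown method {m!r}")


def impute(cfg: ScenarioConfig, pop: Population, plan: SequencingPlan,
           assignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hybrid-peeling imputation at a random subset of SEQ loci.

    Returns (eval locus indices, truth genotypes at those loci, imputed
    dosages at those loci).
    """
    seeds = _child_seeds(cfg.seed)
    ped, panel = pop.pedigree, pop.haplotypes
    gmap = panel.map
    rng = np.random.default_rng(seeds["eval_loci"])
    n_eval = min(cfg.n_eval_loci, panel.n_loci)
    eval_loci = np.sort(rng.choice(panel.n_loci, size=n_eval, replace=False))

    calls = array_calls(panel, assignment)

    s = sample_sequenceability(n_eval, seed=seeds["sequenceability"])
    reads = simulate_reads(plan, panel.alleles[:, eval_loci, :], s,
                           seed=seeds["reads"])
    pen_reads = reads_to_penetrance(reads.n_alt, reads.n_ref, err=cfg.err_seq)

    dos = np.empty((ped.n, n_eval))
    eval_chrom = gmap.chrom[eval_loci]
    for c in gmap.chromosomes():
        hd = np.flatnonzero(panel.is_hd & (gmap.chrom == c))
        pen_hd = array_to_penetrance(calls[:, hd], err=cfg.err_array)
        seg = multi_locus_peel(ped, pen_hd, gmap.cm[hd],
                               n_iter=cfg.multi_iters, tol=cfg.peel_tol,
                               dtype=cfg.peel_dtype)
        sel = np.flatnonzero(eval_chrom == c)
        if sel.size == 0:
            continue
        loci = eval_loci[sel]
        pen = combine_penetrance(
            pen_reads[:, sel, :],
            array_to_penetrance(calls[:, loci], err=cfg.err_array))
        state = hybrid_peel(ped, pen, seg, gmap.cm[loci],
                            n_iter=cfg.hybrid_iters, tol=cfg.peel_tol,
                            dtype=cfg.peel_dtype)
        dos[:, sel] = dosages(state)
    truth = panel.genotypes()[:, eval_loci]
    return eval_loci, truth, dos


def run_scenario(cfg: ScenarioConfig, pool: FounderPool | None = None,
                 population: Population | None = None,
                 out_dir=None) -> ScenarioResult:
    """Run one scenario end to end; deterministic given ``cfg.seed``.

    A pre-simulated founder pool and/or population may be supplied to share
    them across scenarios (paired comparisons).  With ``out_dir`` the plan,
    the per-individual accuracies, a one-line summary and a provenance
    record (config hash, seeds, version) are written as CSV/JSON."""
    t0 = time.time()
    if population is None:
        population, pool = simulate_population(cfg, pool)
    pop = population
    pop_size = population_size_for_investment(cfg, pop)
    if cfg.budget is not None:
        budget = float(cfg.budget)
    else:
        budget = investment_budget(pop_size, cfg.investment_fraction)
    if cfg.enforce_min_investment and budget < MIN_INVESTMENT:
        return ScenarioResult(cfg, None, None, pop_size, budget, skipped=True,
                              reason=f"investment {budget:.0f} MU below "
                                     f"{MIN_INVESTMENT:.0f} MU")
    seeds = _child_seeds(cfg.seed)
    assignment = assign_panels_and_genotyping(pop.pedigree,
                                              seed=seeds["genotyping"])
    plan = build_plan(cfg, pop, assignment.genotyped(), budget)
    _, truth, dos = impute(cfg, pop, plan, assignment)
    mode = cfg.exclusion
    if mode == "auto":
        mode = cfg.population
    excl = apply_exclusions(pop.pedigree, mode)
    p = truth.mean(axis=0) / 2.0
    report = accuracy(truth, dos, p, excluded=excl)
    desc = cfg.describe()
    prov = {"seeds": seeds, "config": desc,
            "config_hash": hashlib.sha256(
                json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16],
            "plan_cost": plan_cost(plan), "runtime_s": time.time() - t0}
    result = ScenarioResult(cfg, plan, report, pop_size, budget,
                            provenance=prov)
    if out_dir is not None:
        _write_scenario(result, Path(out_dir))
    return result


def _write_scenario(res: ScenarioResult, out_dir: Path) -> None:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    res.plan.to_csv(out_dir / "plan.csv")
    res.report.to_frame().to_csv(out_dir / "accuracy.csv", index=False)
    pd.DataFrame([_result_row(res)]).to_csv(out_dir / "summary.csv",
                                            index=False)
    prov = dict(res.provenance)
    prov.pop("runtime_s", None)  # keep the record reproducible
    prov["version"] = __version__
    (out_dir / "provenance.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# grids and trend runs
# ---------------------------------------------------------------------------

def _result_row(res: ScenarioResult, **extra) -> dict:
    row = {"method": res.config.method, "seed": res.config.seed,
           "population_size": res.population_size,
           "investment": res.investment,
           "skipped": res.skipped,
           "n_sequenced": res.plan.n_sequenced if res.plan else 0,
           "plan_cost": plan_cost(res.plan) if res.plan else 0.0,
           "mean_corrected": res.mean_corrected,
           "mean_raw": res.mean_raw}
    row.update(extra)
    return row


def run_grid(test_id: str, seeds=(1, 2), scale: DeskScale | None = None,
             pool: FounderPool | None = None, verbose: bool = False,
             **overrides) -> pd.DataFrame:
    """Run one of the experiment grids at desk scale; returns a tidy table
    with one row per scenario x replicate (aggregate with
    :func:`aggregate_grid`).  Extra keyword arguments override the
    :class:`ScenarioConfig` defaults of every grid cell (e.g. a smaller
    ``generation_size`` for a quick look)."""
    scale = scale or DeskScale()
    rows = []
    if pool is None:
        pool = scale.founder_pool(seed=20_000 + 7)

    def _run(extra, **cfg_kw):
        kw = dict(scale=scale)
        kw.update(cfg_kw)
        kw.update(overrides)
        res = run_scenario(ScenarioConfig(**kw), pool=pool)
        rows.append(_result_row(res, test=test_id, **extra))
        if verbose:
            print(f"{test_id} {extra} seed={kw.get('seed')}: "
                  + (f"acc={res.mean_corrected:.3f}" if not res.skipped
                     else f"skipped: {res.reason}"))

    if test_id == "structure":
        for depth in (2, 5, 10):
            for frac in (0.02, 0.05):
                for s in seeds:
                    _run({"depth": depth, "fraction": frac},
                         n_generations=depth, investment_fraction=frac,
                         method="Combined", exclusion="none", seed=s)
    elif test_id == "test1":
        methods = ("TopSiresAndDams", "KeyAncestors", "PedGenRel",
                   "AlphaSeqOptLike", "Combined", "RandomVar", "RandomUnif")
        for m in methods:
            for frac in (0.02, 0.05):
                for s in seeds:
                    _run({"fraction": frac}, method=m,
                         investment_fraction=frac, seed=s)
    elif test_id == "test2":
        for gen in (1, 3, 5, 8):
            for s in seeds:
                _run({"target_generation": gen}, method="Concentrated",
                     method_params={"generation": gen},
                     investment_fraction=0.05, seed=s)
    elif test_id == "test3":
        for m in ("Combined", "Combined+equal_total_coverage",
                  "Combined+equal_investment", "Combined+fixed_2x"):
            for s in seeds:
                _run({}, method=m, investment_fraction=0.05, seed=s)
    elif test_id == "test4":
        for x in (0.25, 0.5, 1, 2, 3, 4, 5):
            for s in seeds:
                _run({"coverage": x}, method="UniformSweep",
                     method_params={"x": float(x)},
                     investment_fraction=0.02, seed=s)
    else:
        raise ValueError(f"unknown test id {test_id!r}")
    return pd.DataFrame(rows)


def aggregate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Average the replicate rows of a grid table."""
    keys = [c for c in df.columns
            if c not in ("seed", "mean_corrected", "mean_raw", "n_sequenced",
                         "plan_cost")]
    return (df.groupby(keys, dropna=False)
            [["mean_corrected", "mean_raw", "n_sequenced"]]
            .mean().reset_index())


# -- trend runs (scaled-down analogues of the headline comparisons) --------

def depth_trend(seeds=(1, 2, 3), depths=(2, 5, 10), generation_size=200,
                fraction=0.05, scale: DeskScale | None = None,
                pool: FounderPool | None = None) -> pd.DataFrame:
    """Mean population-wide accuracy by pedigree depth at a fixed
    investment fraction (no exclusions, as in the structure comparison)."""
    scale = scale or DeskScale()
    if pool is None:
        pool = scale.founder_pool(seed=101)
    rows = []
    for depth in depths:
        for s in seeds:
            cfg = ScenarioConfig(n_generations=depth,
                                 generation_size=generation_size,
                                 investment_fraction=fraction,
                                 method="Combined", exclusion="none",
                                 enforce_min_investment=False,
                                 seed=s, scale=scale)
            res = run_scenario(cfg, pool=pool)
            rows.append(_result_row(res, depth=depth))
    return pd.DataFrame(rows)


def concentration_contrast(seeds=(1, 2, 3), generations=(1, 5),
                           generation_size=200, n_generations=10,
                           fraction=0.05, scale: DeskScale | None = None,
                           pool: FounderPool | None = None) -> pd.DataFrame:
    """Population accuracy when all sequencing is concentrated in a single
    generation (early vs mid-pedigree), evaluated from generation 4 on."""
    scale = scale or DeskScale()
    if pool is None:
        pool = scale.founder_pool(seed=101)
    rows = []
    for s in seeds:
        pop = None
        for gen in generations:
            cfg = ScenarioConfig(n_generations=n_generations,
                                 generation_size=generation_size,
                                 method="Concentrated",
                                 method_params={"generation": gen},
                                 investment_fraction=fraction,
                                 enforce_min_investment=False,
                                 seed=s, scale=scale)
            if pop is None:
                pop, _ = simulate_population(cfg, pool)
            res = run_scenario(cfg, pool=pool, population=pop)
            rows.append(_result_row(res, target_generation=gen))
    return pd.DataFrame(rows)


def coverage_sweep_trend(seeds=(1, 2, 3), coverages=(0.25, 2.0, 5.0),
                         generation_size=250, n_generations=10,
                         fraction=0.02, scale: DeskScale | None = None,
                         pool: FounderPool | None = None) -> pd.DataFrame:
    """Population accuracy for random sequencing at a uniform coverage,
    at the lowest admissible investment level (number of individuals vs
    coverage trade-off)."""
    scale = scale or DeskScale()
    if pool is None:
        pool = scale.founder_pool(seed=101)
    rows = []
    for s in seeds:
        pop = None
        for x in coverages:
            cfg = ScenarioConfig(n_generations=n_generations,
                                 generation_size=generation_size,
                                 method="UniformSweep",
                                 method_params={"x": float(x)},
                                 investment_fraction=fraction,
                                 seed=s, scale=scale)
            if pop is None:
                pop, _ = simulate_population(cfg, pool)
            res = run_scenario(cfg, pool=pool, population=pop)
            rows.append(_result_row(res, coverage=x))
    return pd.DataFrame(rows)
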