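"""Methods for choosing whom to sequence and at what coverage.

Seven selection methods are implemented, plus the plan transforms used to
study generation concentration, variable-vs-uniform coverage and the
number-vs-coverage trade-off:

* ``top_sires_and_dams`` — rank parents by genotyped progeny +
  grandprogeny; half the budget on top sires at 2x, half on top dams at 1x.
* ``key_ancestors`` — greedily pick the individuals with the largest
  marginal expected genetic contribution to the population, paths through
  already-selected individuals being blocked; sequenced at 15x.
* ``ped_gen_rel`` — stepwise maximization of the pedigree relationship
  between the sequenced set and the rest of the population, score
  1' A_s^{-1} a_s; sequenced at 15x.
* ``alphaseqopt_like`` — a two-stage haplotype-coverage heuristic: stage 1
  sequences "focal" families whose window haplotypes represent a large
  share of the population at variable coverage; stage 2 tops up carriers
  of under-covered haplotypes at 1x.  This is a simplified stand-in for
  the published two-part haplotype optimiser, keeping its budget structure
  and qualitative behaviour rather than its exact algorithm.
* ``combined`` — quarter-budget union of top sires (2x), top dams (1x),
  stage 1 and stage 2; on overlap the maximum coverage wins and the
  cheaper pick's cost stays in that sub-plan's pool.
* ``random_plans`` — random individuals, either replicating a reference
  coverage histogram (variable) or uniformly at 2x.
* ``concentrated_plan`` / ``uniform_sweep_plan`` / ``uniformize`` — the
  plan transforms behind the concentration, uniform-coverage and
  coverage-sweep experiments.

Ties are always broken by ascending pedigree position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .budget import SequencingPlan, sequencing_cost, n_affordable
from .pedigree import Pedigree, MALE, FEMALE, UNKNOWN, count_progeny, additive_matrix
from .simulate import HaplotypePanel

_ASO_LADDER = (0.0, 1.0, 2.0, 5.0, 15.0, 30.0)
_FAMILY_COST = 1400.0  # seven members at 2x
_HIGH_COVERAGE = 15.0  # key-ancestor style sequencing


def _ranked(score: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Candidates sorted by descending score, ties by ascending position."""
    order = np.lexsort((candidates, -score[candidates]))
    return candidates[order]


def _plan(coverage, budget, method, order=None) -> SequencingPlan:
    plan = SequencingPlan(coverage, budget=budget, method=method)
    plan.order = np.asarray(order, dtype=np.int64) if order is not None else \
        plan.sequenced
    return plan


# ---------------------------------------------------------------------------
# pedigree-based methods
# ---------------------------------------------------------------------------

def top_sires_and_dams(ped: Pedigree, genotyped: np.ndarray, budget: float,
                       sire_x: float = 2.0, dam_x: float = 1.0
                       ) -> SequencingPlan:
    """Sequence the sires (dams) with the most genotyped progeny and
    grandprogeny, splitting the investment equally between the two sexes;
    sires at 2x, dams at 1x."""
    if np.any(ped.sex == -1):
        raise ValueError("pedigree sexes must be known")
    prog, grand = count_progeny(ped, genotyped)
    score = (prog + grand).astype(float)
    is_parent = prog + grand >= 0  # all candidates; ranking does the work
    sires = np.flatnonzero((ped.sex == MALE) & is_parent)
    dams = np.flatnonzero((ped.sex == FEMALE) & is_parent)
    half = budget / 2.0
    n_s = min(int(half // sequencing_cost(sire_x)), sires.size)
    n_d = min(int(half // sequencing_cost(dam_x)), dams.size)
    if n_s < 1 or n_d < 1:
        raise ValueError("budget cannot afford one sire and one dam")
    top_s = _ranked(score, sires)[:n_s]
    top_d = _ranked(score, dams)[:n_d]
    cov = np.zeros(ped.n)
    cov[top_s] = sire_x
    cov[top_d] = dam_x
    return _plan(cov, budget, "TopSiresAndDams",
                 order=np.concatenate([top_s, top_d]))


def _marginal_contributions(ped: Pedigree, selected: np.ndarray) -> np.ndarray:
    """Expected marginal genetic contribution of every individual to the
    rest of the population, with descent paths through already-selected
    individuals blocked (their genomes count as known)."""
    n = ped.n
    R = np.zeros((n, n))  # R[c, j] = expected fraction of j's genome from c
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        col = R[:, j]
        if s != UNKNOWN and not selected[s]:
            col += 0.5 * R[:, s]
        if d != UNKNOWN and not selected[d]:
            col += 0.5 * R[:, d]
        R[j, j] = 1.0
    # count contributions to others only, and not to already-selected ones
    score = R.sum(axis=1) - R[:, selected].sum(axis=1) - 1.0
    return score


def key_ancestors(ped: Pedigree, budget: float,
                  coverage: float = _HIGH_COVERAGE) -> SequencingPlan:
    """Greedy key-ancestor selection by marginal pedigree contribution;
    selected individuals sequenced at high coverage (default 15x)."""
    n_pick = min(n_affordable(budget, coverage), ped.n)
    selected = np.zeros(ped.n, dtype=bool)
    order: list[int] = []
    for _ in range(n_pick):
        score = _marginal_contributions(ped, selected)
        score[selected] = -np.inf
        best = int(np.flatnonzero(score == score.max())[0])
        selected[best] = True
        order.append(best)
    cov = np.zeros(ped.n)
    cov[selected] = coverage
    return _plan(cov, budget, "KeyAncestors", order=order)


def ped_gen_rel(ped: Pedigree, budget: float,
                coverage: float = _HIGH_COVERAGE) -> SequencingPlan:
    """Stepwise selection maximizing the pedigree relationship between the
    sequenced set and the rest of the population (score 1' A_s^{-1} a_s);
    selected individuals sequenced at high coverage (default 15x)."""
    n = ped.n
    n_pick = min(n_affordable(budget, coverage), n)
    A = additive_matrix(ped)
    rowsum = A.sum(axis=1)
    order: list[int] = []
    if n_pick >= 1:
        a_all = (rowsum - np.diag(A)) / max(n - 1, 1)
        order.append(int(np.flatnonzero(a_all == a_all.max())[0]))
    while len(order) < n_pick:
        k = len(order) + 1
        rest = n - k
        best_c, best_score = -1, -np.inf
        in_set = np.zeros(n, dtype=bool)
        in_set[order] = True
        for c in range(n):
            if in_set[c]:
                continue
            sub = order + [c]
            A_s = A[np.ix_(sub, sub)]
            a_s = (rowsum[sub] - A_s.sum(axis=1)) / max(rest, 1)
            try:
                score = float(np.linalg.solve(A_s, a_s).sum())
            except np.linalg.LinAlgError:
                continue
            if score > best_score:
                best_c, best_score = c, score
        if best_c < 0:
            break
        order.append(best_c)
    cov = np.zeros(n)
    cov[order] = coverage
    return _plan(cov, budget, "PedGenRel", order=order)


# ---------------------------------------------------------------------------
# haplotype-based stand-in
# ---------------------------------------------------------------------------

def _window_haplotypes(panel: HaplotypePanel, window_size: int):
    """Integer codes of each individual's two haplotypes in non-overlapping
    windows of HD markers; returns (codes (n, n_win, 2), per-window
    population frequencies keyed by code)."""
    hd = panel.hd_indices()
    chrom = panel.map.chrom[hd]
    windows = []
    for c in np.unique(chrom):
        idx = hd[chrom == c]
        for k in range(0, len(idx), window_size):
            w = idx[k:k + window_size]
            if len(w) >= 2:
                windows.append(w)
    n = panel.n_individuals
    codes = np.empty((n, len(windows), 2), dtype=np.int64)
    freqs: list[dict[int, float]] = []
    for wi, w in enumerate(windows):
        sub = panel.alleles[:, w, :]  # (n, |w|, 2)
        weights = (1 << np.arange(len(w), dtype=np.int64)) % (2**62)
        code = np.einsum("nlh,l->nh", sub.astype(np.int64), weights)
        codes[:, wi, :] = code
        vals, counts = np.unique(code, return_counts=True)
        freqs.append({int(v): c / (2.0 * n) for v, c in zip(vals, counts)})
    return codes, freqs


def _stage1_families(ped: Pedigree, codes, freqs, n_fam: int) -> list[list[int]]:
    """Greedy focal individuals maximizing newly covered population-
    frequency-weighted haplotypes; each family = focal + parents +
    grandparents that exist in the pedigree."""
    n, n_win, _ = codes.shape
    covered: list[set[int]] = [set() for _ in range(n_win)]
    families: list[list[int]] = []
    chosen = np.zeros(n, dtype=bool)
    for _ in range(n_fam):
        best, best_gain = -1, -1.0
        for i in range(n):
            if chosen[i]:
                continue
            gain = 0.0
            for w in range(n_win):
                for h in set(codes[i, w]):
                    if h not in covered[w]:
                        gain += freqs[w][int(h)]
            if gain > best_gain:
                best, best_gain = i, gain
        if best < 0:
            break
        chosen[best] = True
        for w in range(n_win):
            covered[w].update(int(h) for h in codes[best, w])
        fam = [best]
        for p in (ped.sire[best], ped.dam[best]):
            if p != UNKNOWN:
                fam.append(int(p))
                for gp in (ped.sire[p], ped.dam[p]):
                    if gp != UNKNOWN:
                        fam.append(int(gp))
        families.append(fam)
    return families


def _family_weights(fam: list[int], ped: Pedigree) -> np.ndarray:
    """Phasing-proxy weights: focal 2, parents 1, grandparents 0.5."""
    focal = fam[0]
    w = np.empty(len(fam))
    parents = {int(ped.sire[focal]), int(ped.dam[focal])}
    for k, m in enumerate(fam):
        w[k] = 2.0 if m == focal else (1.0 if m in parents else 0.5)
    return w


def _assign_family_coverage(fam, weights, coverage, fam_budget) -> float:
    """Greedy coverage ladder climb maximizing d(proxy)/d(cost) under the
    family budget; proxy = sum_m w_m (1 - 2^-x_m).  Charges only the
    incremental cost over any coverage a member already has.  Returns MU
    spent."""
    spent = 0.0
    while True:
        best = None
        best_rate = 0.0
        for k, m in enumerate(fam):
            x = coverage[m]
            nxt = [l for l in _ASO_LADDER if l > x]
            if not nxt:
                continue
            step = nxt[0]
            dc = sequencing_cost(step) - sequencing_cost(x)
            if dc <= 0 or spent + dc > fam_budget:
                continue
            gain = weights[k] * (2.0 ** -x - 2.0 ** -step)
            if gain / dc > best_rate:
                best_rate = gain / dc
                best = (m, step, dc)
        if best is None:
            return spent
        m, step, dc = best
        coverage[m] = step
        spent += dc


def _stage2_topup(ped, codes, freqs, coverage, stage_budget, target_cum
                  ) -> list[int]:
    """Sequence carriers of under-covered window haplotypes at 1x, most
    under-covered carriers first, until the stage budget runs out."""
    n, n_win, _ = codes.shape
    cum: list[dict[int, float]] = [{} for _ in range(n_win)]
    for w in range(n_win):
        for i in np.flatnonzero(coverage > 0):
            for h in codes[i, w]:
                cum[w][int(h)] = cum[w].get(int(h), 0.0) + coverage[i]
    n_under = np.zeros(n, dtype=np.int64)
    for w in range(n_win):
        for i in range(n):
            for h in set(codes[i, w]):
                if cum[w].get(int(h), 0.0) < target_cum:
                    n_under[i] += 1
    cand = np.flatnonzero((coverage == 0) & (n_under > 0))
    cand = _ranked(n_under.astype(float), cand)
    cost1 = sequencing_cost(1.0)
    picked = []
    spent = 0.0
    for i in cand:
        if spent + cost1 > stage_budget:
            break
        coverage[i] = 1.0
        spent += cost1
        picked.append(int(i))
    return picked


def alphaseqopt_like(ped: Pedigree, panel: HaplotypePanel, budget: float,
                     window_size: int = 50, target_cum: float = 10.0,
                     _coverage=None, _method="AlphaSeqOptLike"
                     ) -> SequencingPlan:
    """Two-stage haplotype-coverage heuristic (documented stand-in).

    Stage 1 (half the budget): greedy focal individuals whose window
    haplotypes cover the largest new share of the population haplotypes;
    one family (focal + parents + grandparents, nominal 1400 MU) per
    floor(stage-1 budget / 1400), with coverages from {1, 2, 5, 15, 30}
    assigned greedily by phasing-proxy gain per MU.  Stage 2 (other half):
    carriers of window haplotypes whose carriers' summed coverage is below
    ``target_cum`` are sequenced at 1x, most under-covered first.
    """
    codes, freqs = _window_haplotypes(panel, window_size)
    coverage = np.zeros(ped.n) if _coverage is None else _coverage
    stage1 = budget / 2.0
    n_fam = int(stage1 // _FAMILY_COST)
    order: list[int] = []
    families = _stage1_families(ped, codes, freqs, n_fam)
    for fam in families:
        _assign_family_coverage(fam, _family_weights(fam, ped), coverage,
                                _FAMILY_COST)
        order.extend(m for m in fam if coverage[m] > 0 and m not in order)
    order.extend(_stage2_topup(ped, codes, freqs, coverage, budget / 2.0,
                               target_cum))
    return _plan(coverage, budget, _method, order=order)


# ---------------------------------------------------------------------------
# combination and controls
# ---------------------------------------------------------------------------

def _take_ranked_incremental(ranked, x, sub_budget, coverage) -> list[int]:
    """Walk a ranked candidate list assigning coverage ``x``, charging only
    the increment over existing coverage (max rule); unspent surplus keeps
    buying further candidates."""
    spent = 0.0
    picked = []
    for i in ranked:
        cur = coverage[i]
        dc = max(sequencing_cost(max(x, cur)) - sequencing_cost(cur), 0.0)
        if cur >= x:
            continue
        if spent + dc > sub_budget:
            break
        coverage[i] = x
        spent += dc
        picked.append(int(i))
    return picked


def combined(ped: Pedigree, panel: HaplotypePanel, genotyped: np.ndarray,
             budget: float, window_size: int = 50,
             target_cum: float = 10.0) -> SequencingPlan:
    """Quarter-budget combination: top sires at 2x, top dams at 1x, focal
    families at variable coverage, and 1x top-up of under-covered
    haplotype carriers.  An individual picked twice keeps the maximum
    coverage; the cheaper pick's cost stays available to its sub-plan."""
    q = budget / 4.0
    prog, grand = count_progeny(ped, genotyped)
    score = (prog + grand).astype(float)
    coverage = np.zeros(ped.n)
    order: list[int] = []
    sires = np.flatnonzero(ped.sex == MALE)
    dams = np.flatnonzero(ped.sex == FEMALE)
    order += _take_ranked_incremental(_ranked(score, sires), 2.0, q, coverage)
    order += _take_ranked_incremental(_ranked(score, dams), 1.0, q, coverage)

    codes, freqs = _window_haplotypes(panel, window_size)
    n_fam = int(q // _FAMILY_COST)
    for fam in _stage1_families(ped, codes, freqs, n_fam):
        _assign_family_coverage(fam, _family_weights(fam, ped), coverage,
                                _FAMILY_COST)
        order.extend(m for m in fam if coverage[m] > 0 and m not in order)
    order += _stage2_topup(ped, codes, freqs, coverage, q, target_cum)
    return _plan(coverage, budget, "Combined", order=order)


def random_plans(ped: Pedigree, budget: float, mode: str = "uniform",
                 reference_histogram: dict[float, int] | None = None,
                 seed=None) -> SequencingPlan:
    """Random controls: ``uniform`` sequences floor(budget/200) random
    individuals at 2x; ``variable`` replicates a reference plan's coverage
    histogram over randomly drawn individuals."""
    rng = np.random.default_rng(seed)
    cov = np.zeros(ped.n)
    if mode == "uniform":
        k = n_affordable(budget, 2.0)
        if k > ped.n:
            raise ValueError("population smaller than required draws")
        pick = rng.choice(ped.n, size=k, replace=False)
        cov[pick] = 2.0
        return _plan(cov, budget, "RandomUnif", order=pick)
    if mode != "variable":
        raise ValueError(f"unknown mode {mode!r}")
    if not reference_histogram:
        raise ValueError("variable mode needs a reference coverage histogram")
    k = sum(reference_histogram.values())
    if k > ped.n:
        raise ValueError("population smaller than required draws")
    pick = rng.choice(ped.n, size=k, replace=False)
    j = 0
    for x in sorted(reference_histogram, reverse=True):
        c = reference_histogram[x]
        cov[pick[j:j + c]] = x
        j += c
    return _plan(cov, budget, "RandomVar", order=pick)


def concentrated_plan(ped: Pedigree, budget: float,
                      decile: tuple[float, float] | None = None,
                      generation: int | None = None,
                      x: float = 2.0, seed=None) -> SequencingPlan:
    """Random individuals at coverage ``x`` drawn only from a pedigree
    decile [a, b) of relative positions, or from a single generation."""
    if (decile is None) == (generation is None):
        raise ValueError("give exactly one of decile= or generation=")
    if decile is not None:
        a, b = decile
        lo, hi = int(np.floor(a * ped.n)), int(np.floor(b * ped.n))
        members = np.arange(lo, hi)
        label = f"Concentrated[{a:.1f},{b:.1f})"
    else:
        members = np.flatnonzero(ped.generation == generation)
        label = f"ConcentratedGen{generation}"
    k = n_affordable(budget, x)
    if k > members.size:
        raise ValueError("range smaller than the required number of draws")
    rng = np.random.default_rng(seed)
    pick = rng.choice(members, size=k, replace=False)
    cov = np.zeros(ped.n)
    cov[pick] = x
    return _plan(cov, budget, label, order=pick)


def uniform_sweep_plan(ped: Pedigree, budget: float, x: float,
                       seed=None) -> SequencingPlan:
    """As many random individuals as affordable, all at coverage ``x``."""
    k = min(n_affordable(budget, x), ped.n)
    rng = np.random.default_rng(seed)
    pick = rng.choice(ped.n, size=k, replace=False)
    cov = np.zeros(ped.n)
    cov[pick] = x
    return _plan(cov, budget, f"Uniform{x}x", order=pick)


# ---------------------------------------------------------------------------
# uniformization (variable vs uniform coverage)
# ---------------------------------------------------------------------------

@dataclass
class UniformizeResult:
    """A uniformized plan plus the bookkeeping columns of the comparison:
    number sequenced, per-individual coverage, and required investment."""

    plan: SequencingPlan
    n_sequenced: int
    coverage: float
    investment: float


def uniformize(plan: SequencingPlan, mode: str) -> UniformizeResult:
    """Transform a variable-coverage plan into a uniform one.

    ``equal_total_coverage``: every sequenced individual gets the average
    coverage; the investment is accounted as n x 40 + total_coverage x 80
    (the per-x cost of the linear segment, regardless of the average).
    ``equal_investment``: the same individuals get the uniform coverage
    whose cost equals the variable plan's realized investment,
    X = (investment/n - 40)/80.
    ``fixed_2x``: as many of the originally selected individuals as the
    realized investment affords, in original selection order, at 2x.
    """
    idx = plan.sequenced
    n = idx.size
    if n == 0:
        raise ValueError("plan has no sequenced individuals")
    total = plan.total_coverage
    invest = plan.cost()
    cov = np.zeros_like(plan.coverage)
    if mode == "equal_total_coverage":
        xbar = total / n
        cov[idx] = xbar
        investment = n * 40.0 + total * 80.0
        out = SequencingPlan(cov, budget=investment,
                             method=plan.method + "+UniformCoverage")
        return UniformizeResult(out, n, xbar, investment)
    if mode == "equal_investment":
        x = (invest / n - 40.0) / 80.0
        if x <= 0:
            raise ValueError("investment too small for uniform coverage")
        cov[idx] = x
        out = SequencingPlan(cov, budget=invest,
                             method=plan.method + "+UniformInvestment")
        return UniformizeResult(out, n, x, invest)
    if mode == "fixed_2x":
        k = min(int(invest // sequencing_cost(2.0)), n)
        order = plan.order if plan.order is not None else idx
        keep = np.asarray(order)[:k]
        cov[keep] = 2.0
        out = SequencingPlan(cov, budget=invest,
                             method=plan.method + "+Uniform2x")
        return UniformizeResult(out, k, 2.0, float(k * sequencing_cost(2.0)))
    raise ValueError(f"unknown mode {mode!r}")
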