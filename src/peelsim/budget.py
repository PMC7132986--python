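"""Sequencing cost model, investment levels and plan arithmetic.

Costs are expressed in monetary units (MU) with the convention that 2x
sequencing of one individual costs 200 MU: a library preparation of 40 MU
plus a linear sequencing cost of 80 MU per x up to 5x, flattening to fixed
anchors of 500 MU at 15x and 850 MU at 30x (library included).  Between the
anchors the cost is interpolated linearly; an unsequenced individual (0x)
costs nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LIBRARY_COST = 40.0
PER_X_COST = 80.0
#: (coverage, combined cost) anchor points above the linear segment
FIXED_POINTS = ((5.0, 440.0), (15.0, 500.0), (30.0, 850.0))

#: coverage grid used by the variable-coverage strategies
COVERAGE_LADDER = (0.0, 1.0, 2.0, 5.0, 15.0, 30.0)

#: investment levels expressed as a fraction of the population sequenced at 2x
INVESTMENT_FRACTIONS = (0.005, 0.01, 0.02, 0.05)
MIN_INVESTMENT = 10_000.0


def sequencing_cost(x) -> np.ndarray | float:
    """Combined library + sequencing cost (MU) for coverage ``x``.

    0 at 0x; 40 + 80x on (0, 5]; 500 at 15x and 850 at 30x with linear
    interpolation between (5, 440)-(15, 500)-(30, 850) and linear
    extrapolation of the last segment beyond 30x.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("coverage must be non-negative")
    xs = np.array([p[0] for p in FIXED_POINTS])
    cs = np.array([p[1] for p in FIXED_POINTS])
    out = np.where(
        x_arr <= xs[0],
        LIBRARY_COST + PER_X_COST * x_arr,
        np.interp(x_arr, xs, cs),
    )
    # extrapolate past the last anchor with the final segment's slope
    slope = (cs[-1] - cs[-2]) / (xs[-1] - xs[-2])
    out = np.where(x_arr > xs[-1], cs[-1] + slope * (x_arr - xs[-1]), out)
    out = np.where(x_arr == 0, 0.0, out)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def investment_budget(population_size: int, fraction: float) -> float:
    """Investment level: cost-equivalent of sequencing ``fraction`` of the
    population at 2x, i.e. fraction x population x 200 MU (integer MU)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return float(round(fraction * population_size * sequencing_cost(2.0)))


def investment_levels(population_size: int,
                      fractions=INVESTMENT_FRACTIONS) -> dict[float, float]:
    """Admissible investment levels for a population; levels below
    10,000 MU are dropped."""
    levels = {f: investment_budget(population_size, f) for f in fractions}
    return {f: b for f, b in levels.items() if b >= MIN_INVESTMENT}


@dataclass
class SequencingPlan:
    """Per-individual sequencing coverage with a budget and provenance tag."""

    coverage: np.ndarray
    budget: float
    method: str = ""
    #: positions in original selection order (used by plan transforms)
    order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if np.any(self.coverage < 0):
            raise ValueError("negative coverage in plan")

    @property
    def n_sequenced(self) -> int:
        return int(np.count_nonzero(self.coverage))

    @property
    def sequenced(self) -> np.ndarray:
        return np.flatnonzero(self.coverage)

    @property
    def total_coverage(self) -> float:
        return float(self.coverage.sum())

    def cost(self) -> float:
        return plan_cost(self)

    def histogram(self) -> dict[float, int]:
        """Number of sequenced individuals per coverage level."""
        cov = self.coverage[self.coverage > 0]
        levels, counts = np.unique(cov, return_counts=True)
        return {float(l): int(c) for l, c in zip(levels, counts)}

    def to_frame(self, ids=None) -> pd.DataFrame:
        idx = self.sequenced
        return pd.DataFrame({
            "id": idx if ids is None else np.asarray(ids)[idx],
            "position": idx,
            "coverage": self.coverage[idx],
            "method": self.method,
        })

    def to_csv(self, path, ids=None) -> None:
        self.to_frame(ids).to_csv(path, index=False)


def plan_from_histogram(hist: dict[float, int], n: int, budget: float | None = None,
                        method: str = "", rng=None) -> SequencingPlan:
    """Materialize a plan with the given coverage histogram over ``n``
    individuals (positions drawn at random if an rng is given, else filled
    from position 0 upward)."""
    total = sum(hist.values())
    if total > n:
        raise ValueError("histogram larger than the population")
    cov = np.zeros(n)
    if rng is None:
        idx = np.arange(total)
    else:
        idx = rng.choice(n, size=total, replace=False)
    k = 0
    for x in sorted(hist, reverse=True):
        c = hist[x]
        cov[idx[k:k + c]] = x
        k += c
    plan = SequencingPlan(cov, budget=budget if budget is not None else np.inf,
                          method=method)
    if budget is None:
        plan.budget = plan.cost()
    return plan


def plan_cost(plan: SequencingPlan) -> float:
    """Total cost of a plan: sum of per-individual combined costs."""
    return float(np.sum(sequencing_cost(plan.coverage)))


def n_affordable(budget: float, x: float) -> int:
    """How many individuals can be sequenced at coverage ``x`` within budget."""
    c = sequencing_cost(x)
    if c <= 0:
        raise ValueError("coverage must be positive")
    return int(budget // c)
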