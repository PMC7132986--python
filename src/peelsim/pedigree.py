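"""Pedigree data model, I/O, ordering, progeny counts and additive relationships.

The pedigree is the backbone shared by every other module: individuals are
stored in topological order (every parent precedes all of its progeny), with
integer positions 0..n-1 that double as the "relative position" used when
working with overlapping-generation populations.

Relationship computations follow the classical numerator-relationship-matrix
(A-matrix) machinery: the tabular method for explicit matrices on small
pedigrees, Meuwissen & Luo's algorithm for inbreeding coefficients, and
Colleau's indirect method (two pedigree sweeps) for A·v products so that
average relationships never require materializing A on large pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1

MALE = 0
FEMALE = 1
SEX_UNKNOWN = -1

_SEX_TOKENS = {"m": MALE, "M": MALE, "1": MALE, "f": FEMALE, "F": FEMALE, "2": FEMALE,
               "0": SEX_UNKNOWN, "U": SEX_UNKNOWN, "u": SEX_UNKNOWN}
_SEX_OUT = {MALE: "M", FEMALE: "F", SEX_UNKNOWN: "0"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A sorted pedigree.

    Attributes
    ----------
    ids : array of original labels (object/int), in sorted order.
    sire, dam : int arrays with the *position* of each parent, or UNKNOWN.
    sex : int array, MALE/FEMALE/SEX_UNKNOWN.
    generation : int array, generation number (>= 0) for discrete pedigrees,
        UNKNOWN where undefined (overlapping pedigrees).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.generation is None:
            self.generation = np.full(n, UNKNOWN, dtype=np.int32)
        for name in ("sire", "dam", "sex", "generation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int32))
        if not (len(self.sire) == len(self.dam) == len(self.sex) == n):
            raise PedigreeError("field length mismatch")
        self._validate()

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def position(self) -> np.ndarray:
        return np.arange(self.n)

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def _validate(self) -> None:
        for parents in (self.sire, self.dam):
            known = parents != UNKNOWN
            if np.any(parents[known] >= np.flatnonzero(known)):
                raise PedigreeError("parent does not precede progeny; pedigree not sorted")
        both = (self.sire != UNKNOWN) & (self.dam != UNKNOWN)
        if np.any(self.sire[both] == self.dam[both]):
            raise PedigreeError("individual has identical sire and dam")
        used_as_sire = np.unique(self.sire[self.sire != UNKNOWN])
        used_as_dam = np.unique(self.dam[self.dam != UNKNOWN])
        clash = np.intersect1d(used_as_sire, used_as_dam)
        if clash.size:
            raise PedigreeError(
                f"individual(s) used as both sire and dam: {self.ids[clash][:5]}")
        if np.any(self.sex[used_as_sire] == FEMALE) or np.any(self.sex[used_as_dam] == MALE):
            raise PedigreeError("sex inconsistent with parental role")

    # -- derived structures ----------------------------------------------
    def progeny_lists(self) -> list[list[int]]:
        """children[i] = positions of i's progeny (through either sex)."""
        children: list[list[int]] = [[] for _ in range(self.n)]
        for c in range(self.n):
            for p in (self.sire[c], self.dam[c]):
                if p != UNKNOWN:
                    children[p].append(c)
        return children

    def families(self) -> dict[tuple[int, int], list[int]]:
        """Group non-founders by (sire, dam) pair; UNKNOWN slots preserved."""
        fams: dict[tuple[int, int], list[int]] = {}
        for c in range(self.n):
            s, d = int(self.sire[c]), int(self.dam[c])
            if s == UNKNOWN and d == UNKNOWN:
                continue
            fams.setdefault((s, d), []).append(c)
        return fams


# ---------------------------------------------------------------------------
# construction / I/O
# ---------------------------------------------------------------------------

def _topological_order(ids, sire_lab, dam_lab) -> list[int]:
    """Kahn's algorithm over parent->child edges; stable in input order."""
    index = {lab: i for i, lab in enumerate(ids)}
    if len(index) != len(ids):
        dup = pd.Series(ids).duplicated()
        raise PedigreeError(f"duplicate id(s): {np.asarray(ids)[dup][:5]}")
    n = len(ids)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for lab in (sire_lab[i], dam_lab[i]):
            if lab is None:
                continue
            p = index.get(lab)
            if p is None:
                raise PedigreeError(f"parent {lab!r} of {ids[i]!r} not in pedigree")
            if p == i:
                raise PedigreeError(f"cycle: individual {ids[i]!r} is its own ancestor")
            children[p].append(i)
            indeg[i] += 1
    order: list[int] = []
    import heapq
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        raise PedigreeError("cycle detected in pedigree")
    return order


def make_pedigree(ids, sire_labels, dam_labels, sex=None, generation=None,
                  missing=(0, "0", ".", "NA", None)) -> Pedigree:
    """Build a sorted :class:`Pedigree` from parallel label sequences.

    ``sire_labels``/``dam_labels`` refer to entries of ``ids``; anything in
    ``missing`` marks an unknown parent.  Sex, where absent, is inferred from
    parental roles.
    """
    ids = list(ids)
    miss = set(missing)
    s_lab = [None if s in miss else s for s in sire_labels]
    d_lab = [None if d in miss else d for d in dam_labels]
    order = _topological_order(ids, s_lab, d_lab)
    pos = {ids[i]: k for k, i in enumerate(order)}

    n = len(ids)
    sire = np.full(n, UNKNOWN, dtype=np.int32)
    dam = np.full(n, UNKNOWN, dtype=np.int32)
    sx = np.full(n, SEX_UNKNOWN, dtype=np.int32)
    gen = np.full(n, UNKNOWN, dtype=np.int32)
    for k, i in enumerate(order):
        if s_lab[i] is not None:
            sire[k] = pos[s_lab[i]]
        if d_lab[i] is not None:
            dam[k] = pos[d_lab[i]]
        if sex is not None:
            v = sex[i]
            sx[k] = _SEX_TOKENS.get(v, v) if isinstance(v, str) else (
                SEX_UNKNOWN if v is None else int(v))
        if generation is not None:
            gen[k] = int(generation[i])
    # infer missing sex from parental roles
    for k in range(n):
        if sire[k] != UNKNOWN and sx[sire[k]] == SEX_UNKNOWN:
            sx[sire[k]] = MALE
        if dam[k] != UNKNOWN and sx[dam[k]] == SEX_UNKNOWN:
            sx[dam[k]] = FEMALE
    sorted_ids = np.empty(n, dtype=object)
    sorted_ids[:] = [ids[i] for i in order]
    return Pedigree(ids=sorted_ids, sire=sire, dam=dam, sex=sx, generation=gen)


def read_pedigree(path) -> Pedigree:
    """Read a whitespace- or comma-delimited id/sire/dam[/sex] text file.

    Unknown parents are encoded as ``0`` (or ``.``/``NA``).  A header line is
    detected by non-numeric first field named like 'id'.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    first = str(df.iloc[0, 0]).lower()
    if first in {"id", "individual", "animal"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs at least 3 columns: id sire dam")
    ids = df.iloc[:, 0].str.strip().tolist()
    sire = df.iloc[:, 1].str.strip().tolist()
    dam = df.iloc[:, 2].str.strip().tolist()
    sex = df.iloc[:, 3].str.strip().tolist() if df.shape[1] > 3 else None
    if all(str(i).lstrip("-").isdigit() for i in ids):
        ids = [int(i) for i in ids]
        sire = [int(s) if str(s).lstrip("-").isdigit() else s for s in sire]
        dam = [int(d) if str(d).lstrip("-").isdigit() else d for d in dam]
        missing = {0, ".", "NA", "na", "", None}
    else:
        missing = {"0", ".", "NA", "na", "", None}
    return make_pedigree(ids, sire, dam, sex=sex, missing=missing)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the same dialect that :func:`read_pedigree` accepts."""
    with open(path, "w") as fh:
        for i in range(ped.n):
            s = ped.ids[ped.sire[i]] if ped.sire[i] != UNKNOWN else 0
            d = ped.ids[ped.dam[i]] if ped.dam[i] != UNKNOWN else 0
            fh.write(f"{ped.ids[i]} {s} {d} {_SEX_OUT[int(ped.sex[i])]}\n")


# ---------------------------------------------------------------------------
# progeny counting
# ---------------------------------------------------------------------------

def count_progeny(ped: Pedigree, genotyped: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual counts of (genotyped) progeny and grandprogeny.

    Only individuals flagged ``genotyped`` are counted; grandprogeny are
    counted through intermediate offspring of either sex regardless of the
    intermediate's own flag.  With ``genotyped=None`` everybody counts.
    """
    if genotyped is None:
        genotyped = np.ones(ped.n, dtype=bool)
    genotyped = np.asarray(genotyped, dtype=bool)
    if genotyped.shape != (ped.n,):
        raise PedigreeError("genotyped flags not aligned to pedigree")
    children = ped.progeny_lists()
    prog = np.zeros(ped.n, dtype=np.int64)
    grand = np.zeros(ped.n, dtype=np.int64)
    n_geno_children = np.array([sum(genotyped[c] for c in ch) for ch in children])
    for i, ch in enumerate(children):
        prog[i] = n_geno_children[i]
        grand[i] = sum(n_geno_children[c] for c in ch)
    return prog, grand


# ---------------------------------------------------------------------------
# relationships
# ---------------------------------------------------------------------------

def additive_matrix(ped: Pedigree) -> np.ndarray:
    """Full numerator relationship matrix A by the tabular method.

    Founders are assumed unrelated and non-inbred; an individual with one
    known parent is treated as if the missing parent were an unrelated
    phantom founder (its row simply contributes nothing).
    Intended for pedigrees up to a few thousand individuals.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo ancestor-tracing
    algorithm; O(total ancestor paths), no matrix.

    Uses the identity A_ii = 1 + F_i = sum_j L_ij^2 d_j where the row of the
    Cholesky factor is traced through the ancestors of i's parents
    (c_j = 0.5(L_sj + L_dj)) and d_j = 0.5 - 0.25(F_sire(j) + F_dam(j)) is
    the Mendelian-sampling variance, an unknown parent entering as F = -1
    (so one-unknown gives d = 0.75, both-unknown 1.0).  Hence
    F_i = d_i + sum_{j<i} c_j^2 d_j - 1.
    """
    import heapq

    n = ped.n
    F = np.zeros(n)
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s == UNKNOWN or d == UNKNOWN:
            continue
        heap = [-s, -d]
        heapq.heapify(heap)
        contrib: dict[int, float] = {s: 0.5, d: 0.5}
        fi = 0.0
        while heap:
            j = -heapq.heappop(heap)
            while heap and -heap[0] == j:
                heapq.heappop(heap)
            cj = contrib.pop(j)
            js, jd = int(ped.sire[j]), int(ped.dam[j])
            dj = 0.5 - 0.25 * ((F[js] if js != UNKNOWN else -1.0)
                               + (F[jd] if jd != UNKNOWN else -1.0))
            fi += cj * cj * dj
            for p in (js, jd):
                if p == UNKNOWN:
                    continue
                if p in contrib:
                    contrib[p] += 0.5 * cj
                else:
                    contrib[p] = 0.5 * cj
                    heapq.heappush(heap, -p)
        d_i = 0.5 - 0.25 * (F[s] + F[d])
        F[i] = fi + d_i - 1.0
    return F


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    n = ped.n
    d = np.ones(n)
    s_known = ped.sire != UNKNOWN
    d_known = ped.dam != UNKNOWN
    Fs = np.where(s_known, F[np.where(s_known, ped.sire, 0)], -1.0)
    Fd = np.where(d_known, F[np.where(d_known, ped.dam, 0)], -1.0)
    d = 0.5 - 0.25 * (Fs + Fd)
    return d


def amat_vec(ped: Pedigree, v: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
    """Indirect product A·v via Colleau's two pedigree sweeps, O(n) memory.

    A = (I-P)^-1 D (I-P)^-T with P holding 0.5 at parent links and D the
    Mendelian-sampling variances; the product is computed as three sparse
    solves/sweeps without forming A.
    """
    v = np.asarray(v, dtype=float)
    if F is None:
        F = inbreeding_coefficients(ped)
    dvec = _mendelian_variances(ped, F)
    n = ped.n
    # u = (I-P)^-T v : reverse sweep, u_i = v_i + 0.5 * sum_{children c} u_c
    u = v.copy()
    for c in range(n - 1, -1, -1):
        uc = 0.5 * u[c]
        s, d = ped.sire[c], ped.dam[c]
        if s != UNKNOWN:
            u[s] += uc
        if d != UNKNOWN:
            u[d] += uc
    u *= dvec
    # w = (I-P)^-1 u : forward sweep, w_i = u_i + 0.5(w_s + w_d)
    w = u
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        acc = 0.0
        if s != UNKNOWN:
            acc += 0.5 * w[s]
        if d != UNKNOWN:
            acc += 0.5 * w[d]
        w[i] += acc
    return w


@dataclass
class RelationshipView:
    """Relationships of a subset: A over the subset plus each member's average
    relationship to all individuals *outside* the subset."""

    subset: np.ndarray
    A_s: np.ndarray
    a_s: np.ndarray


_FULL_A_LIMIT = 5000


def relationship_view(ped: Pedigree, subset, _force_indirect: bool = False
                      ) -> RelationshipView:
    """A_s and average-relationship vector a_s for a subset of individuals.

    Uses the tabular A for pedigrees up to a few thousand individuals and
    Colleau indirect products (one A·e_j sweep per subset member) beyond.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise PedigreeError("subset is empty")
    if np.unique(subset).size != subset.size:
        raise PedigreeError("subset contains duplicates")
    n = ped.n
    rest = n - subset.size
    if ped.n <= _FULL_A_LIMIT and not _force_indirect:
        A = additive_matrix(ped)
        A_s = A[np.ix_(subset, subset)]
        rows = A[subset]
    else:
        F = inbreeding_coefficients(ped)
        rows = np.empty((subset.size, n))
        for k, j in enumerate(subset):
            e = np.zeros(n)
            e[j] = 1.0
            rows[k] = amat_vec(ped, e, F=F)
        A_s = rows[:, subset]
    if rest > 0:
        a_s = (rows.sum(axis=1) - rows[:, subset].sum(axis=1)) / rest
    else:
        a_s = np.zeros(subset.size)
    return RelationshipView(subset=subset, A_s=A_s, a_s=a_s)
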