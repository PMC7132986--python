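"""Iterative pedigree peeling: single-locus, multi-locus and hybrid.

The imputation engine works on 4-vectors of *ordered* (phased) genotype
probabilities per individual and locus, states G = {(0,0),(0,1),(1,0),(1,1)}
with (paternal allele, maternal allele).  Information flows through the
pedigree as messages on the family ("marriage node") factor graph:

* the **anterior** of an individual carries information from its ancestors,
  computed from its parents' states through the Mendelian transmission
  kernel;
* each family an individual parents sends back a **posterior** message
  carrying information from the mate and the progeny;
* the **penetrance** holds the observation likelihoods (sequence reads
  and/or marker-array calls).

On loop-free pedigrees iterating these updates is exact (it is belief
propagation with one factor per family, so full-sib families do not create
loops); with inbreeding loops the same updates are iterated as an
approximation, as is standard for this family of methods.

Segregation probabilities extend the kernel to linked loci: a non-founder's
state at a locus records which grandparental haplotype it received from its
sire and from its dam (4 states).  Multi-locus peeling alternates
segregation-aware genotype peeling with a per-individual forward-backward
pass along the chromosome, with switch probability between adjacent loci
given by Haldane's map function r = 0.5(1 - exp(-2d/100)) for d in cM.
Hybrid peeling interpolates those segregation probabilities to every
sequenced site and runs segregation-aware single-locus peeling there.

All probability work is in linear space with a 1e-30 floor and per-step
renormalization; 4-state vectors cannot underflow catastrophically once
floored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FLOOR = 1e-30
FREQ_CLAMP = 1e-4

#: allele carried paternally / maternally by each ordered genotype
PAT = np.array([0, 0, 1, 1])
MAT = np.array([0, 1, 0, 1])

#: segregation states: index 2*ss + sd, where ss (sd) = 0 if the paternal
#: (maternal) allele came from the parent's own paternal haplotype, 1 if
#: from its maternal haplotype
_ALLELE = np.stack([PAT, MAT])  # (2, 4): _ALLELE[sigma, g]


def _make_basis() -> np.ndarray:
    B = np.zeros((4, 4, 4, 4))
    for ss in range(2):
        for sd in range(2):
            s = 2 * ss + sd
            for gs in range(4):
                for gd in range(4):
                    for gc in range(4):
                        B[s, gs, gd, gc] = float(
                            _ALLELE[ss, gs] == PAT[gc]
                            and _ALLELE[sd, gd] == MAT[gc])
    return B


#: B[seg_state, G_sire, G_dam, G_child] indicator kernels
SEG_BASIS = _make_basis()
#: classic Mendelian kernel = segregation-uniform average
KERNEL = SEG_BASIS.mean(axis=0)
#: SEG_BASIS with the two parent axes flattened: (4 seg, 16, 4 child)
_SEG_BASIS_FLAT = SEG_BASIS.reshape(4, 16, 4)


def hw_prior(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg prior over ordered genotypes, shape (L, 4)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    q = 1.0 - p
    return np.stack([q * q, q * p, p * q, p * p], axis=-1)


def _norm(a: np.ndarray) -> np.ndarray:
    a = np.maximum(a, FLOOR)
    return a / a.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# penetrance construction
# ---------------------------------------------------------------------------

def reads_to_penetrance(n_alt: np.ndarray, n_ref: np.ndarray,
                        err: float = 0.001) -> np.ndarray:
    """Genotype likelihoods from read counts.

    P(reads | G) with the probability that a read shows the alternative
    allele equal to err, 0.5, 0.5, 1-err for the four ordered genotypes.
    Zero-read entries come out as all-ones (uninformative).  Output is
    scaled so each 4-vector has maximum 1.
    """
    if not 0 < err < 0.5:
        raise ValueError("read error must be in (0, 0.5)")
    theta = np.array([err, 0.5, 0.5, 1.0 - err])
    na = np.asarray(n_alt, dtype=float)[..., None]
    nr = np.asarray(n_ref, dtype=float)[..., None]
    with np.errstate(divide="ignore"):
        logp = na * np.log(theta) + nr * np.log1p(-theta)
    logp -= logp.max(axis=-1, keepdims=True)
    return np.maximum(np.exp(logp), FLOOR)


def array_to_penetrance(calls: np.ndarray, err: float = 0.01) -> np.ndarray:
    """Genotype likelihoods from marker-array calls (0/1/2, -1 = missing).

    The called genotype gets likelihood 1-err, split equally over the two
    phased orderings for heterozygotes; the error mass is spread over the
    inconsistent states.
    """
    if not 0 < err < 0.5:
        raise ValueError("array error must be in (0, 0.5)")
    table = np.array([
        [1.0 - err, err / 3, err / 3, err / 3],          # call 0
        [err / 2, (1 - err) / 2, (1 - err) / 2, err / 2],  # call 1
        [err / 3, err / 3, err / 3, 1.0 - err],          # call 2
        [1.0, 1.0, 1.0, 1.0],                            # missing
    ])
    calls = np.asarray(calls)
    idx = np.where(calls < 0, 3, calls).astype(np.int64)
    return table[idx]


def combine_penetrance(*pens: np.ndarray) -> np.ndarray:
    out = pens[0].copy()
    for p in pens[1:]:
        out *= p
    return np.maximum(out, FLOOR)


# ---------------------------------------------------------------------------
# peeling state
# ---------------------------------------------------------------------------

@dataclass
class PeelingState:
    """Posterior phased-genotype probabilities per individual and locus."""

    genotype_probs: np.ndarray  # (n, L, 4)
    allele_freq: np.ndarray     # (L,)
    n_iter: int
    max_delta: float
    converged: bool

    def dosages(self) -> np.ndarray:
        return dosages(self)


def dosages(state: PeelingState) -> np.ndarray:
    """Expected alternative-allele count in [0, 2] per individual x locus."""
    q = state.genotype_probs
    return q[..., 1] + q[..., 2] + 2.0 * q[..., 3]


@dataclass
class SegregationProbs:
    """Per individual x locus inheritance-state probabilities (4 states);
    founders carry the uniform vector."""

    probs: np.ndarray  # (n, L, 4)
    cm: np.ndarray     # (L,) genetic positions


def haldane_recombination(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between loci separated by d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# the peeler
# ---------------------------------------------------------------------------

class _Peeler:
    """Shared machinery for single- and multi-locus peeling on one locus
    block (e.g. one chromosome)."""

    def __init__(self, ped, penetrance: np.ndarray, p_init=None,
                 update_freq: bool = True, dtype=np.float64):
        from .pedigree import UNKNOWN
        self.UNK = UNKNOWN
        self.ped = ped
        self.dtype = np.dtype(dtype)
        self.basis = _SEG_BASIS_FLAT.astype(self.dtype)
        self.pen = np.maximum(np.asarray(penetrance, dtype=self.dtype), FLOOR)
        n, L, k = self.pen.shape
        if n != ped.n or k != 4:
            raise ValueError("penetrance must have shape (n_individuals, n_loci, 4)")
        self.n, self.L = n, L
        fams = ped.families()
        # family order: by position of the earliest child (a valid peeling order)
        self.families = sorted(((s, d, np.array(cs)) for (s, d), cs in fams.items()),
                               key=lambda t: t[2].min())
        self.fam_of_child = np.full(n, -1, dtype=np.int64)
        self.fams_as_parent: list[list[int]] = [[] for _ in range(n)]
        for fid, (s, d, cs) in enumerate(self.families):
            self.fam_of_child[cs] = fid
            if s != UNKNOWN:
                self.fams_as_parent[s].append(fid)
            if d != UNKNOWN:
                self.fams_as_parent[d].append(fid)
        self.n_fam = len(self.families)
        # messages family -> parent, flat ones initially
        self.msg_s = np.full((self.n_fam, L, 4), 0.25, dtype=self.dtype)
        self.msg_d = np.full((self.n_fam, L, 4), 0.25, dtype=self.dtype)
        self.update_freq = update_freq
        if p_init is None:
            p0 = self._freq_from_penetrance()
        else:
            p0 = np.broadcast_to(np.asarray(p_init, dtype=float), (L,)).copy()
        self.p = np.clip(p0, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
        self.prior = hw_prior(self.p).astype(self.dtype)  # (L, 4)
        self.anterior = np.full((n, L, 4), 0.25, dtype=self.dtype)
        founders = ped.is_founder()
        self.anterior[founders] = self.prior
        self.is_founder = founders
        self.q = self._posteriors()

    # -- helpers ----------------------------------------------------------
    def _freq_from_penetrance(self) -> np.ndarray:
        q = _norm(self.pen)
        dose = q[..., 1] + q[..., 2] + 2 * q[..., 3]
        # individuals with flat penetrance contribute dose 1; add pseudocounts
        return (dose.sum(axis=0) + 1.0) / (2.0 * self.n + 2.0)

    def _below(self, i: int) -> np.ndarray:
        """pen x prod of posterior messages from i's own families."""
        fams = self.fams_as_parent[i]
        if not fams:  # childless: below is just the (floored) penetrance
            return self.pen[i]
        b = self.pen[i]
        for fid in fams:
            s, d, _ = self.families[fid]
            b = b * (self.msg_s[fid] if s == i else self.msg_d[fid])
        return _norm(b)

    def _below_all(self) -> np.ndarray:
        """Below vectors for everybody at the current messages, (n, L, 4)."""
        b = self.pen.copy()
        for fid, (s, d, _) in enumerate(self.families):
            if s != self.UNK:
                b[s] *= self.msg_s[fid]
            if d != self.UNK:
                b[d] *= self.msg_d[fid]
        return _norm(b)

    def _u_msg(self, i: int, fid_exclude: int) -> np.ndarray:
        """anterior x pen x all posterior messages except the target family."""
        u = self.anterior[i] * self.pen[i]
        for fid in self.fams_as_parent[i]:
            if fid == fid_exclude:
                continue
            s, d, _ = self.families[fid]
            u = u * (self.msg_s[fid] if s == i else self.msg_d[fid])
        return _norm(u)

    def _posteriors(self) -> np.ndarray:
        q = self.anterior * self.pen
        for fid, (s, d, _) in enumerate(self.families):
            if s != self.UNK:
                q[s] = q[s] * self.msg_s[fid]
            if d != self.UNK:
                q[d] = q[d] * self.msg_d[fid]
        return _norm(q)

    def _child_kernels(self, cs: np.ndarray, seg) -> np.ndarray:
        """Transmission kernels for the children of one family: (C, L, 4, 4, 4)."""
        if seg is None:
            K = KERNEL.astype(self.dtype).reshape(16, 4)
            return np.broadcast_to(K, (len(cs), self.L, 16, 4))
        return np.einsum("nls,skg->nlkg", seg[cs].astype(self.dtype),
                         self.basis)

    # -- one sweep --------------------------------------------------------
    def sweep(self, seg=None, collect_emissions: bool = False):
        """One down+up pass over all families.

        With ``collect_emissions`` the up pass also returns, per child and
        locus, the unnormalized likelihood of each of the 4 segregation
        states given everything else (used by the multi-locus update).
        """
        emissions = np.full((self.n, self.L, 4), 0.25) if collect_emissions else None
        # --- down: anteriors ---
        # messages are fixed during the down pass, so all below vectors can
        # be computed once up front
        below = self._below_all()
        for fid, (s, d, cs) in enumerate(self.families):
            us = self.prior if s == self.UNK else self._u_msg(s, fid)
            ud = self.prior if d == self.UNK else self._u_msg(d, fid)
            jp = (us[:, :, None] * ud[:, None, :]).reshape(self.L, 16)
            T = self._child_kernels(cs, seg)
            z = np.maximum(np.einsum("clkg,clg->clk", T, below[cs]), FLOOR)
            prod_all = z.prod(axis=0)  # (L, 16)
            others = (jp * prod_all)[None] / z  # (C, L, 16)
            ant = np.einsum("clk,clkg->clg", others, T)
            self.anterior[cs] = _norm(ant)
        # --- up: posterior messages (and segregation emissions) ---
        for fid in range(self.n_fam - 1, -1, -1):
            s, d, cs = self.families[fid]
            us = self.prior if s == self.UNK else self._u_msg(s, fid)
            ud = self.prior if d == self.UNK else self._u_msg(d, fid)
            T = self._child_kernels(cs, seg)
            b = np.empty((len(cs), self.L, 4), dtype=self.dtype)
            for k, c in enumerate(cs):
                b[k] = self._below(c)
            z = np.maximum(np.einsum("clkg,clg->clk", T, b), FLOOR)
            prod_sq = z.prod(axis=0).reshape(self.L, 4, 4)
            if s != self.UNK:
                self.msg_s[fid] = _norm(np.einsum("lab,lb->la", prod_sq, ud))
            if d != self.UNK:
                self.msg_d[fid] = _norm(np.einsum("lab,la->lb", prod_sq, us))
            if collect_emissions:
                jp = (us[:, :, None] * ud[:, None, :]).reshape(self.L, 16)
                ctx = (jp * prod_sq.reshape(self.L, 16))[None] / z  # (C, L, 16)
                # e[c,l,s] = sum_k ctx[c,l,k] sum_g B[s,k,g] b[c,l,g]
                tmp = np.einsum("clg,skg->clsk", b, self.basis)
                emissions[cs] = _norm(np.einsum("clsk,clk->cls", tmp, ctx))
        return emissions

    def finish_iteration(self) -> float:
        q_new = self._posteriors()
        delta = float(np.max(np.abs(q_new - self.q)))
        self.q = q_new
        if self.update_freq:
            dose = q_new[..., 1] + q_new[..., 2] + 2 * q_new[..., 3]
            self.p = np.clip(dose.mean(axis=0) / 2.0, FREQ_CLAMP, 1 - FREQ_CLAMP)
            self.prior = hw_prior(self.p).astype(self.dtype)
            self.anterior[self.is_founder] = self.prior
        return delta


def single_locus_peel(ped, penetrance: np.ndarray, p_init=None,
                      n_iter: int = 20, tol: float = 1e-6,
                      seg: SegregationProbs | np.ndarray | None = None,
                      update_freq: bool = True,
                      dtype=np.float64) -> PeelingState:
    """Iterative single-locus peeling over a block of independent loci.

    Parameters
    ----------
    penetrance : (n, L, 4) observation likelihoods.
    p_init : initial allele frequency (scalar or per locus); estimated from
        the penetrance when omitted.
    seg : optional (n, L, 4) segregation probabilities; when given, each
        child's transmission kernel is conditioned on its inheritance states
        (this is the second, genome-wide step of hybrid peeling).
    update_freq : re-estimate allele frequencies (and founder priors) from
        the current posteriors after each iteration.
    """
    if isinstance(seg, SegregationProbs):
        seg = seg.probs
    peeler = _Peeler(ped, penetrance, p_init=p_init, update_freq=update_freq,
                     dtype=dtype)
    delta = np.inf
    it = 0
    for it in range(1, n_iter + 1):
        peeler.sweep(seg=seg)
        delta = peeler.finish_iteration()
        if delta < tol:
            break
    return PeelingState(genotype_probs=peeler.q, allele_freq=peeler.p,
                        n_iter=it, max_delta=delta, converged=delta < tol)


# ---------------------------------------------------------------------------
# multi-locus peeling (segregation estimation)
# ---------------------------------------------------------------------------

def _segregation_fb(emissions: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Forward-backward over the 4 inheritance states along one chromosome,
    vectorized over individuals.

    emissions : (n, L, 4); r : (L-1,) recombination fractions.  The
    transition factorizes per parent: switch with probability r_k
    independently for the paternally- and maternally-inherited chromosome.
    """
    n, L, _ = emissions.shape
    dt = emissions.dtype
    R = np.empty((L - 1, 2, 2), dtype=dt) if L > 1 else np.empty((0, 2, 2))
    if L > 1:
        R[:, 0, 0] = R[:, 1, 1] = 1.0 - r
        R[:, 0, 1] = R[:, 1, 0] = r
        # kron over the two parental chains -> (L-1, 4, 4)
        M = np.einsum("kab,kcd->kacbd", R, R).reshape(L - 1, 4, 4)
    fwd = np.empty((n, L, 4), dtype=dt)
    fwd[:, 0] = _norm(0.25 * emissions[:, 0])
    for k in range(1, L):
        fwd[:, k] = _norm(np.einsum("na,ab->nb", fwd[:, k - 1], M[k - 1])
                          * emissions[:, k])
    bwd = np.ones((n, 4), dtype=dt)
    post = np.empty_like(fwd)
    post[:, L - 1] = _norm(fwd[:, L - 1])
    for k in range(L - 2, -1, -1):
        bwd = _norm(np.einsum("ab,nb->na", M[k], emissions[:, k + 1] * bwd))
        post[:, k] = _norm(fwd[:, k] * bwd)
    return post


def multi_locus_peel(ped, penetrance: np.ndarray, cm: np.ndarray,
                     n_iter: int = 20, tol: float = 1e-6, p_init=None,
                     update_freq: bool = True, dtype=np.float64,
                     return_state: bool = False):
    """Estimate segregation probabilities on a set of linked loci
    (typically the marker-array loci of one chromosome).

    Alternates (a) segregation-aware genotype peeling at every locus with
    (b) a forward-backward update of each individual's inheritance states
    along the chromosome, until the genotype posteriors stabilize.
    """
    cm = np.asarray(cm, dtype=float)
    if np.any(np.diff(cm) < 0):
        raise ValueError("locus map positions must be non-decreasing")
    peeler = _Peeler(ped, penetrance, p_init=p_init, update_freq=update_freq,
                     dtype=dtype)
    n, L = peeler.n, peeler.L
    seg = np.full((n, L, 4), 0.25, dtype=peeler.dtype)
    r = haldane_recombination(np.diff(cm))
    r = np.clip(r, 1e-8, 0.5)
    non_founder = ~ped.is_founder()
    delta = np.inf
    it = 0
    for it in range(1, n_iter + 1):
        emissions = peeler.sweep(seg=seg, collect_emissions=True)
        if L > 1:
            seg[non_founder] = _segregation_fb(emissions[non_founder], r)
        else:
            seg[non_founder] = _norm(emissions[non_founder])
        delta = peeler.finish_iteration()
        if delta < tol:
            break
    segp = SegregationProbs(probs=seg, cm=cm)
    if return_state:
        state = PeelingState(genotype_probs=peeler.q, allele_freq=peeler.p,
                             n_iter=it, max_delta=delta, converged=delta < tol)
        return segp, state
    return segp


def interpolate_segregation(seg: SegregationProbs, target_cm: np.ndarray
                            ) -> np.ndarray:
    """Linear interpolation of segregation probabilities (in cM) to other
    loci on the same chromosome; constant beyond the mapped ends."""
    hd_cm = seg.cm
    t = np.asarray(target_cm, dtype=float)
    if len(hd_cm) == 1:
        out = np.repeat(seg.probs[:, :1, :], len(t), axis=1)
        return _norm(out)
    idx = np.clip(np.searchsorted(hd_cm, t, side="right"), 1, len(hd_cm) - 1)
    lo, hi = idx - 1, idx
    span = np.maximum(hd_cm[hi] - hd_cm[lo], 1e-12)
    w = np.clip((t - hd_cm[lo]) / span, 0.0, 1.0)
    out = (1.0 - w)[None, :, None] * seg.probs[:, lo, :] \
        + w[None, :, None] * seg.probs[:, hi, :]
    return _norm(out)


def hybrid_peel(ped, penetrance: np.ndarray, seg: SegregationProbs,
                target_cm: np.ndarray, n_iter: int = 20, tol: float = 1e-6,
                p_init=None, update_freq: bool = True,
                dtype=np.float64) -> PeelingState:
    """Segregation-aware single-locus peeling at arbitrary sites.

    ``penetrance`` holds the observations at the target loci (reads and/or
    array calls); segregation probabilities estimated at the marker loci
    are linearly interpolated in cM to the target positions.
    """
    seg_t = interpolate_segregation(seg, target_cm)
    return single_locus_peel(ped, penetrance, seg=seg_t, n_iter=n_iter,
                             tol=tol, p_init=p_init, update_freq=update_freq,
                             dtype=dtype)
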