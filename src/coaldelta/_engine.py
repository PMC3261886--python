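"""MCMC engine for multispecies-coalescent posterior sampling.

The state is (species-tree node ages tau, per-population theta, per-locus
rate and heredity multipliers, and one gene genealogy per locus).  The
target is

    p(tau, theta, r, h, {G_l} | D) propto
        prod_l P(D_l | G_l, r_l) f_MSC(G_l | tau, theta * h_l) * priors

with the sequence likelihood by pruning (JC69 by default, the
equal-frequency HKY variant behind a flag) and everything on the nuclear
time scale internally (gene-tree branch lengths enter the likelihood
multiplied by the locus rate multiplier).

Moves: gene-node age sliders; subtree re-attachment by re-coalescence
into the remaining genealogy (proposal equals the conditional MSC
density, so the acceptance ratio is the likelihood ratio alone); the
rubber-band move on species divergence times, which deforms the gene-tree
ages inside the affected populations linearly and carries the
corresponding Jacobian; multiplier moves on theta, rate and heredity
parameters; a whole-state scale ("mixing") move; and, optionally, rooted
NNI moves on the species-tree topology with re-drawn node ages and
rejection of incompatible gene trees.  Proposal step sizes are tuned
during burn-in toward acceptance rates of 0.2-0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from ._kernels import abc_coeffs, msc_logdens, pruning_update, root_loglik
from .coalsim import simulate_gene_genealogy
from .design import MarkerProfile, SpeciesTree
from .seqsim import Alignment

__all__ = ["EnginePriors", "MSCEngine", "substream"]


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent reproducible substream for (replicate, locus, ...) keys."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in keys)))


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (shape - 1.0) * math.log(x) - x / scale \
        - shape * math.log(scale) - gammaln(shape)


@dataclass
class EnginePriors:
    """Resolved prior configuration (all on the nuclear scale)."""

    theta_shape: float = 2.0
    theta_scale: float = 0.0125
    tau_mean: float = 0.001
    rate_shape: float = 5.0       # mean-1 Gamma on locus rate multipliers
    heredity_shape: float = 4.0   # Gamma(4, mean/4) on heredity multipliers


class _LocusState:
    def __init__(self, alignment: Alignment, profile: MarkerProfile,
                 st: SpeciesTree, rng: np.random.Generator,
                 r: float, h: float, kappa_lik: float):
        self.prof = profile
        self.r = r
        self.h = h
        self.kappa_lik = kappa_lik
        self.aln = alignment

        # initial gene tree from the MSC prior at the current state
        counts: Dict[str, int] = {}
        for lab in alignment.labels:
            sp = lab.rsplit("_", 1)[0]
            if sp not in st.labels:
                raise ValueError(f"tip {lab!r} does not match any species")
            counts[sp] = counts.get(sp, 0) + 1
        g = simulate_gene_genealogy(st, profile, counts, rng)
        self.n_tips = g.n_tips
        self.nn = g.n_nodes
        self.labels = g.labels
        self.tip_species = g.species[:self.n_tips].copy()
        self.tip_counts = np.zeros(st.n_species, dtype=np.int64)
        for s in self.tip_species:
            self.tip_counts[s] += 1
        self.parent = g.parent.copy()
        self.age = g.age / profile.rate_multiplier  # nuclear scale
        self._set_data(alignment)
        self._rebuild_structure()
        self.A = np.zeros(self.nn)
        self.B = np.zeros(self.nn)
        self.C = np.zeros(self.nn)
        self.ll = 0.0
        self.dens = 0.0

    def _set_data(self, alignment: Alignment):
        if set(alignment.labels) != set(self.labels):
            raise ValueError("alignment labels do not match gene-tree tips")
        rows = [alignment.labels.index(lab) for lab in self.labels]
        data = alignment.data[rows]
        uniq, w = np.unique(data.T, axis=0, return_counts=True)
        self.codes = np.ascontiguousarray(uniq.T).astype(np.int8)
        self.w = w.astype(np.float64)
        self.part = np.ones((self.nn, self.codes.shape[1], 4))

    def _rebuild_structure(self):
        """children, masks and internal postorder from the parent array."""
        child = np.full((self.nn, 2), -1, dtype=np.int64)
        slot = np.zeros(self.nn, dtype=np.int64)
        root = -1
        for v in range(self.nn):
            p = self.parent[v]
            if p < 0:
                root = v
            else:
                child[p, slot[p]] = v
                slot[p] += 1
        self.child = child
        self.root = root
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            if child[v, 0] >= 0:
                order.append(v)
                stack.append(child[v, 0])
                stack.append(child[v, 1])
        order.reverse()
        self.post_int = np.array(order, dtype=np.int64)
        mask = np.zeros(self.nn, dtype=np.int64)
        for i in range(self.n_tips):
            mask[i] = 1 << int(self.tip_species[i])
        for v in self.post_int:
            mask[v] = mask[child[v, 0]] | mask[child[v, 1]]
        self.mask = mask

    # branch coefficient helpers -----------------------------------------
    def set_abc(self, v: int):
        p = self.parent[v]
        if p < 0:
            return
        d = (self.age[p] - self.age[v]) * self.r
        self.A[v], self.B[v], self.C[v] = abc_coeffs(max(d, 0.0),
                                                     self.kappa_lik)

    def set_all_abc(self):
        par = self.parent
        has_par = par >= 0
        d = np.zeros(self.nn)
        d[has_par] = (self.age[par[has_par]] - self.age[has_par]) * self.r
        np.maximum(d, 0.0, out=d)
        k = self.kappa_lik
        e2 = np.exp(-4.0 * d / (k + 2.0))
        e1 = np.exp(-2.0 * d * (k + 1.0) / (k + 2.0))
        self.A = 0.5 * (e2 + e1)
        self.B = 0.5 * (e2 - e1)
        self.C = 0.25 * (1.0 - e2)

    def path_to_root(self, v: int) -> np.ndarray:
        path = []
        while v >= 0:
            if self.child[v, 0] >= 0:
                path.append(v)
            v = self.parent[v]
        return np.array(path, dtype=np.int64)


class MSCEngine:
    """Sampler over (tau, theta, rates, heredities, gene trees [, topology])."""

    def __init__(self, st: SpeciesTree, alignments: Sequence[Alignment],
                 profiles: Sequence[MarkerProfile], priors: EnginePriors,
                 rng: np.random.Generator, rate_mode: str = "fixed_true",
                 heredity_mode: str = "fixed_true",
                 fixed_rates: Optional[Sequence[float]] = None,
                 likelihood: str = "jc69", likelihood_scale: float = 1.0,
                 estimate_topology: bool = False):
        if rate_mode not in ("fixed_true", "estimated_internal",
                             "fixed_external"):
            raise ValueError(f"unknown rate_mode {rate_mode!r}")
        if heredity_mode not in ("fixed_true", "estimated"):
            raise ValueError(f"unknown heredity_mode {heredity_mode!r}")
        if likelihood not in ("jc69", "hky85"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        self.st = st.copy()
        self.priors = priors
        self.rng = rng
        self.rate_mode = rate_mode
        self.heredity_mode = heredity_mode
        self.likelihood_scale = likelihood_scale
        self.estimate_topology = estimate_topology

        self.loci: List[_LocusState] = []
        for i, (aln, prof) in enumerate(zip(alignments, profiles)):
            if fixed_rates is not None:
                r = float(fixed_rates[i])
            elif rate_mode == "estimated_internal":
                r = 1.0
            else:
                r = prof.rate_multiplier
            if heredity_mode == "fixed_true":
                h = prof.heredity_multiplier
            else:
                h = 1.0 if prof.marker_class == "nuclear" else 0.25
            kappa_lik = prof.kappa if likelihood == "hky85" else 1.0
            self.loci.append(_LocusState(aln, prof, self.st, rng, r, h,
                                         kappa_lik))
        self.h_prior_mean = [1.0 if l.prof.marker_class == "nuclear" else 0.25
                             for l in self.loci]

        # tuned proposal widths
        m = priors.tau_mean
        self.step = {"tau": {v: m for v in self._internal_sp_nodes()},
                     "theta": 1.0, "rate": 0.4, "her": 0.5, "mix": 0.3,
                     "gage_root": 0.8}
        self.acc = {k: [0, 0] for k in
                    ("gage", "spr", "tau", "theta", "rate", "her", "mix",
                     "topo")}

        for ls in self.loci:
            ls.set_all_abc()
            self._full_update(ls)
            ls.dens = self._dens(ls)
            if not np.isfinite(ls.dens):
                raise RuntimeError("invalid initial gene tree")

    # -- basic quantities --------------------------------------------------
    def _internal_sp_nodes(self) -> List[int]:
        return [v for v in range(self.st.n_nodes) if self.st.children[v]]

    def _full_update(self, ls: _LocusState):
        if self.likelihood_scale == 0.0:
            ls.ll = 0.0
            return
        pruning_update(ls.post_int, ls.child[:, 0], ls.child[:, 1],
                       ls.n_tips, ls.codes, ls.A, ls.B, ls.C, ls.part)
        ls.ll = self.likelihood_scale * root_loglik(ls.part, ls.root, ls.w)

    def _path_update(self, ls: _LocusState, path: np.ndarray):
        if self.likelihood_scale == 0.0:
            ls.ll = 0.0
            return
        pruning_update(path, ls.child[:, 0], ls.child[:, 1],
                       ls.n_tips, ls.codes, ls.A, ls.B, ls.C, ls.part)
        ls.ll = self.likelihood_scale * root_loglik(ls.part, ls.root, ls.w)

    def _dens(self, ls: _LocusState) -> float:
        return msc_logdens(self.st.parent, self.st.age, self.st.mask,
                           self.st.theta, self.st.n_species, ls.age, ls.mask,
                           ls.n_tips, ls.tip_counts, ls.h)

    def tau_logprior(self) -> float:
        lp = 0.0
        m = self.priors.tau_mean
        for v in self._internal_sp_nodes():
            inc = self.st.age[v] - max(self.st.age[c]
                                       for c in self.st.children[v])
            lp += -inc / m - math.log(m)
        return lp

    def theta_logprior(self) -> float:
        return sum(_gamma_logpdf(t, self.priors.theta_shape,
                                 self.priors.theta_scale)
                   for t in self.st.theta)

    def rate_logprior(self) -> float:
        if self.rate_mode != "estimated_internal":
            return 0.0
        a = self.priors.rate_shape
        return sum(_gamma_logpdf(ls.r, a, 1.0 / a) for ls in self.loci)

    def heredity_logprior(self) -> float:
        if self.heredity_mode != "estimated":
            return 0.0
        a = self.priors.heredity_shape
        return sum(_gamma_logpdf(ls.h, a, mean / a)
                   for ls, mean in zip(self.loci, self.h_prior_mean))

    def log_posterior(self) -> float:
        return (sum(ls.ll + ls.dens for ls in self.loci)
                + self.tau_logprior() + self.theta_logprior()
                + self.rate_logprior() + self.heredity_logprior())

    # -- gene-tree moves ---------------------------------------------------
    def _sp_constraint(self, ls: _LocusState, v: int) -> float:
        return self.st.age[self.st.mrca_node(int(ls.mask[v]))]

    def move_gene_age(self, ls: _LocusState, v: int):
        rng = self.rng
        lb = max(float(ls.age[ls.child[v, 0]]), float(ls.age[ls.child[v, 1]]),
                 self._sp_constraint(ls, v))
        old_age = float(ls.age[v])
        if ls.parent[v] < 0:
            ex = old_age - lb
            if ex <= 0:
                ex = 1e-12
            new_ex = ex * math.exp(self.step["gage_root"]
                                   * (rng.random() - 0.5))
            new_age = lb + new_ex
            hastings = math.log(new_ex / ex)
        else:
            ub = float(ls.age[ls.parent[v]])
            if ub <= lb:
                return
            new_age = lb + rng.random() * (ub - lb)
            hastings = 0.0
        old_ll, old_dens = ls.ll, ls.dens
        ls.age[v] = new_age
        for u in (v, ls.child[v, 0], ls.child[v, 1]):
            ls.set_abc(u)
        path = ls.path_to_root(v)
        self._path_update(ls, path)
        new_dens = self._dens(ls)
        logr = (new_dens - old_dens) + (ls.ll - old_ll) + hastings
        self.acc["gage"][1] += 1
        if math.log(rng.random() + 1e-300) < logr:
            ls.dens = new_dens
            self.acc["gage"][0] += 1
        else:
            ls.age[v] = old_age
            for u in (v, ls.child[v, 0], ls.child[v, 1]):
                ls.set_abc(u)
            self._path_update(ls, path)
            ls.ll, ls.dens = old_ll, old_dens

    # re-coalescence SPR ---------------------------------------------------
    def _pop_path(self, mask: int) -> List[int]:
        cache = getattr(self, "_pop_path_cache", None)
        if cache is None:
            cache = self._pop_path_cache = {}
        path = cache.get(mask)
        if path is not None:
            return path
        p = self.st.mrca_node(mask)
        path = [p]
        while self.st.parent[p] >= 0:
            p = self.st.parent[p]
            path.append(p)
        cache[mask] = path
        return path

    def _invalidate_topology_caches(self):
        self._pop_path_cache = {}

    def move_gene_spr(self, ls: _LocusState):
        rng = self.rng
        st = self.st
        nn = ls.nn
        if ls.n_tips < 2:
            return
        # choose a non-root node to prune
        c = int(rng.integers(0, nn))
        while ls.parent[c] < 0:
            c = int(rng.integers(0, nn))
        save = (ls.parent.copy(), ls.child.copy(), ls.age.copy(),
                ls.mask.copy(), ls.post_int.copy(), ls.root,
                ls.A.copy(), ls.B.copy(), ls.C.copy(), ls.ll, ls.dens)
        p = int(ls.parent[c])
        sib = int(ls.child[p, 0] if ls.child[p, 1] == c else ls.child[p, 1])
        gp = int(ls.parent[p])
        # prune: sib takes p's place
        ls.parent[sib] = gp
        if gp >= 0:
            slot = 0 if ls.child[gp, 0] == p else 1
            ls.child[gp, slot] = sib
            rem_root = ls.root if p != ls.root else sib
        else:
            rem_root = sib
        ls.parent[c] = -2  # detached marker
        ls.parent[p] = -2

        # active = remaining tree (excludes c's subtree and p)
        active = np.ones(nn, dtype=np.bool_)
        stack = [c]
        while stack:
            u = stack.pop()
            active[u] = False
            if ls.child[u, 0] >= 0:
                stack.append(int(ls.child[u, 0]))
                stack.append(int(ls.child[u, 1]))
        active[p] = False

        from ._kernels import spr_attach
        kseed = int(rng.integers(0, 2 ** 31))
        target, t_star = spr_attach(kseed, ls.parent, ls.age,
                                    ls.tip_species, ls.n_tips, active,
                                    float(ls.age[c]), int(ls.mask[c]),
                                    st.parent, st.age, st.mask, st.theta,
                                    ls.h)
        target = int(target)
        if target < 0:  # numerically impossible (root pop is infinite)
            self._spr_restore(ls, save)
            return
        # splice p back with children (c, target) at t_star
        tpar = int(ls.parent[target])
        ls.parent[c] = p
        ls.parent[p] = tpar
        if tpar >= 0:
            slot = 0 if ls.child[tpar, 0] == target else 1
            ls.child[tpar, slot] = p
        ls.parent[target] = p
        ls.child[p, 0] = c
        ls.child[p, 1] = target
        ls.age[p] = t_star
        ls._rebuild_structure()
        ls.set_all_abc()
        old_ll = save[9]
        self._full_update(ls)
        self.acc["spr"][1] += 1
        logr = ls.ll - old_ll  # prior and proposal cancel exactly
        if math.log(rng.random() + 1e-300) < logr:
            ls.dens = self._dens(ls)
            self.acc["spr"][0] += 1
        else:
            self._spr_restore(ls, save)

    def _spr_restore(self, ls: _LocusState, save):
        (ls.parent, ls.child, ls.age, ls.mask, ls.post_int, ls.root,
         ls.A, ls.B, ls.C, ls.ll, ls.dens) = save
        self._full_update(ls)

    # -- species-tree moves ------------------------------------------------
    def move_tau(self, s: int):
        rng = self.rng
        st = self.st
        tau = float(st.age[s])
        lb = max(float(st.age[c]) for c in st.children[s])
        is_root = st.parent[s] < 0
        ub = math.inf if is_root else float(st.age[st.parent[s]])
        w = self.step["tau"][s]
        new = tau + (rng.random() - 0.5) * w
        # reflect into (lb, ub)
        for _ in range(100):
            if new < lb:
                new = 2 * lb - new
            elif new > ub:
                new = 2 * ub - new
            else:
                break
        if not (lb < new < ub):
            return
        old_state = (st.age.copy(),
                     [ls.age.copy() for ls in self.loci],
                     [ls.ll for ls in self.loci],
                     [ls.dens for ls in self.loci])
        old_tau_prior = self.tau_logprior()
        old_sum = sum(ls.ll + ls.dens for ls in self.loci)
        children = set(st.children[s])
        log_jac = 0.0
        ratio_lo = (new - lb) / (tau - lb) if tau > lb else 1.0
        ratio_hi = (ub - new) / (ub - tau) if ub < math.inf else 1.0
        st.age[s] = new
        ok = True
        for ls in self.loci:
            for k in range(ls.n_tips, ls.nn):
                a = float(ls.age[k])
                host = self._host(ls, k, a, old_sp_age=old_state[0])
                if host in children and lb < a < tau:
                    ls.age[k] = lb + (a - lb) * ratio_lo
                    log_jac += math.log(ratio_lo)
                elif host == s:
                    if is_root:
                        ls.age[k] = a + (new - tau)
                    else:
                        ls.age[k] = ub - (ub - a) * ratio_hi
                        log_jac += math.log(ratio_hi)
            ls.set_all_abc()
            self._full_update(ls)
            ls.dens = self._dens(ls)
            if not np.isfinite(ls.dens):
                ok = False
                break
        self.acc["tau"][1] += 1
        if ok:
            new_sum = sum(ls.ll + ls.dens for ls in self.loci)
            logr = (new_sum - old_sum) + (self.tau_logprior()
                                          - old_tau_prior) + log_jac
            if math.log(rng.random() + 1e-300) < logr:
                self.acc["tau"][0] += 1
                return
        st.age[:] = old_state[0]
        for ls, ages, ll, dens in zip(self.loci, *old_state[1:]):
            ls.age[:] = ages
            ls.set_all_abc()
            self._full_update(ls)
            ls.ll, ls.dens = ll, dens

    def _host(self, ls: _LocusState, k: int, a: float,
              old_sp_age: np.ndarray) -> int:
        """Host population of gene node k at age a under the OLD tau."""
        st = self.st
        p = st.mrca_node(int(ls.mask[k]))
        while st.parent[p] >= 0 and old_sp_age[st.parent[p]] <= a:
            p = st.parent[p]
        return p

    def move_theta(self, pop: int):
        rng = self.rng
        st = self.st
        old = float(st.theta[pop])
        new = old * math.exp(self.step["theta"] * (rng.random() - 0.5))
        old_dens = [ls.dens for ls in self.loci]
        d_prior = (_gamma_logpdf(new, self.priors.theta_shape,
                                 self.priors.theta_scale)
                   - _gamma_logpdf(old, self.priors.theta_shape,
                                   self.priors.theta_scale))
        st.theta[pop] = new
        new_dens = [self._dens(ls) for ls in self.loci]
        logr = d_prior + sum(new_dens) - sum(old_dens) \
            + math.log(new / old)
        self.acc["theta"][1] += 1
        if math.log(rng.random() + 1e-300) < logr:
            for ls, d in zip(self.loci, new_dens):
                ls.dens = d
            self.acc["theta"][0] += 1
        else:
            st.theta[pop] = old

    def move_rate(self, li: int):
        if self.rate_mode != "estimated_internal":
            return
        rng = self.rng
        ls = self.loci[li]
        old = ls.r
        new = old * math.exp(self.step["rate"] * (rng.random() - 0.5))
        a = self.priors.rate_shape
        d_prior = _gamma_logpdf(new, a, 1.0 / a) - _gamma_logpdf(old, a, 1.0 / a)
        old_ll = ls.ll
        ls.r = new
        ls.set_all_abc()
        self._full_update(ls)
        logr = d_prior + ls.ll - old_ll + math.log(new / old)
        self.acc["rate"][1] += 1
        if math.log(rng.random() + 1e-300) < logr:
            self.acc["rate"][0] += 1
        else:
            ls.r = old
            ls.set_all_abc()
            self._full_update(ls)
            ls.ll = old_ll

    def move_heredity(self, li: int):
        if self.heredity_mode != "estimated":
            return
        rng = self.rng
        ls = self.loci[li]
        old = ls.h
        new = old * math.exp(self.step["her"] * (rng.random() - 0.5))
        a = self.priors.heredity_shape
        mean = self.h_prior_mean[li]
        d_prior = _gamma_logpdf(new, a, mean / a) \
            - _gamma_logpdf(old, a, mean / a)
        old_dens = ls.dens
        ls.h = new
        new_dens = self._dens(ls)
        logr = d_prior + new_dens - old_dens + math.log(new / old)
        self.acc["her"][1] += 1
        if math.log(rng.random() + 1e-300) < logr:
            ls.dens = new_dens
            self.acc["her"][0] += 1
        else:
            ls.h = old

    def move_mixing(self):
        rng = self.rng
        st = self.st
        c = math.exp(self.step["mix"] * (rng.random() - 0.5))
        rates_scale = self.rate_mode == "estimated_internal"
        n_scaled = (len(self._internal_sp_nodes()) + st.n_nodes
                    + sum(ls.nn - ls.n_tips for ls in self.loci))
        if rates_scale:
            n_scaled -= len(self.loci)
        old_prior = (self.tau_logprior() + self.theta_logprior()
                     + self.rate_logprior())
        old_dens = [ls.dens for ls in self.loci]
        old_ll = [ls.ll for ls in self.loci]
        old_sp_age = st.age.copy()
        old_theta = st.theta.copy()
        old_ages = [ls.age.copy() for ls in self.loci]
        old_r = [ls.r for ls in self.loci]
        st.age *= c
        st.theta *= c
        for ls in self.loci:
            ls.age *= c
            if rates_scale:
                ls.r /= c
            else:
                ls.set_all_abc()
                self._full_update(ls)
            ls.dens = self._dens(ls)
        new_prior = (self.tau_logprior() + self.theta_logprior()
                     + self.rate_logprior())
        logr = (new_prior - old_prior
                + sum(ls.dens for ls in self.loci) - sum(old_dens)
                + sum(ls.ll for ls in self.loci) - sum(old_ll)
                + n_scaled * math.log(c))
        self.acc["mix"][1] += 1
        if math.log(rng.random() + 1e-300) < logr:
            self.acc["mix"][0] += 1
        else:
            st.age[:] = old_sp_age
            st.theta[:] = old_theta
            for ls, ages, r, d, ll in zip(self.loci, old_ages, old_r,
                                          old_dens, old_ll):
                ls.age[:] = ages
                ls.r = r
                if not rates_scale:
                    ls.set_all_abc()
                    self._full_update(ls)
                ls.ll, ls.dens = ll, d

    # -- topology move (rooted NNI) ------------------------------------------
    def move_topology(self):
        rng = self.rng
        st = self.st
        # internal non-root nodes with an internal parent edge
        edges = [v for v in range(st.n_nodes)
                 if st.children[v] and st.parent[v] >= 0]
        if not edges:
            return
        v = edges[int(rng.integers(0, len(edges)))]
        u = int(st.parent[v])
        sib = [x for x in st.children[u] if x != v][0]
        a = st.children[v][int(rng.integers(0, 2))]
        b = [x for x in st.children[v] if x != a][0]
        old_lb = max(st.age[a], st.age[b])
        new_lb = max(st.age[sib], st.age[b])
        if new_lb >= st.age[u]:
            return
        old_age_v = float(st.age[v])
        old_parent = st.parent.copy()
        old_tau_prior = self.tau_logprior()
        old_dens = [ls.dens for ls in self.loci]
        # swap a <-> sib
        st.parent[a] = u
        st.parent[sib] = v
        st.age[v] = new_lb + rng.random() * (st.age[u] - new_lb)
        st._rebuild()
        self._invalidate_topology_caches()
        ok = True
        new_dens = []
        for ls in self.loci:
            d = self._dens(ls)
            if not np.isfinite(d):
                ok = False
                break
            new_dens.append(d)
        self.acc["topo"][1] += 1
        if ok:
            hastings = math.log((st.age[u] - new_lb)
                                / (st.age[u] - old_lb))
            logr = (sum(new_dens) - sum(old_dens)
                    + self.tau_logprior() - old_tau_prior + hastings)
            if math.log(rng.random() + 1e-300) < logr:
                for ls, d in zip(self.loci, new_dens):
                    ls.dens = d
                self.acc["topo"][0] += 1
                return
        st.parent[:] = old_parent
        st.age[v] = old_age_v
        st._rebuild()
        self._invalidate_topology_caches()

    # -- sweeps and runs -----------------------------------------------------
    def sweep(self):
        rng = self.rng
        from ._kernels import gene_age_sweep
        st = self.st
        for li, ls in enumerate(self.loci):
            n_int = ls.nn - ls.n_tips
            n_age = max(4, n_int // 2)
            kseed = int(rng.integers(0, 2 ** 31))
            ll, dens, acc, tot = gene_age_sweep(
                n_age, kseed, ls.parent, ls.child[:, 0], ls.child[:, 1],
                ls.age, ls.mask, ls.n_tips, ls.post_int, ls.codes, ls.w,
                ls.A, ls.B, ls.C, ls.part, ls.r, ls.kappa_lik,
                self.likelihood_scale, self.step["gage_root"],
                st.parent, st.age, st.mask, st.theta, st.n_species,
                ls.tip_counts, ls.h, ls.ll, ls.dens)
            ls.ll = ll
            ls.dens = dens
            self.acc["gage"][0] += acc
            self.acc["gage"][1] += tot
            for _ in range(max(1, n_int // 8)):
                self.move_gene_spr(ls)
            self.move_rate(li)
            self.move_heredity(li)
        nodes = self._internal_sp_nodes()
        if nodes:
            self.move_tau(nodes[int(rng.integers(0, len(nodes)))])
        for pop in range(self.st.n_nodes):
            self.move_theta(pop)
        self.move_mixing()
        if self.estimate_topology:
            for _ in range(6):
                self.move_topology()

    def adapt(self):
        """Burn-in tuning toward acceptance rates in [0.2, 0.5]."""

        def tune(value, frac):
            if frac > 0.5:
                return value * 1.4
            if frac < 0.2:
                return value * 0.7
            return value

        for key in ("theta", "rate", "her", "mix", "gage_root"):
            mapping = {"theta": "theta", "rate": "rate", "her": "her",
                       "mix": "mix", "gage_root": "gage"}
            acc, tot = self.acc[mapping[key]]
            if tot >= 20:
                self.step[key] = tune(self.step[key], acc / tot)
        acc, tot = self.acc["tau"]
        if tot >= 20:
            frac = acc / tot
            for v in self.step["tau"]:
                self.step["tau"][v] = tune(self.step["tau"][v], frac)
        for k in self.acc:
            self.acc[k] = [0, 0]

    def record(self) -> Dict[str, float]:
        st = self.st
        row: Dict[str, float] = {}
        internal = sorted(self._internal_sp_nodes(), key=lambda v: st.age[v])
        for rank, v in enumerate(internal, start=1):
            row[f"tau{rank}"] = float(st.age[v])
        # named clade age for the fixed-topology runs
        if "sp1" in st.labels and "sp2" in st.labels:
            m12 = (1 << st.species_index("sp1")) \
                | (1 << st.species_index("sp2"))
            row["tau_sp1sp2"] = float(st.age[st.mrca_node(m12)])
        if st.children[st.root]:
            row["tau_root"] = float(st.age[st.root])
        for v in range(st.n_nodes):
            row[f"theta_n{v}"] = float(st.theta[v])
        for i, ls in enumerate(self.loci):
            row[f"rate_{i}"] = ls.r
            row[f"heredity_{i}"] = ls.h
        row["loglik"] = float(sum(ls.ll for ls in self.loci))
        row["logdens"] = float(sum(ls.dens for ls in self.loci))
        if self.estimate_topology:
            row["topology"] = st.topology_key()
        return row

    def set_alignment(self, li: int, alignment: Alignment):
        """Replace the data of locus ``li`` (used by calibration tests)."""
        ls = self.loci[li]
        ls._set_data(alignment)
        ls.aln = alignment
        self._full_update(ls)

    def gene_tree(self, li: int):
        """Current genealogy of locus ``li`` as a GeneTree (locus scale)."""
        from .coalsim import GeneTree
        ls = self.loci[li]
        return GeneTree(ls.labels, ls.tip_species, ls.parent,
                        ls.age * ls.r, ls.prof)

    def run(self, n_iter: int, burn_in: int, thin: int,
            adapt_interval: int = 100) -> List[Dict[str, float]]:
        out = []
        for it in range(n_iter):
            self.sweep()
            if it < burn_in:
                if (it + 1) % adapt_interval == 0:
                    self.adapt()
            elif (it - burn_in) % thin == 0:
                out.append(self.record())
        return out
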