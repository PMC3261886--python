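"""Joint Bayesian species-tree topology inference for radiation scenarios.

Extends the fixed-topology MSC sampler with rooted-NNI moves over the
species tree (re-attaching a species subtree across an internal branch
with a re-drawn node age; gene trees are kept and the move is rejected
when they become incompatible).  The posterior over the 105 rooted
5-taxon topologies is summarised by sampled frequencies and the MAP
topology; accuracy is reported as percent-correct and rooted-clade
Robinson-Foulds distance against the true tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._engine import EnginePriors, MSCEngine, substream
from ._kernels import abc_coeffs, pruning_update, root_loglik
from .coalsim import GeneTree, simulate_gene_genealogy
from .design import MarkerProfile, SpeciesTree
from .mscbayes import MSCDivergenceSampler, PriorSpec
from .seqsim import Alignment

__all__ = ["TopologyPosterior", "SpeciesTreeTopologySampler",
           "sample_topology_posterior", "rf_distance", "radiation_summary",
           "topology_from_key", "random_topology",
           "enumerate_rooted_topologies", "importance_marginal_loglik"]


# ---------------------------------------------------------------------------
# topology utilities
# ---------------------------------------------------------------------------

def topology_from_key(key: str, age_step: float = 1.0) -> SpeciesTree:
    """SpeciesTree (arbitrary ages/theta) from a canonical topology key."""
    pos = [0]

    def parse() -> object:
        if key[pos[0]] == "(":
            pos[0] += 1
            left = parse()
            assert key[pos[0]] == ","
            pos[0] += 1
            right = parse()
            assert key[pos[0]] == ")"
            pos[0] += 1
            return (left, right)
        j = pos[0]
        while j < len(key) and key[j] not in ",()":
            j += 1
        name = key[pos[0]:j]
        pos[0] = j
        return name

    nested = parse()
    ages: Dict[frozenset, float] = {}

    def depth(t) -> Tuple[frozenset, int]:
        if isinstance(t, str):
            return frozenset([t]), 0
        (c1, d1), (c2, d2) = depth(t[0]), depth(t[1])
        clade = c1 | c2
        d = max(d1, d2) + 1
        ages[clade] = d * age_step
        return clade, d

    depth(nested)
    return SpeciesTree.from_nested(nested, ages, 1.0)


def random_topology(labels: Sequence[str],
                    rng: np.random.Generator) -> SpeciesTree:
    """Uniform-ish random rooted topology by sequential random joining."""
    groups: List[object] = list(labels)
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        b = groups.pop(j)
        a = groups.pop(i)
        groups.append((a, b))
    ages: Dict[frozenset, float] = {}

    def depth(t):
        if isinstance(t, str):
            return frozenset([t]), 0
        (c1, d1), (c2, d2) = depth(t[0]), depth(t[1])
        clade = c1 | c2
        d = max(d1, d2) + 1
        ages[clade] = float(d)
        return clade, d

    depth(groups[0])
    return SpeciesTree.from_nested(groups[0], ages, 1.0)


def enumerate_rooted_topologies(labels: Sequence[str]) -> List[str]:
    """Canonical keys of all rooted binary topologies ((2n-3)!! of them)."""
    labels = sorted(labels)

    def rec(items: Tuple[str, ...]) -> List[str]:
        if len(items) == 1:
            return [items[0]]
        first, rest = items[0], items[1:]
        out = []
        # the first label anchors the left side, so each unordered root
        # split is enumerated exactly once
        for split in range(0, 1 << len(rest)):
            left = (first,) + tuple(x for k, x in enumerate(rest)
                                    if (split >> k) & 1)
            right = tuple(x for k, x in enumerate(rest)
                          if not (split >> k) & 1)
            if not right:
                continue
            for lt in rec(left):
                for rt in rec(right):
                    a, b = sorted([lt, rt])
                    out.append(f"({a},{b})")
        return out

    return sorted(set(rec(tuple(labels))))


def rf_distance(a: SpeciesTree, b: SpeciesTree) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of the
    non-trivial clade sets of the two rooted trees."""
    if set(a.labels) != set(b.labels):
        raise ValueError("tip sets differ")
    return len(set(a.clades()) ^ set(b.clades()))


# ---------------------------------------------------------------------------
# posterior container and sampler
# ---------------------------------------------------------------------------

@dataclass
class TopologyPosterior:
    """Sampled topology frequencies and the MAP topology."""

    frequencies: pd.DataFrame  # columns: topology, frequency
    map_topology: str
    samples: pd.DataFrame

    def __post_init__(self):
        tot = float(self.frequencies["frequency"].sum())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("topology frequencies must sum to 1")

    def map_tree(self) -> SpeciesTree:
        return topology_from_key(self.map_topology)


class SpeciesTreeTopologySampler(BaseEstimator):
    """Joint MSC sampler over species-tree topologies (radiation study).

    Same state and moves as the divergence-time sampler plus rooted NNI
    topology moves; the chain starts from a seed-dependent random
    topology.  ``fit`` exposes ``topology_posterior_``, ``map_topology_``
    and the full ``trace_``.
    """

    def __init__(self, priors: Optional[PriorSpec] = None,
                 n_iter: int = 1500, burn_in: int = 500, thin: int = 3,
                 seed: int = 0, likelihood: str = "hky85",
                 start_topology: Optional[SpeciesTree] = None):
        self.priors = priors
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.likelihood = likelihood
        self.start_topology = start_topology

    def fit(self, X: Sequence[Alignment], y=None,
            profiles: Optional[Sequence[MarkerProfile]] = None):
        alignments = list(X)
        if not alignments:
            raise ValueError("at least one locus required")
        if profiles is None:
            profiles = [a.locus for a in alignments]
        if any(p is None for p in profiles):
            raise ValueError("marker profiles required")
        self.priors_ = self.priors or PriorSpec()
        species = sorted({lab.rsplit("_", 1)[0]
                          for lab in alignments[0].labels})
        if len(species) < 3:
            raise ValueError("topology sampling needs >= 3 species")
        rng = substream(self.seed, 0x70)

        helper = MSCDivergenceSampler(priors=self.priors_, seed=self.seed,
                                      likelihood=self.likelihood)
        helper.priors_ = self.priors_
        if self.priors_.tau_mean is not None:
            tau_mean = self.priors_.tau_mean
        else:
            tau_mean = helper._tau_mean_from_data(alignments, profiles)
        self.tau_mean_ = tau_mean

        st = self.start_topology.copy() if self.start_topology is not None \
            else random_topology(species, rng)
        for v in st.postorder:
            if st.children[v]:
                st.age[v] = max(st.age[c] for c in st.children[v]) + tau_mean
        st.theta[:] = self.priors_.theta_shape * self.priors_.theta_scale
        st._rebuild()

        fixed_rates = None
        if self.priors_.rate_mode == "fixed_external":
            fixed_rates = helper._external_rates(alignments, profiles)
        eng_priors = EnginePriors(self.priors_.theta_shape,
                                  self.priors_.theta_scale, tau_mean,
                                  self.priors_.rate_shape,
                                  self.priors_.heredity_shape)
        self.engine_ = MSCEngine(
            st, alignments, profiles, eng_priors, rng,
            rate_mode=self.priors_.rate_mode,
            heredity_mode=self.priors_.heredity_mode,
            fixed_rates=fixed_rates, likelihood=self.likelihood,
            estimate_topology=True)
        rows = self.engine_.run(self.n_iter, self.burn_in, self.thin)
        samples = pd.DataFrame(rows)
        freq = (samples["topology"].value_counts(normalize=True)
                .rename_axis("topology").reset_index(name="frequency"))
        self.trace_ = samples
        self.topology_posterior_ = TopologyPosterior(
            freq, str(freq.iloc[0]["topology"]), samples)
        self.map_topology_ = self.topology_posterior_.map_topology
        return self


def sample_topology_posterior(alignments: Sequence[Alignment],
                              priors: Optional[PriorSpec] = None,
                              loci: Optional[Sequence[MarkerProfile]] = None,
                              mcmc: Optional[Dict] = None,
                              rng_seed: int = 0) -> TopologyPosterior:
    """Functional wrapper over :class:`SpeciesTreeTopologySampler`."""
    mcmc = dict(mcmc or {})
    est = SpeciesTreeTopologySampler(priors=priors, seed=rng_seed, **mcmc)
    est.fit(alignments, profiles=loci)
    return est.topology_posterior_


def radiation_summary(results: Iterable[Tuple[SpeciesTree, SpeciesTree]]
                      ) -> Tuple[float, float]:
    """(% MAP topologies equal to truth, mean rooted RF distance)."""
    results = list(results)
    if not results:
        raise ValueError("no results")
    correct = 0
    rfs = []
    for map_tree, true_tree in results:
        rfs.append(rf_distance(map_tree, true_tree))
        if map_tree.topology_key() == true_tree.topology_key():
            correct += 1
    return 100.0 * correct / len(results), float(np.mean(rfs))


# ---------------------------------------------------------------------------
# debug oracle: importance-sampling marginal likelihood per topology
# ---------------------------------------------------------------------------

def _gene_tree_loglik(g: GeneTree, aln: Alignment, kappa: float = 1.0) -> float:
    """Pruning log likelihood of an alignment on a fixed gene tree."""
    rows = [aln.labels.index(lab) for lab in g.labels]
    data = aln.data[rows]
    uniq, w = np.unique(data.T, axis=0, return_counts=True)
    codes = np.ascontiguousarray(uniq.T).astype(np.int8)
    w = w.astype(np.float64)
    nn = g.n_nodes
    child = np.full((nn, 2), -1, dtype=np.int64)
    slot = np.zeros(nn, dtype=np.int64)
    root = g.root
    for v in range(nn):
        p = g.parent[v]
        if p >= 0:
            child[p, slot[p]] = v
            slot[p] += 1
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        if child[v, 0] >= 0:
            order.append(v)
            stack.append(int(child[v, 0]))
            stack.append(int(child[v, 1]))
    order.reverse()
    post = np.array(order, dtype=np.int64)
    A = np.zeros(nn)
    B = np.zeros(nn)
    C = np.zeros(nn)
    for v in range(nn):
        p = g.parent[v]
        if p >= 0:
            A[v], B[v], C[v] = abc_coeffs(max(g.age[p] - g.age[v], 0.0),
                                          kappa)
    part = np.ones((nn, codes.shape[1], 4))
    pruning_update(post, child[:, 0], child[:, 1], g.n_tips, codes,
                   A, B, C, part)
    return float(root_loglik(part, root, w))


def importance_marginal_loglik(topology_key: str,
                               alignments: Sequence[Alignment],
                               profiles: Sequence[MarkerProfile],
                               priors: PriorSpec, tau_mean: float,
                               n_draws: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo marginal log likelihood of a species-tree topology.

    Draws (tau, theta) from the priors and gene trees from the MSC, and
    averages the JC sequence likelihood — an unbiased estimate of the
    same marginal likelihood the MCMC sampler targets; used as an
    independent check of the NNI sampler on small data sets.
    """
    rng = substream(seed, 0x15)
    base = topology_from_key(topology_key)
    counts_per_aln = []
    for aln in alignments:
        counts: Dict[str, int] = {}
        for lab in aln.labels:
            sp = lab.rsplit("_", 1)[0]
            counts[sp] = counts.get(sp, 0) + 1
        counts_per_aln.append(counts)
    logws = np.empty(n_draws)
    for d in range(n_draws):
        st = base.copy()
        for v in st.postorder:
            if st.children[v]:
                st.age[v] = max(st.age[c] for c in st.children[v]) \
                    + rng.exponential(tau_mean)
        st.theta[:] = rng.gamma(priors.theta_shape, priors.theta_scale,
                                size=st.n_nodes)
        st._rebuild()
        ll = 0.0
        for aln, prof, counts in zip(alignments, profiles, counts_per_aln):
            g = simulate_gene_genealogy(st, prof, counts, rng)
            ll += _gene_tree_loglik(g, aln, kappa=1.0)
        logws[d] = ll
    return float(logsumexp(logws) - math.log(n_draws))
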