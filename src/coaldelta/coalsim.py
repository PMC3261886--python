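"""Gene genealogies under the neutral multispecies coalescent (MSC).

Within every population of locus-scale parameter ``theta_locus`` the
waiting time to the next coalescence among ``j`` lineages is exponential
with rate ``j (j-1) / theta_locus``; lineages that fail to coalesce by the
top of a population are handed to the parent population, and the root
population extends to infinity.  The coalescing pair is uniform over
pairs.  No migration and no recombination within a locus; loci are
independent ("free recombination").

Simulation runs on the nuclear time scale with effective
``theta = h * theta_pop`` and the resulting node ages are multiplied by
the locus rate multiplier ``r``, so a :class:`GeneTree` carries ages in
substitutions/site at the locus's own rate (the scale of its alignment).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np

from .design import MarkerProfile, SpeciesTree, nuclear_profile

__all__ = ["GeneTree", "simulate_gene_genealogy", "msc_log_density",
           "write_newick_set"]


class GeneTree:
    """Array-backed rooted genealogy.

    Tips are nodes ``0..n_tips-1`` with labels ``"<species>_<i>"``; ages
    are in substitutions/site at the locus rate; ``species[i]`` is the
    species index (into the species tree's labels) for tip ``i``.
    """

    def __init__(self, labels: Sequence[str], species: Sequence[int],
                 parent: Sequence[int], age: Sequence[float],
                 locus: Optional[MarkerProfile] = None):
        self.labels = list(labels)
        self.species = np.asarray(species, dtype=np.int64).copy()
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.age = np.asarray(age, dtype=float).copy()
        self.locus = locus
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> List[List[int]]:
        ch: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def tip_mask(self, node: int) -> int:
        """Bitmask over species indices of the tips below ``node``."""
        ch = self.children()
        mask = 0
        stack = [node]
        while stack:
            v = stack.pop()
            if not ch[v]:
                mask |= 1 << int(self.species[v])
            else:
                stack.extend(ch[v])
        return mask

    def mrca_age(self, species_names: Sequence[str],
                 species_labels: Sequence[str]) -> float:
        """Age of the MRCA of every tip belonging to ``species_names``."""
        want = {species_labels.index(s) for s in species_names}
        tips = [i for i in range(self.n_tips) if self.species[i] in want]
        if not tips:
            raise ValueError(f"no tips for species {species_names}")
        if len(tips) == 1:
            return 0.0
        anc = set()
        v = tips[0]
        while v >= 0:
            anc.add(v)
            v = self.parent[v]
        mrca = tips[0]
        for t in tips[1:]:
            v = t
            while v not in anc:
                v = self.parent[v]
            if self.age[v] > self.age[mrca]:
                mrca = v
        return float(self.age[mrca])

    @property
    def tmrca(self) -> float:
        """Age of the root (0 for a single-tip tree)."""
        return float(self.age[self.root])

    def newick(self) -> str:
        ch = self.children()

        def rec(v: int) -> str:
            p = self.parent[v]
            blen = "" if p < 0 else f":{self.age[p] - self.age[v]:.10g}"
            if not ch[v]:
                return f"{self.labels[v]}{blen}"
            return "(" + ",".join(rec(c) for c in ch[v]) + f"){blen}"

        return rec(self.root) + ";"

    def to_dendropy(self):
        import dendropy
        return dendropy.Tree.get(data=self.newick(), schema="newick")


def simulate_gene_genealogy(tree: SpeciesTree, locus: MarkerProfile,
                            samples: Dict[str, int],
                            rng_seed) -> GeneTree:
    """Simulate one gene genealogy under the MSC within ``tree``.

    ``samples`` maps species labels to the number of sampled gene copies;
    ``rng_seed`` is an integer seed or a numpy Generator.  Deterministic
    given the seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    if not samples or not isinstance(samples, dict):
        raise ValueError("samples must be a non-empty mapping")
    for sp, k in samples.items():
        if sp not in tree.labels:
            raise ValueError(f"unknown species {sp!r}")
        if k < 0 or int(k) != k:
            raise ValueError("sample counts must be non-negative integers")
    n = int(sum(samples.values()))
    if n < 1:
        raise ValueError("at least one lineage is required")

    labels: List[str] = []
    species: List[int] = []
    for sp in tree.labels:
        for i in range(samples.get(sp, 0)):
            labels.append(f"{sp}_{i + 1}")
            species.append(tree.species_index(sp))

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    h = locus.heredity_multiplier
    nxt = n  # next internal node index

    # species-tree nodes in increasing age (children always precede parents)
    order = sorted(range(tree.n_nodes), key=lambda v: tree.age[v])
    pools: Dict[object, List[int]] = {}
    for i, sp_idx in enumerate(species):
        pools.setdefault(sp_idx, []).append(i)

    for v in order:
        active = pools.pop(v, [])
        for c in tree.children[v]:
            active.extend(pools.pop(f"done{c}", []))
        theta_eff = h * tree.theta[v]
        lo = tree.age[v]
        hi = math.inf if v == tree.root else tree.age[tree.parent[v]]
        t = lo
        while len(active) >= 2:
            j = len(active)
            rate = j * (j - 1) / theta_eff
            t = t + rng.exponential(1.0 / rate)
            if t >= hi:
                break
            i1, i2 = rng.choice(j, size=2, replace=False)
            a, b = active[i1], active[i2]
            parent[a] = nxt
            parent[b] = nxt
            age[nxt] = t
            active = [x for k, x in enumerate(active) if k not in (i1, i2)]
            active.append(nxt)
            nxt += 1
        pools[f"done{v}"] = active

    age *= locus.rate_multiplier  # locus substitution scale
    return GeneTree(labels, species, parent, age, locus)


def msc_log_density(g: GeneTree, tree: SpeciesTree,
                    locus: Optional[MarkerProfile] = None) -> float:
    """Log density of a gene genealogy under the MSC.

    Per population the density contributes ``(2/theta_locus)
    exp(-j(j-1)/theta_locus * dt)`` per coalescent event and interval, plus
    the survival term for intervals ending at population boundaries.  A
    genealogy violating a population age constraint (a cross-species
    coalescence younger than the species split) yields ``-inf`` rather
    than raising, so MCMC kernels can simply reject.
    """
    locus = locus or g.locus or nuclear_profile()
    r = locus.rate_multiplier
    h = locus.heredity_multiplier
    tau = tree.age * r  # species boundaries on the locus scale
    ch = g.children()
    tol = 1e-12

    # species-composition bitmask of every gene node, bottom-up
    mask = np.zeros(g.n_nodes, dtype=np.int64)
    order = np.argsort(g.age, kind="stable")
    for v in order:
        if not ch[v]:
            mask[v] = 1 << int(g.species[v])
        else:
            mask[v] = mask[ch[v][0]] | mask[ch[v][1]]

    # host population of each internal node
    host = np.full(g.n_nodes, -1, dtype=np.int64)
    for v in range(g.n_tips, g.n_nodes):
        p = tree.mrca_node(int(mask[v]))
        if g.age[v] < tau[p] - tol:
            return -math.inf
        while p != tree.root and tau[tree.parent[p]] <= g.age[v]:
            p = tree.parent[p]
        host[v] = p

    # tips per species
    tip_counts = np.zeros(tree.n_species, dtype=np.int64)
    for i in range(g.n_tips):
        tip_counts[g.species[i]] += 1

    internal_ages = g.age[g.n_tips:]
    internal_masks = mask[g.n_tips:]
    logd = 0.0
    for p in range(tree.n_nodes):
        clade = tree.mask[p]
        lo = tau[p]
        hi = math.inf if p == tree.root else tau[tree.parent[p]]
        tips_in = int(sum(tip_counts[s] for s in range(tree.n_species)
                          if clade >> s & 1))
        if tips_in == 0:
            continue
        below = int(np.sum((internal_ages < lo - tol)
                           & ((internal_masks & ~clade) == 0)))
        j = tips_in - below
        theta_eff = h * r * tree.theta[p]
        ev = sorted(g.age[v] for v in range(g.n_tips, g.n_nodes)
                    if host[v] == p)
        t = lo
        for te in ev:
            if j < 2:
                return -math.inf
            logd += math.log(2.0 / theta_eff) - j * (j - 1) / theta_eff * (te - t)
            j -= 1
            t = te
        if hi < math.inf and j >= 2:
            logd += -j * (j - 1) / theta_eff * (hi - t)
    return logd


def write_newick_set(trees: Sequence[GeneTree], path: str) -> None:
    """Write a replicate set of gene trees, one Newick string per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")
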