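"""Gene-tree estimation, molecular-clock dating and rescaling.

The estimation pipeline mirrors a standard ML-phylogeny + clock workflow
at distribution level: per-partition maximum-likelihood pairwise distances
under K80+Gamma (HKY with the equal base frequencies of the simulation),
combined across partitions weighted by length, neighbor-joining on the
combined matrix, outgroup rooting, Poisson-likelihood (Langley-Fitch)
single-rate ultrametricization and a least-squares-through-origin
branch-length rescale (the scalar that minimises the K-score against the
original non-clock tree).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from sklearn.base import BaseEstimator

from .seqsim import Alignment, discrete_gamma_rates, k80_transition_probs, \
    _TI_PARTNER

__all__ = ["EstimatedGeneTree", "GeneTreeEstimator", "estimate_gene_tree",
           "ml_pairwise_distance", "langley_fitch_clock", "kscore_rescale",
           "tmrca_sp1_sp2", "tau_prior_mean"]

_JC_SATURATION = 0.749  # p-distance beyond which even JC is undefined


class EstimatedGeneTree:
    """Rooted estimated tree: branch lengths, optional ultrametric ages.

    Tips ``0..n_tips-1`` (labelled ``"<species>_<i>"``), arrays indexed by
    node: ``parent``, ``length`` (branch above the node; the root's entry
    is 0) and, after clock fitting, ``age``.  ``scale_factor`` records the
    K-score rescale applied, ``flags`` any estimation warnings.
    """

    def __init__(self, labels: Sequence[str], parent: Sequence[int],
                 length: Sequence[float], age: Optional[Sequence[float]] = None,
                 scale_factor: float = 1.0, flags: Optional[set] = None):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.length = np.asarray(length, dtype=float).copy()
        self.age = None if age is None else np.asarray(age, dtype=float).copy()
        self.scale_factor = scale_factor
        self.flags = set() if flags is None else set(flags)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        if np.any(self.length < 0):
            raise ValueError("branch lengths must be >= 0")

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> List[List[int]]:
        ch: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def species_of_tip(self, i: int) -> str:
        return self.labels[i].rsplit("_", 1)[0]

    def copy(self) -> "EstimatedGeneTree":
        return EstimatedGeneTree(self.labels, self.parent, self.length,
                                 self.age, self.scale_factor, self.flags)

    def mrca(self, tips: Sequence[int]) -> int:
        anc = set()
        v = tips[0]
        while v >= 0:
            anc.add(v)
            v = self.parent[v]
        mrca = tips[0]
        ref = None
        for t in tips[1:]:
            v = t
            while v not in anc:
                v = self.parent[v]
            ref = v if ref is None else (v if self._is_ancestor(ref, v) else ref)
        if ref is None:
            return tips[0]
        return ref

    def _is_ancestor(self, a: int, b: int) -> bool:
        """True if b is an ancestor of a (or equal)."""
        v = a
        while v >= 0:
            if v == b:
                return True
            v = self.parent[v]
        return False

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        if self.age is None:
            return False
        return bool(np.all(np.abs(self.age[:self.n_tips]) <= tol))

    def newick(self) -> str:
        ch = self.children()

        def rec(v: int) -> str:
            blen = "" if self.parent[v] < 0 else f":{self.length[v]:.10g}"
            if not ch[v]:
                return f"{self.labels[v]}{blen}"
            return "(" + ",".join(rec(c) for c in ch[v]) + f"){blen}"

        return rec(self.root) + ";"

    def to_dendropy(self):
        import dendropy
        return dendropy.Tree.get(data=self.newick(), schema="newick")


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

def _pair_counts(data: np.ndarray, i: int, j: int) -> Tuple[int, int, int]:
    a, b = data[i], data[j]
    same = int(np.sum(a == b))
    ti = int(np.sum(_TI_PARTNER[a] == b))
    tv = a.shape[0] - same - ti
    return same, ti, tv


def ml_pairwise_distance(n_same: int, n_ti: int, n_tv: int, kappa: float,
                         gamma_shape: float, n_categories: int = 4,
                         max_distance: float = 5.0) -> Tuple[float, bool]:
    """ML distance under K80 + discrete Gamma from pattern counts.

    Returns ``(distance, saturated)``.  When the raw proportion of
    differing sites reaches the JC saturation bound (0.749) the distance
    is capped at ``max_distance`` and flagged.
    """
    n = n_same + n_ti + n_tv
    if n == 0:
        raise ValueError("empty alignment")
    p = (n_ti + n_tv) / n
    if p >= _JC_SATURATION:
        return max_distance, True
    if p == 0.0:
        return 0.0, False
    rates = discrete_gamma_rates(gamma_shape, n_categories)

    def nll(d):
        ps, pti, ptv = k80_transition_probs(d * rates, kappa)
        ps, pti, ptv = ps.mean(), pti.mean(), (2.0 * ptv).mean()
        return -(n_same * math.log(ps) + n_ti * math.log(max(pti, 1e-300))
                 + n_tv * math.log(max(ptv, 1e-300)))

    res = minimize_scalar(nll, bounds=(1e-9, max_distance), method="bounded",
                          options={"xatol": 1e-10})
    d = float(res.x)
    saturated = d >= max_distance * 0.999
    return (max_distance if saturated else d), saturated


def _distance_matrix(alignments: Sequence[Alignment],
                     max_distance: float) -> Tuple[np.ndarray, List[str], set]:
    labels = list(alignments[0].labels)
    for a in alignments[1:]:
        if set(a.labels) != set(labels):
            raise ValueError("alignments must share one tip set")
    n = len(labels)
    if n < 4:
        raise ValueError("at least 4 tips are required")
    D = np.zeros((n, n))
    flags: set = set()
    total_len = sum(a.length for a in alignments)
    for a in alignments:
        prof = a.locus
        if prof is None:
            raise ValueError("alignment lacks a marker profile")
        idx = [a.labels.index(lab) for lab in labels]
        data = a.data[idx]
        w = a.length / total_len
        for i in range(n):
            for j in range(i + 1, n):
                s, ti, tv = _pair_counts(data, i, j)
                d, sat = ml_pairwise_distance(s, ti, tv, prof.kappa,
                                              prof.gamma_shape,
                                              prof.n_categories, max_distance)
                if sat:
                    flags.add("saturated")
                D[i, j] += w * d
                D[j, i] = D[i, j]
    return D, labels, flags


# ---------------------------------------------------------------------------
# neighbor joining + outgroup rooting
# ---------------------------------------------------------------------------

def _nj_rooted(D: np.ndarray, labels: List[str],
               outgroup: str) -> EstimatedGeneTree:
    """NJ via scikit-bio, negative branch lengths clamped, outgroup-rooted."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    ids = [f"t{i}" for i in range(len(labels))]  # avoid label quirks
    tree = skbio_nj(DistanceMatrix(D, ids))

    # undirected adjacency
    adj: Dict[int, List[Tuple[int, float]]] = {}
    names: Dict[int, str] = {}
    idx_of = {}

    def vid(node):
        if id(node) not in idx_of:
            idx_of[id(node)] = len(idx_of)
        return idx_of[id(node)]

    for node in tree.traverse():
        v = vid(node)
        if node.is_tip():
            names[v] = labels[ids.index(node.name)]
        if node.parent is not None:
            u = vid(node.parent)
            w = max(float(node.length or 0.0), 0.0)
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        else:
            adj.setdefault(v, [])

    og_vertex = next(v for v, nm in names.items() if nm == outgroup)
    (nb, og_len), = adj[og_vertex]

    # orient away from a new root on the outgroup edge
    n_tips_total = len(labels)
    new_labels: List[str] = []
    parent: List[int] = []
    length: List[float] = []
    node_of_vertex: Dict[int, int] = {}
    internal_records: List[Tuple[int, float]] = []  # (parent node, length)
    tip_records: List[Tuple[str, int, float]] = []

    def walk(v: int, par_vertex: int, blen: float, par_node: int):
        kids = [(w, l) for w, l in adj[v] if w != par_vertex]
        if not kids:  # tip
            tip_records.append((names[v], par_node, blen))
            return
        if len(kids) == 1:  # suppress degree-2 vertex
            w, l = kids[0]
            walk(w, v, blen + l, par_node)
            return
        internal_records.append((par_node, blen))
        me = len(internal_records) - 1
        for w, l in kids:
            walk(w, v, l, me)

    internal_records.append((-2, 0.0))  # new root placeholder (index 0)
    tip_records.append((outgroup, 0, og_len / 2.0))
    walk(nb, og_vertex, og_len / 2.0, 0)

    n_int = len(internal_records)
    n_tip = len(tip_records)
    order = {nm: k for k, nm in enumerate(labels)}
    tip_records.sort(key=lambda rec: order[rec[0]])
    parent_arr = np.full(n_tip + n_int, -1, dtype=np.int64)
    length_arr = np.zeros(n_tip + n_int)
    lab_list = [rec[0] for rec in tip_records]
    for k, (nm, pn, l) in enumerate(tip_records):
        parent_arr[k] = n_tip + pn
        length_arr[k] = l
    for k, (pn, l) in enumerate(internal_records):
        parent_arr[n_tip + k] = -1 if pn == -2 else n_tip + pn
        length_arr[n_tip + k] = l
    return EstimatedGeneTree(lab_list, parent_arr, length_arr)


# ---------------------------------------------------------------------------
# Langley-Fitch clock
# ---------------------------------------------------------------------------

def langley_fitch_clock(t: EstimatedGeneTree,
                        site_counts: float | Sequence[float] = 1000.0,
                        tol: float = 1e-10,
                        max_sweeps: int = 500) -> EstimatedGeneTree:
    """Single-rate Poisson-likelihood (Langley-Fitch) ultrametricization.

    Branch substitution counts ``n_b = length_b * L_b`` are Poisson with
    mean ``duration_b * L_b`` (rate absorbed into the age scale, so ages
    come out in substitutions/site).  The two root-child branches are
    merged into one observation because the root position along that path
    is unidentifiable under a clock.  Concave in the node ages, solved by
    coordinate ascent to a log-likelihood improvement below ``tol``.
    """
    if np.all(t.parent >= 0):
        raise ValueError("rooted tree required")
    ch = t.children()
    root = t.root
    n = t.n_nodes
    L = np.full(n, float(site_counts)) if np.isscalar(site_counts) \
        else np.asarray(site_counts, dtype=float)
    counts = t.length * L

    if np.all(counts[np.arange(n) != root] <= 0):
        out = t.copy()
        out.age = np.zeros(n)
        out.length = np.zeros(n)
        out.flags.add("zero_divergence")
        return out

    # initial ages: average path length to descendant tips
    age = np.zeros(n)
    post = _postorder(t.parent, ch, root)
    ntips_below = np.zeros(n)
    pathsum = np.zeros(n)
    for v in post:
        if not ch[v]:
            ntips_below[v] = 1
        else:
            for c in ch[v]:
                ntips_below[v] += ntips_below[c]
                pathsum[v] += pathsum[c] + t.length[c] * ntips_below[c]
            age[v] = max(pathsum[v] / ntips_below[v],
                         max(age[c] for c in ch[v]) * (1 + 1e-9) + 1e-12)

    rc = ch[root]
    Lm = (L[rc[0]] + L[rc[1]]) / 2.0  # effective length of merged root edge
    n_merged = counts[rc[0]] + counts[rc[1]]
    eps = 1e-15

    def loglik() -> float:
        ll = 0.0
        for v in range(n):
            if v == root or v in rc:
                continue
            mu = (age[t.parent[v]] - age[v]) * L[v]
            ll += (counts[v] * math.log(max(mu, eps)) - mu)
        s = age[rc[0]] + age[rc[1]]
        mu = (2 * age[root] - s) * Lm
        ll += n_merged * math.log(max(mu, eps)) - mu
        return ll

    internal = [v for v in post if ch[v]]
    prev = loglik()
    for _ in range(max_sweeps):
        for v in internal:
            lo = max((age[c] for c in ch[v]), default=0.0)
            if v == root:
                s = age[rc[0]] + age[rc[1]]
                cand = (s + n_merged / Lm) / 2.0
                age[v] = max(cand, lo + eps)
                continue
            hi = age[t.parent[v]]
            up_to_root = t.parent[v] == root
            if up_to_root:
                sib = rc[0] if rc[1] == v else rc[1]

            def grad(a):
                g = 0.0
                for c in ch[v]:
                    g += counts[c] / max(a - age[c], eps) - L[c]
                if up_to_root:
                    g -= n_merged / max(2 * age[root] - a - age[sib], eps) \
                        - Lm
                else:
                    g -= counts[v] / max(hi - a, eps) - L[v]
                return g

            a_lo, a_hi = lo + 1e-14, hi - 1e-14
            if a_lo >= a_hi:
                age[v] = (lo + hi) / 2.0
                continue
            g_lo, g_hi = grad(a_lo), grad(a_hi)
            if g_lo <= 0:
                age[v] = a_lo
            elif g_hi >= 0:
                age[v] = a_hi
            else:
                age[v] = brentq(grad, a_lo, a_hi, xtol=1e-15)
        cur = loglik()
        if cur - prev < tol:
            break
        prev = cur

    out = t.copy()
    out.age = age - age[:t.n_tips].max()  # tips at exactly 0
    out.age[:t.n_tips] = 0.0
    out.length = np.zeros(n)
    for v in range(n):
        if t.parent[v] >= 0:
            out.length[v] = max(out.age[t.parent[v]] - out.age[v], 0.0)
    return out


def _postorder(parent, ch, root) -> List[int]:
    order: List[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(ch[v])
    order.reverse()
    return order


# ---------------------------------------------------------------------------
# K-score rescaling
# ---------------------------------------------------------------------------

def kscore_rescale(clock_tree: EstimatedGeneTree,
                   reference: EstimatedGeneTree) -> EstimatedGeneTree:
    """Rescale a clock tree by the K-score-minimising scalar.

    ``k* = sum(b_ref * b_clock) / sum(b_clock^2)`` over matched branches —
    the least-squares-through-origin slope; the two root-child branches are
    compared as one combined pair (root placement on that path is
    arbitrary under the clock).
    """
    if clock_tree.n_nodes != reference.n_nodes or \
            clock_tree.labels != reference.labels:
        raise ValueError("trees must share tips and topology")
    rc = clock_tree.children()[clock_tree.root]
    num = 0.0
    den = 0.0
    for v in range(clock_tree.n_nodes):
        if v == clock_tree.root or v in rc:
            continue
        num += reference.length[v] * clock_tree.length[v]
        den += clock_tree.length[v] ** 2
    b_ref = reference.length[rc[0]] + reference.length[rc[1]]
    b_clk = clock_tree.length[rc[0]] + clock_tree.length[rc[1]]
    num += b_ref * b_clk
    den += b_clk ** 2
    if den <= 0:
        raise ValueError("clock tree has all-zero branch lengths")
    k = num / den
    out = clock_tree.copy()
    out.length = clock_tree.length * k
    if out.age is not None:
        out.age = clock_tree.age * k
    out.scale_factor = k
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def tmrca_sp1_sp2(ultra: EstimatedGeneTree, u: float,
                  species: Tuple[str, str] = ("sp1", "sp2")) -> float:
    """Age of the MRCA of all sp1 and sp2 tips, converted to Myr.

    ``u`` is the per-lineage rate in substitutions/site/Myr on the scale
    of the tree (for concatenations, the length-weighted mean rate).
    """
    if ultra.age is None:
        raise ValueError("ultrametric (clock) tree required")
    tips = [i for i in range(ultra.n_tips)
            if ultra.species_of_tip(i) in species]
    present = {ultra.species_of_tip(i) for i in tips}
    if set(species) - present:
        raise ValueError(f"missing species {set(species) - present}")
    node = ultra.mrca(tips)
    return float(ultra.age[node]) / u


def tau_prior_mean(gene_trees: Sequence[EstimatedGeneTree],
                   rate_ratio: float = 1.0,
                   species: Tuple[str, str] = ("sp1", "sp2")) -> float:
    """Mean (across trees) minimum sp1-sp2 divergence, nuclear scale.

    Per tree: the minimum over cross-species tip pairs of their MRCA age
    (half the minimum patristic distance on an ultrametric tree); divided
    by ``rate_ratio`` when the trees are on a faster (e.g. mitochondrial)
    scale.
    """
    if not gene_trees:
        raise ValueError("empty gene-tree list")
    vals = []
    for t in gene_trees:
        if t.age is None:
            raise ValueError("ultrametric trees required")
        a = [i for i in range(t.n_tips) if t.species_of_tip(i) == species[0]]
        b = [i for i in range(t.n_tips) if t.species_of_tip(i) == species[1]]
        if not a or not b:
            raise ValueError("trees must contain both species")
        best = math.inf
        for i in a:
            for j in b:
                best = min(best, t.age[t.mrca([i, j])])
        vals.append(best)
    return float(np.mean(vals)) / rate_ratio


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GeneTreeEstimator(BaseEstimator):
    """Distance-ML + NJ + Langley-Fitch + K-score gene-tree estimator.

    Parameters
    ----------
    outgroup : str or None
        Species used for rooting; default picks ``sp5`` when present,
        else ``sp4``.
    max_distance : float
        Cap for saturated pairwise distances.
    clock, rescale : bool
        Whether to ultrametricize and rescale.

    Attributes (after :meth:`fit`)
    ------------------------------
    nj_tree_, clock_tree_, tree_ : EstimatedGeneTree
    distance_matrix_ : ndarray
    scale_factor_ : float
    mean_rate_ : float
        Length-weighted mean per-lineage rate of the input loci
        (substitutions/site/Myr), used by :meth:`tmrca_myr`.
    flags_ : set of str
    """

    def __init__(self, outgroup: Optional[str] = None,
                 max_distance: float = 5.0, clock: bool = True,
                 rescale: bool = True):
        self.outgroup = outgroup
        self.max_distance = max_distance
        self.clock = clock
        self.rescale = rescale

    def fit(self, X, y=None):
        alignments = [X] if isinstance(X, Alignment) else list(X)
        if not alignments:
            raise ValueError("no alignments given")
        D, labels, flags = _distance_matrix(alignments, self.max_distance)
        self.distance_matrix_ = D
        if np.all(D == 0):
            flags.add("zero_divergence")
        species = {lab.rsplit("_", 1)[0] for lab in labels}
        og_species = self.outgroup or ("sp5" if "sp5" in species else "sp4")
        og_tips = [lab for lab in labels
                   if lab.rsplit("_", 1)[0] == og_species]
        if not og_tips:
            raise ValueError(f"outgroup {og_species!r} not in alignment")
        self.nj_tree_ = _nj_rooted(D, labels, og_tips[0])
        self.nj_tree_.flags |= flags
        total = sum(a.length for a in alignments)
        self.mean_rate_ = sum(a.locus.per_lineage_rate * a.length
                              for a in alignments) / total
        tree = self.nj_tree_
        if self.clock:
            site_counts = np.full(tree.n_nodes, float(total))
            self.clock_tree_ = langley_fitch_clock(tree, site_counts)
            tree = self.clock_tree_
            if self.rescale and "zero_divergence" not in tree.flags:
                tree = kscore_rescale(tree, self.nj_tree_)
        self.tree_ = tree
        self.scale_factor_ = tree.scale_factor
        self.flags_ = set(tree.flags) | flags
        return self

    def tmrca_myr(self, u: Optional[float] = None,
                  species: Tuple[str, str] = ("sp1", "sp2")) -> float:
        """sp1-sp2 MRCA age of the fitted clock tree in Myr."""
        return tmrca_sp1_sp2(self.tree_, u if u is not None
                             else self.mean_rate_, species)


def estimate_gene_tree(alignments, partitions=None,
                       outgroup: Optional[str] = None,
                       max_distance: float = 5.0) -> EstimatedGeneTree:
    """NJ tree from per-partition ML distances (thin estimator wrapper).

    ``partitions`` may supply per-alignment marker profiles when the
    alignments do not already carry one.
    """
    alignments = [alignments] if isinstance(alignments, Alignment) \
        else list(alignments)
    if partitions is not None:
        alignments = [Alignment(a.labels, a.data, p)
                      for a, p in zip(alignments, partitions)]
    est = GeneTreeEstimator(outgroup=outgroup, max_distance=max_distance,
                            clock=False).fit(alignments)
    return est.nj_tree_
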