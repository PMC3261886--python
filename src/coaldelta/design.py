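"""Species trees, marker profiles and the simulation condition grid.

All times and population-size parameters are kept internally in expected
substitutions per site *at the nuclear mean rate* ("nuclear scale").  A
mitochondrial locus differs from a nuclear one only through its marker
profile: a rate multiplier ``r`` (10 by default, mtDNA evolves an order of
magnitude faster than the autosomal mean in mammals) and a heredity
multiplier ``h`` (0.25, haploid and uniparental inheritance).  The
effective locus-scale population parameter is ``theta_locus = h * r *
theta_nuc``, which reproduces the empirical theta_mit = 2.5 * theta_nuc
bookkeeping used throughout (0.025 <-> 0.01 and 0.01 <-> 0.004).

Effective population sizes never appear as absolute numbers: branch
lengths specified in units of ``N_e`` generations are resolved through
``theta_nuc = 4 N_e mu_nuc``, i.e. ``g * N_e`` generations equal
``(g / 4) * theta_nuc`` nuclear substitutions per site.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "MarkerProfile",
    "SpeciesTree",
    "StudyCondition",
    "mitochondrial_profile",
    "nuclear_profile",
    "build_focal_tree",
    "build_radiation_tree",
    "convert_units",
    "paper_grid",
    "load_condition_grid",
    "dump_condition_grid",
]

_UNITS = ("Myr", "generations_Ne", "coalescent_units", "subs_per_site")


@dataclass(frozen=True)
class MarkerProfile:
    """Per-locus evolutionary contract.

    Parameters are dimensionless multipliers relative to the nuclear mean
    (``rate_multiplier``, ``heredity_multiplier``), the HKY
    transition/transversion rate ratio ``kappa``, the discrete-Gamma shape
    ``gamma_shape`` with ``n_categories`` equal-probability categories, the
    locus length in base pairs and the absolute per-lineage substitution
    rate ``per_lineage_rate`` in substitutions/site/Myr.
    """

    marker_class: str  # "mitochondrial" | "nuclear"
    rate_multiplier: float
    heredity_multiplier: float
    kappa: float
    gamma_shape: float = 1.0
    n_categories: int = 4
    length: int = 1000
    per_lineage_rate: float = 0.001
    name: str = ""

    def __post_init__(self):
        if self.marker_class not in ("mitochondrial", "nuclear"):
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        for attr in ("rate_multiplier", "heredity_multiplier", "kappa",
                     "gamma_shape", "per_lineage_rate"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")

    def effective_theta(self, theta_nuc: float) -> float:
        """Locus-scale theta: h * r * theta_nuc."""
        return self.heredity_multiplier * self.rate_multiplier * theta_nuc


def mitochondrial_profile(u_mit: float = 0.01, length: int = 1000,
                          kappa: float = 10.0, gamma_shape: float = 1.0,
                          name: str = "mit") -> MarkerProfile:
    """Default mitochondrial marker: r=10, h=0.25, kappa=10."""
    return MarkerProfile("mitochondrial", rate_multiplier=10.0,
                         heredity_multiplier=0.25, kappa=kappa,
                         gamma_shape=gamma_shape, length=length,
                         per_lineage_rate=u_mit, name=name)


def nuclear_profile(u_nuc: float = 0.001, rate_multiplier: float = 1.0,
                    length: int = 1000, kappa: float = 2.0,
                    gamma_shape: float = 1.0, name: str = "nuc") -> MarkerProfile:
    """Default nuclear marker: h=1, kappa=2.

    ``rate_multiplier`` may deviate from 1 (the among-loci rate-variation
    experiment draws it uniformly in [0.7, 1.4]); ``per_lineage_rate`` is
    the realised locus rate, i.e. the nuclear mean times the multiplier.
    """
    return MarkerProfile("nuclear", rate_multiplier=rate_multiplier,
                         heredity_multiplier=1.0, kappa=kappa,
                         gamma_shape=gamma_shape, length=length,
                         per_lineage_rate=u_nuc * rate_multiplier, name=name)


class SpeciesTree:
    """Rooted binary species tree with node ages and per-population theta.

    Array-backed: nodes ``0..n_species-1`` are tips (in the order of
    ``labels``), internal nodes follow, the root is the node with parent
    ``-1``.  ``age[i]`` is the node age and ``theta[i]`` the population
    parameter of the branch *above* node ``i`` (the root's entry is the
    ancestral root population, which extends to infinity).  Ages and thetas
    are in nuclear-scale substitutions/site.
    """

    def __init__(self, labels: Sequence[str], parent: Sequence[int],
                 age: Sequence[float], theta: Sequence[float]):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.age = np.asarray(age, dtype=float).copy()
        self.theta = np.asarray(theta, dtype=float).copy()
        self.n_species = len(self.labels)
        self.n_nodes = 2 * self.n_species - 1
        if len(self.parent) != self.n_nodes:
            raise ValueError("parent array has wrong length")
        self._rebuild()
        self.validate()

    # -- structure ---------------------------------------------------------
    def _rebuild(self):
        """Recompute children lists, clade bitmasks and traversal orders."""
        n = self.n_nodes
        children: List[List[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                children[p].append(i)
        self.children = children
        self.root = root
        # postorder
        order: List[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        order.reverse()
        self.postorder = np.array(order, dtype=np.int64)
        mask = np.zeros(n, dtype=np.int64)
        for v in order:
            if not children[v]:
                mask[v] = 1 << v
            else:
                m = 0
                for c in children[v]:
                    m |= mask[c]
                mask[v] = m
        self.mask = mask
        self._mrca_cache: Dict[int, int] = {}

    def validate(self):
        for v in range(self.n_nodes):
            if self.children[v]:
                if len(self.children[v]) != 2:
                    raise ValueError("tree must be binary")
                for c in self.children[v]:
                    if not self.age[v] > self.age[c]:
                        raise ValueError(
                            f"parent age {self.age[v]} not greater than "
                            f"child age {self.age[c]}")
            else:
                if self.age[v] != 0:
                    raise ValueError("tip ages must be 0")
        if np.any(self.theta <= 0):
            raise ValueError("all theta must be > 0")
        if np.any(self.age < 0):
            raise ValueError("all ages must be >= 0")

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self.labels, self.parent, self.age, self.theta)

    def species_index(self, label: str) -> int:
        return self.labels.index(label)

    def mrca_node(self, species_mask: int) -> int:
        """Lowest node whose clade contains every species in the bitmask."""
        node = self._mrca_cache.get(species_mask)
        if node is not None:
            return node
        # start from any species in the mask and walk up
        i = (species_mask & -species_mask).bit_length() - 1
        node = i
        while species_mask & ~self.mask[node]:
            node = self.parent[node]
        self._mrca_cache[species_mask] = node
        return node

    def mrca_age(self, species_mask: int) -> float:
        return float(self.age[self.mrca_node(species_mask)])

    def topology_key(self) -> str:
        """Canonical string identifying the rooted topology (labels only)."""

        def rec(v: int) -> str:
            if not self.children[v]:
                return self.labels[v]
            parts = sorted(rec(c) for c in self.children[v])
            return "(" + ",".join(parts) + ")"

        return rec(self.root)

    def clades(self) -> List[frozenset]:
        """Non-trivial rooted clades (species label sets)."""
        out = []
        for v in range(self.n_nodes):
            if self.children[v] and v != self.root:
                out.append(frozenset(self.labels[i]
                                     for i in range(self.n_species)
                                     if self.mask[v] >> i & 1))
        return out

    # -- serialisation -----------------------------------------------------
    def newick(self, annotate: bool = True) -> str:
        def rec(v: int) -> str:
            blen = "" if v == self.root else \
                f":{self.age[self.parent[v]] - self.age[v]:.10g}"
            comment = f"[&theta={self.theta[v]:.10g}]" if annotate else ""
            if not self.children[v]:
                return f"{self.labels[v]}{comment}{blen}"
            inner = ",".join(rec(c) for c in self.children[v])
            return f"({inner}){comment}{blen}"

        return rec(self.root) + ";"

    @classmethod
    def from_nested(cls, topology, ages: Dict[frozenset, float],
                    theta) -> "SpeciesTree":
        """Build from a nested-tuple topology, e.g. ((("sp1","sp2"),"sp3"),"sp4").

        ``ages`` maps frozensets of species labels to node ages; ``theta``
        is either a scalar (constant) or a mapping from frozensets (clades,
        incl. singletons and the full set) to values.
        """
        labels: List[str] = []

        def collect(t):
            if isinstance(t, str):
                labels.append(t)
            else:
                for s in t:
                    collect(s)

        collect(topology)
        n = len(labels)
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        age = np.zeros(2 * n - 1)
        th = np.zeros(2 * n - 1)
        counter = [n]

        def build(t) -> Tuple[int, frozenset]:
            if isinstance(t, str):
                i = labels.index(t)
                clade = frozenset([t])
            else:
                i = counter[0]
                counter[0] += 1
                kids = [build(s) for s in t]
                clade = frozenset().union(*(c for _, c in kids))
                for j, _ in kids:
                    parent[j] = i
                age[i] = ages[clade]
            if np.isscalar(theta):
                th[i] = theta
            else:
                th[i] = theta[clade]
            return i, clade

        build(topology)
        return cls(labels, parent, age, th)


def convert_units(value: float, src: str, dst: str, *,
                  profile: Optional[MarkerProfile] = None,
                  theta_nuc: Optional[float] = None) -> float:
    """Convert between Myr, N_e-generations, coalescent units and subs/site.

    ``subs_per_site`` is on the *locus* rate scale of ``profile`` (for the
    default nuclear profile with multiplier 1 this is the nuclear scale).
    ``generations_Ne`` counts multiples of N_e generations; the identity
    theta_nuc = 4 N_e mu_nuc makes ``g`` N_e generations equal
    ``(g/4) * theta_nuc`` nuclear substitutions/site (times the locus rate
    multiplier on the locus scale).  Coalescent units for a locus are
    ``2 t / theta_locus`` (pairwise coalescence rate 2/theta).
    """
    if src not in _UNITS or dst not in _UNITS:
        raise ValueError(f"units must be one of {_UNITS}")
    if src == dst:
        return value
    if profile is None:
        profile = nuclear_profile()

    def to_subs(v: float, unit: str) -> float:
        if unit == "subs_per_site":
            return v
        if unit == "Myr":
            return v * profile.per_lineage_rate
        if theta_nuc is None:
            raise ValueError(f"theta_nuc context required for {unit}")
        if unit == "generations_Ne":
            return v / 4.0 * theta_nuc * profile.rate_multiplier
        # coalescent_units
        return v * profile.effective_theta(theta_nuc) / 2.0

    def from_subs(v: float, unit: str) -> float:
        if unit == "subs_per_site":
            return v
        if unit == "Myr":
            return v / profile.per_lineage_rate
        if theta_nuc is None:
            raise ValueError(f"theta_nuc context required for {unit}")
        if unit == "generations_Ne":
            return v * 4.0 / (theta_nuc * profile.rate_multiplier)
        return v * 2.0 / profile.effective_theta(theta_nuc)

    return from_subs(to_subs(value, src), dst)


def build_focal_tree(theta_mit: float, u_mit: float,
                     tau1_myr: float) -> SpeciesTree:
    """The 4-taxon asymmetric tree (((sp1,sp2),sp3),sp4), nuclear scale.

    tau1 = tau1_myr * u_nuc with u_nuc = u_mit / 10; the internal branches
    x (tau1..tau2) and y (tau2..tau3) are 4 N_e and 8 N_e generations,
    i.e. theta_nuc and 2 theta_nuc substitutions/site; theta is constant
    (= theta_mit / 2.5) on every population.
    """
    if theta_mit <= 0 or u_mit <= 0 or tau1_myr <= 0:
        raise ValueError("theta_mit, u_mit and tau1_myr must be positive")
    theta_nuc = theta_mit / 2.5
    u_nuc = u_mit / 10.0
    tau1 = tau1_myr * u_nuc
    x = convert_units(4.0, "generations_Ne", "subs_per_site",
                      theta_nuc=theta_nuc)
    y = convert_units(8.0, "generations_Ne", "subs_per_site",
                      theta_nuc=theta_nuc)
    f = frozenset
    ages = {f(["sp1", "sp2"]): tau1,
            f(["sp1", "sp2", "sp3"]): tau1 + x,
            f(["sp1", "sp2", "sp3", "sp4"]): tau1 + x + y}
    return SpeciesTree.from_nested(((("sp1", "sp2"), "sp3"), "sp4"),
                                   ages, theta_nuc)


_RADIATION = {"moderate": (0.5, 1.6), "fast": (0.1, 0.2)}


def build_radiation_tree(scenario: str, theta_nuc: float = 0.01) -> SpeciesTree:
    """5-taxon radiation tree ((((sp1,sp2),sp3),sp4),sp5), nuclear scale.

    The sp1-sp2 split sits at 8 N_e generations and the sp5 stem branch is
    12 N_e; the two internal branches x and y are (0.5, 1.6) N_e for the
    moderate radiation and (0.1, 0.2) N_e for the fast one (the latter well
    inside the anomaly zone).
    """
    if scenario not in _RADIATION:
        raise ValueError(f"unknown scenario {scenario!r}")
    if theta_nuc <= 0:
        raise ValueError("theta_nuc must be > 0")
    x_ne, y_ne = _RADIATION[scenario]
    g = lambda v: convert_units(v, "generations_Ne", "subs_per_site",
                                theta_nuc=theta_nuc)
    tau1 = g(8.0)
    tau2 = tau1 + g(x_ne)
    tau3 = tau2 + g(y_ne)
    tau4 = tau3 + g(12.0)
    f = frozenset
    ages = {f(["sp1", "sp2"]): tau1,
            f(["sp1", "sp2", "sp3"]): tau2,
            f(["sp1", "sp2", "sp3", "sp4"]): tau3,
            f(["sp1", "sp2", "sp3", "sp4", "sp5"]): tau4}
    return SpeciesTree.from_nested((((("sp1", "sp2"), "sp3"), "sp4"), "sp5"),
                                   ages, theta_nuc)


@dataclass
class StudyCondition:
    """One cell of the simulation grid."""

    theta_mit: float
    u_mit: float
    tau1_myr: float
    strategy: List[MarkerProfile]
    n_per_species: int = 5
    n_replicates: int = 50
    name: str = ""

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def theta_nuc(self) -> float:
        return self.theta_mit / 2.5

    @property
    def u_nuc(self) -> float:
        return self.u_mit / 10.0

    def species_tree(self) -> SpeciesTree:
        return build_focal_tree(self.theta_mit, self.u_mit, self.tau1_myr)


def marker_strategy(name: str, u_mit: float, length: int = 1000) -> List[MarkerProfile]:
    """Named multilocus strategies: '1mit', '1mit+4nuc', '5nuc', '10nuc'."""
    u_nuc = u_mit / 10.0
    mit = [mitochondrial_profile(u_mit, length=length)]
    nuc = lambda k: [nuclear_profile(u_nuc, length=length, name=f"nuc{i+1}")
                     for i in range(k)]
    table = {"1mit": mit,
             "1mit+4nuc": mit + nuc(4),
             "4nuc+1mit": mit + nuc(4),
             "5nuc": nuc(5),
             "10nuc": nuc(10)}
    if name not in table:
        raise ValueError(f"unknown strategy {name!r}")
    return table[name]


def paper_grid(strategies: Iterable[str] = ("1mit", "1mit+4nuc", "5nuc", "10nuc"),
               n_replicates: int = 50) -> List[StudyCondition]:
    """The full 2 theta x 2 rate x 5 depth condition grid."""
    grid = []
    for theta_mit in (0.025, 0.01):
        for u_mit in (0.01, 0.02):
            for tau1 in (0.5, 1.0, 3.0, 5.0, 10.0):
                for s in strategies:
                    grid.append(StudyCondition(
                        theta_mit, u_mit, tau1, marker_strategy(s, u_mit),
                        n_per_species=5, n_replicates=n_replicates,
                        name=f"th{theta_mit}_u{u_mit}_t{tau1}_{s}"))
    return grid


def dump_condition_grid(grid: Sequence[StudyCondition], stream=None) -> str:
    """Serialise a condition grid to YAML."""
    docs = []
    for c in grid:
        docs.append({
            "name": c.name, "theta_mit": c.theta_mit, "u_mit": c.u_mit,
            "tau1_myr": c.tau1_myr, "n_per_species": c.n_per_species,
            "n_replicates": c.n_replicates,
            "strategy": [dataclasses.asdict(p) for p in c.strategy]})
    text = yaml.safe_dump({"conditions": docs}, sort_keys=False)
    if stream is not None:
        stream.write(text)
    return text


def load_condition_grid(source) -> List[StudyCondition]:
    """Load a condition grid from a YAML path, file object or string."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    elif isinstance(source, str):
        data = yaml.safe_load(io.StringIO(source))
    else:
        data = yaml.safe_load(source)
    grid = []
    for d in data["conditions"]:
        profiles = [MarkerProfile(**p) for p in d["strategy"]]
        grid.append(StudyCondition(d["theta_mit"], d["u_mit"], d["tau1_myr"],
                                   profiles, d.get("n_per_species", 5),
                                   d.get("n_replicates", 50),
                                   d.get("name", "")))
    return grid
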