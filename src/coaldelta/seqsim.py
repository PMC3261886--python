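"""Nucleotide alignment simulation under HKY85 + discrete-Gamma rates.

With the equal base frequencies used throughout this study HKY85 reduces
to the Kimura two-parameter model, whose transition probabilities have a
closed form in the transition/transversion rate ratio ``kappa`` (the
alpha/beta ratio) and the branch length ``d`` in expected
substitutions/site.  Site-to-site rate heterogeneity uses the standard
discrete Gamma with ``k`` equal-probability categories represented by
their category means (mean rate exactly 1).

Nucleotide order is A, C, G, T; transitions are A<->G and C<->T.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .coalsim import GeneTree
from .design import MarkerProfile

__all__ = ["Alignment", "evolve_alignment", "discrete_gamma_rates",
           "k80_transition_probs", "k80_p_matrix",
           "write_partition_manifest"]

_ALPHABET = "ACGT"
_TI_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Equal-probability discrete-Gamma category rates (category means).

    The Gamma(alpha, alpha) distribution (mean 1) is cut at its
    ``i/k`` quantiles; each category is represented by its conditional
    mean, so the category rates average to exactly 1.
    """
    if alpha <= 0 or n_categories < 1:
        raise ValueError("alpha must be > 0 and n_categories >= 1")
    k = n_categories
    bounds = _gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    # E[X; X in bin] for Gamma(a, rate a): (a/a) * P(a+1, a*b) differences
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    return k * (upper - lower)


def k80_transition_probs(d: float | np.ndarray, kappa: float):
    """K80 probabilities (p_same, p_transition, p_transversion_each).

    ``d`` is the expected number of substitutions per site and ``kappa``
    the alpha/beta rate ratio; the two transversion targets are
    equiprobable.
    """
    d = np.asarray(d, dtype=float)
    e2 = np.exp(-4.0 * d / (kappa + 2.0))
    e1 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e2 + 0.5 * e1
    p_ti = 0.25 + 0.25 * e2 - 0.5 * e1
    p_tv = 0.25 - 0.25 * e2
    return p_same, p_ti, p_tv


def k80_p_matrix(d: float, kappa: float) -> np.ndarray:
    """Full 4x4 transition-probability matrix (ACGT order)."""
    p_same, p_ti, p_tv = k80_transition_probs(d, kappa)
    P = np.full((4, 4), float(p_tv))
    for x in range(4):
        P[x, x] = p_same
        P[x, _TI_PARTNER[x]] = p_ti
    return P


class Alignment:
    """Fixed-length nucleotide alignment keyed by tip label."""

    def __init__(self, labels: Sequence[str], data: np.ndarray,
                 locus: Optional[MarkerProfile] = None):
        self.labels = list(labels)
        self.data = np.asarray(data, dtype=np.int8)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one row per label required")
        self.locus = locus

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        row = self.data[self.labels.index(label)]
        return "".join(_ALPHABET[b] for b in row)

    def as_dict(self) -> Dict[str, str]:
        return {lab: self.sequence(lab) for lab in self.labels}

    def write_fasta(self, path: str) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        recs = [SeqRecord(Seq(self.sequence(lab)), id=lab, description="")
                for lab in self.labels]
        SeqIO.write(recs, path, "fasta")

    def write_phylip(self, path: str) -> None:
        """Relaxed PHYLIP (labels of arbitrary length, two-space separator)."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.labels)} {self.length}\n")
            for lab in self.labels:
                fh.write(f"{lab}  {self.sequence(lab)}\n")

    @classmethod
    def read_fasta(cls, path: str,
                   locus: Optional[MarkerProfile] = None) -> "Alignment":
        from Bio import SeqIO
        labels, rows = [], []
        lut = np.full(128, -1, dtype=np.int8)
        for i, b in enumerate(_ALPHABET):
            lut[ord(b)] = i
            lut[ord(b.lower())] = i
        for rec in SeqIO.parse(path, "fasta"):
            labels.append(rec.id)
            rows.append(lut[np.frombuffer(str(rec.seq).encode(), np.uint8)])
        return cls(labels, np.array(rows, dtype=np.int8), locus)


def evolve_alignment(g: GeneTree, locus: MarkerProfile,
                     rng_seed) -> Alignment:
    """Evolve an alignment of ``locus.length`` sites along ``g``.

    The root sequence is uniform over the four nucleotides, each site is
    assigned one of the discrete-Gamma categories with equal probability,
    and every branch applies the K80 matrix for distance
    ``branch_length * site_rate``.  Deterministic given the seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    L = locus.length
    ch = g.children()
    rates = discrete_gamma_rates(locus.gamma_shape, locus.n_categories)
    cats = rng.integers(0, locus.n_categories, size=L)
    root = g.root
    data = np.empty((g.n_nodes, L), dtype=np.int8)
    data[root] = rng.integers(0, 4, size=L)

    # preorder
    stack = list(ch[root])
    while stack:
        v = stack.pop()
        d = g.age[g.parent[v]] - g.age[v]
        if d < 0:
            raise ValueError("negative branch length")
        parent_states = data[g.parent[v]]
        out = np.empty(L, dtype=np.int8)
        u = rng.random(L)
        for c in range(locus.n_categories):
            p_same, p_ti, p_tv = k80_transition_probs(d * rates[c],
                                                      locus.kappa)
            sel_c = cats == c
            for x in range(4):
                sel = sel_c & (parent_states == x)
                if not np.any(sel):
                    continue
                # targets ordered: same, transition, transversion 1, 2
                ti = _TI_PARTNER[x]
                tv = [y for y in range(4) if y != x and y != ti]
                cum = np.cumsum([p_same, p_ti, p_tv, p_tv])
                idx = np.searchsorted(cum, u[sel], side="right")
                idx = np.minimum(idx, 3)
                targets = np.array([x, ti, tv[0], tv[1]], dtype=np.int8)
                out[sel] = targets[idx]
        data[v] = out
        stack.extend(ch[v])

    tip_data = data[:g.n_tips]
    return Alignment(g.labels, tip_data, locus)


def write_partition_manifest(alignments: Sequence[Alignment],
                             path: str) -> None:
    """TSV manifest of partition boundaries for a concatenation.

    Columns: locus name, marker class, 1-based start/end in the
    concatenated alignment, kappa, gamma shape, per-lineage rate.
    """
    pos = 1
    with open(path, "w") as fh:
        fh.write("locus\tmarker_class\tstart\tend\tkappa\t"
                 "gamma_shape\tper_lineage_rate\n")
        for i, a in enumerate(alignments):
            prof = a.locus
            if prof is None:
                raise ValueError("alignment lacks a marker profile")
            name = prof.name or f"locus{i + 1}"
            end = pos + a.length - 1
            fh.write(f"{name}\t{prof.marker_class}\t{pos}\t{end}\t"
                     f"{prof.kappa:g}\t{prof.gamma_shape:g}\t"
                     f"{prof.per_lineage_rate:g}\n")
            pos = end + 1
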