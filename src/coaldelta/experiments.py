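"""Condition-grid orchestration: the delta statistic and study summaries.

delta is the study's discordance statistic: the percent difference
between the tMRCA of the sp1/sp2 gene copies read off an (estimated,
clock-rescaled) gene tree and the true species split time.  The Bayesian
(MB) runs are summarised instead by the percent error of the tau1
posterior mean, with box-whisker bounds at the most extreme estimates
still inside the inter-quartile fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR),
quartiles by the linear-interpolation (type-7) convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._engine import substream
from .coalsim import simulate_gene_genealogy
from .design import MarkerProfile, SpeciesTree, StudyCondition
from .genetrees import GeneTreeEstimator
from .mscbayes import MSCDivergenceSampler, PriorSpec
from .seqsim import Alignment, evolve_alignment

__all__ = ["delta_statistic", "whisker_summary", "simulate_replicate",
           "run_discordance_grid", "run_mb_grid", "randomize_nuclear_rates",
           "PROFILES"]

# chain profiles: sweep-based scaled equivalents of the original
# generation-based settings (a sweep visits every gene-tree node class)
PROFILES = {
    "paper": {"n_replicates": 50,
              "mcmc": {"n_iter": 20000, "burn_in": 5000, "thin": 10}},
    "ci": {"n_replicates": 10,
           "mcmc": {"n_iter": 3000, "burn_in": 900, "thin": 3}},
}


def delta_statistic(tmrca_myr: float, tau_true_myr: float) -> float:
    """100 * (tMRCA - true split) / true split, in percent."""
    if tau_true_myr <= 0:
        raise ValueError("true split time must be positive")
    return 100.0 * (tmrca_myr - tau_true_myr) / tau_true_myr


def whisker_summary(estimates: Sequence[float]) -> Dict[str, float]:
    """Mean plus box-whisker bounds of a set of percent errors.

    Whiskers are the lowest and highest values still inside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (quartiles type-7, linear
    interpolation).  Requires at least 4 values.
    """
    x = np.asarray(list(estimates), dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_f) & (x <= hi_f)]
    return {"mean": float(x.mean()),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "q1": float(q1), "q3": float(q3), "n": int(x.size)}


def randomize_nuclear_rates(profiles: Sequence[MarkerProfile],
                            rng: np.random.Generator,
                            low: float = 0.7,
                            high: float = 1.4) -> List[MarkerProfile]:
    """Redraw nuclear locus rates uniformly in [low, high] x the mean."""
    out = []
    for p in profiles:
        if p.marker_class == "nuclear":
            m = float(rng.uniform(low, high))
            base = p.per_lineage_rate / p.rate_multiplier
            out.append(dataclasses.replace(p, rate_multiplier=m,
                                           per_lineage_rate=base * m))
        else:
            out.append(p)
    return out


def simulate_replicate(st: SpeciesTree, profiles: Sequence[MarkerProfile],
                       samples: Dict[str, int], seed: int,
                       replicate: int) -> List[Alignment]:
    """Simulate one multilocus data set (genealogies + alignments).

    One RNG substream per (seed, replicate, locus): loci are independent
    ("free recombination") and every replicate is exactly reproducible.
    """
    out = []
    for li, prof in enumerate(profiles):
        rng = substream(seed, replicate, li)
        g = simulate_gene_genealogy(st, prof, samples, rng)
        out.append(evolve_alignment(g, prof, rng))
    return out


def _ingroup_samples(st: SpeciesTree, n: int) -> Dict[str, int]:
    """5-seq-per-ingroup design: outgroups (sp4, and sp5 if present) get 1.

    For the 4-taxon tree only sp1 and sp2 carry ``n`` copies (sp3 and sp4
    are outgroups); for the 5-taxon radiation tree every species except
    the external outgroup sp5 carries ``n``.
    """
    if "sp5" in st.labels:
        return {sp: (1 if sp == "sp5" else n) for sp in st.labels}
    return {"sp1": n, "sp2": n, "sp3": 1, "sp4": 1}


def run_discordance_grid(grid: Sequence[StudyCondition], seed: int = 0,
                         return_records: bool = False):
    """Gene-tree (non-MB) experiment: mean delta per condition.

    Per replicate: simulate the multilocus data set, estimate the
    concatenated clock gene tree, read the sp1-sp2 tMRCA in Myr using the
    length-weighted mean rate, and convert to delta.
    """
    if not grid:
        raise ValueError("empty grid")
    rows, records = [], []
    for ci, cond in enumerate(grid):
        st = cond.species_tree()
        samples = _ingroup_samples(st, cond.n_per_species)
        deltas, tms = [], []
        for rep in range(cond.n_replicates):
            rep_seed = int(substream(seed, ci, rep).integers(0, 2 ** 31))
            alns = simulate_replicate(st, cond.strategy, samples,
                                      rep_seed, 0)
            est = GeneTreeEstimator().fit(alns)
            t = est.tmrca_myr()
            d = delta_statistic(t, cond.tau1_myr)
            deltas.append(d)
            tms.append(t)
            records.append({"condition": cond.name, "replicate": rep,
                            "seed": rep_seed, "tmrca_myr": t, "delta": d,
                            "true_tau1_myr": cond.tau1_myr,
                            "flags": ",".join(sorted(est.flags_))})
        w = whisker_summary(deltas) if len(deltas) >= 4 else \
            {"mean": float(np.mean(deltas)), "whisker_low": np.nan,
             "whisker_high": np.nan, "q1": np.nan, "q3": np.nan,
             "n": len(deltas)}
        rows.append({"condition": cond.name, "theta_mit": cond.theta_mit,
                     "u_mit": cond.u_mit, "tau1_myr": cond.tau1_myr,
                     "n_loci": len(cond.strategy),
                     "mean_tmrca_myr": float(np.mean(tms)),
                     "se_tmrca_myr": float(np.std(tms, ddof=1)
                                           / np.sqrt(len(tms)))
                     if len(tms) > 1 else np.nan,
                     "mean_delta": w["mean"],
                     "whisker_low": w["whisker_low"],
                     "whisker_high": w["whisker_high"],
                     "n_replicates": cond.n_replicates})
    summary = pd.DataFrame(rows)
    if return_records:
        return summary, pd.DataFrame(records)
    return summary


def run_mb_grid(grid: Sequence[StudyCondition], seed: int = 0,
                rate_mode: str = "fixed_true",
                heredity_mode: str = "fixed_true",
                mcmc: Optional[Dict] = None,
                vary_nuclear_rates: bool = False,
                priors: Optional[PriorSpec] = None,
                return_records: bool = False):
    """Bayesian (MB) experiment: percent error of tau1 per condition."""
    if not grid:
        raise ValueError("empty grid")
    mcmc = dict(mcmc or PROFILES["ci"]["mcmc"])
    rows, records = [], []
    for ci, cond in enumerate(grid):
        st = cond.species_tree()
        samples = _ingroup_samples(st, cond.n_per_species)
        true_tau1 = cond.tau1_myr * cond.u_nuc  # nuclear subs/site
        errors = []
        for rep in range(cond.n_replicates):
            rep_seed = int(substream(seed, ci, rep).integers(0, 2 ** 31))
            profiles = cond.strategy
            if vary_nuclear_rates:
                profiles = randomize_nuclear_rates(
                    profiles, substream(rep_seed, 0xA))
            alns = simulate_replicate(st, profiles, samples, rep_seed, 0)
            pr = priors or PriorSpec()
            pr = dataclasses.replace(pr, rate_mode=rate_mode,
                                     heredity_mode=heredity_mode)
            est = MSCDivergenceSampler(topology=st, priors=pr,
                                       seed=rep_seed, **mcmc)
            est.fit(alns, profiles=profiles)
            e = est.percent_error(true_tau1)
            errors.append(e)
            records.append({"condition": cond.name, "replicate": rep,
                            "seed": rep_seed,
                            "tau1_post_mean": est.tau1_posterior_mean_,
                            "true_tau1": true_tau1, "percent_error": e,
                            "rate_mode": rate_mode,
                            "heredity_mode": heredity_mode})
        w = whisker_summary(errors) if len(errors) >= 4 else \
            {"mean": float(np.mean(errors)), "whisker_low": np.nan,
             "whisker_high": np.nan, "q1": np.nan, "q3": np.nan,
             "n": len(errors)}
        rows.append({"condition": cond.name, "theta_mit": cond.theta_mit,
                     "u_mit": cond.u_mit, "tau1_myr": cond.tau1_myr,
                     "n_loci": len(cond.strategy),
                     "n_per_species": cond.n_per_species,
                     "rate_mode": rate_mode,
                     "mean_percent_error": w["mean"],
                     "whisker_low": w["whisker_low"],
                     "whisker_high": w["whisker_high"],
                     "n_replicates": cond.n_replicates})
    summary = pd.DataFrame(rows)
    if return_records:
        return summary, pd.DataFrame(records)
    return summary
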