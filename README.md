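# coaldelta

Deep coalescence — the failure of gene lineages to sort within the
population where species split — makes gene trees systematically older
than the speciation events they are used to date. For closely related
mammals, where internal branches measured in generations are comparable
to effective population sizes, this is the dominant error in
divergence-time estimates from one or a few markers. `coaldelta` is a
fully synthetic simulation study of that problem, aimed at
phylogeneticists choosing markers for shallow species trees: it
quantifies the overestimation expected from classical gene-tree dating
(mitochondrial vs nuclear, single vs concatenated loci), and how many
and which markers a Bayesian multispecies-coalescent (MSC) method needs
to recover true split times and radiation topologies.

The machinery, end to end:

- **Multispecies coalescent simulator** — genealogies within a species
  tree (tau in substitutions/site, per-population theta = 4 N_e mu);
  within a population, `j` lineages coalesce at rate
  `j(j-1)/theta_locus`, with per-locus rate (`r`, 10 for mtDNA) and
  heredity (`h`, 0.25 for mtDNA) multipliers.
- **Sequence simulation** under HKY85 (equal base frequencies, kappa =
  10 mitochondrial / 2 nuclear) with 4-category discrete-Gamma rates
  (alpha = 1), 1000 bp per locus.
- **Gene-tree dating pipeline** — per-partition ML distances, neighbor
  joining, outgroup rooting, Langley-Fitch (Poisson single-rate) clock,
  K-score rescaling — and the discordance statistic
  `delta = 100 (tMRCA - tau_true)/tau_true`.
- **Bayesian MSC samplers** — MCMC over divergence times, population
  sizes, per-locus rate/heredity multipliers and per-locus gene
  genealogies on a fixed topology (JC69 likelihood, the deliberately
  simple model of the classic implementations), plus a variant with
  rooted-NNI moves that samples the 5-taxon species-tree topology for
  the radiation experiment.

Inference components follow scikit-learn conventions
(`GeneTreeEstimator`, `MSCDivergenceSampler`,
`SpeciesTreeTopologySampler`: constructor parameters, `fit`,
trailing-underscore attributes).

## Worked example

Simulate one mitochondrial locus under the high-diversity condition
(theta_mit = 0.025, rate 0.01 subs/site/Myr) with a true sp1-sp2 split
of 1 Myr, then date the split from the estimated clock tree:

```python
from coaldelta import (build_focal_tree, mitochondrial_profile,
                       simulate_gene_genealogy, evolve_alignment,
                       GeneTreeEstimator, delta_statistic)

tree = build_focal_tree(theta_mit=0.025, u_mit=0.01, tau1_myr=1.0)
print(tree.newick(annotate=False))
# (sp4:0.031,(sp3:0.011,(sp1:0.001,sp2:0.001):0.01):0.02);

locus = mitochondrial_profile(u_mit=0.01)
samples = {"sp1": 5, "sp2": 5, "sp3": 1, "sp4": 1}
genealogy = simulate_gene_genealogy(tree, locus, samples, rng_seed=42)
print(f"true tMRCA: {genealogy.mrca_age(['sp1','sp2'], tree.labels)/0.01:.2f} Myr")
# true tMRCA: 1.65 Myr

aln = evolve_alignment(genealogy, locus, rng_seed=42)
est = GeneTreeEstimator().fit([aln])
t = est.tmrca_myr()
print(f"estimated tMRCA: {t:.2f} Myr   delta = {delta_statistic(t, 1.0):.0f}%")
# estimated tMRCA: 1.90 Myr   delta = 90%
```

The species split is 1 Myr; this replicate's gene copies last share an
ancestor 1.65 Myr ago (deep coalescence), and the re-estimated clock
tree dates that ancestor at 1.90 Myr — a 90% overestimate before any
model misspecification enters. Averaged over 50 replicates the
overestimate at this condition is roughly 170-185%, and it grows as the
split gets shallower. The Bayesian arm (`MSCDivergenceSampler`), which
models the coalescent explicitly, recovers tau1 without that bias.

Condition grids (the delta surface over theta x rate x depth x marker
strategy, and the Bayesian percent-error surface) run through
`coaldelta.experiments.run_discordance_grid` / `run_mb_grid`, or the
CLI:

```bash
coaldelta experiment --profile ci --mode genetree --seed 1 --out results/
```

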