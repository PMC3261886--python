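# Methods

`coaldelta` is a self-contained simulation study of how deep coalescence
(incomplete lineage sorting) distorts divergence-time estimates read off
gene trees in mammals, and of which multilocus strategies let a Bayesian
multispecies-coalescent (MSC) method recover true split times and
species-tree topologies. Everything is synthetic: the package generates
its own data, re-estimates the quantities of interest, and compares them
with the known truth.

## Model and units

All internal bookkeeping uses expected substitutions per site at the
nuclear mean rate ("nuclear scale"). A species tree carries node ages
`tau` and one population parameter `theta` per branch (plus the root
stem), both in substitutions/site. The locus-scale population parameter
of a marker is `theta_locus = h * r * theta_nuc`, where `r` is the rate
multiplier (10 for mtDNA, ~1 for autosomes) and `h` the heredity
multiplier (0.25 for mtDNA: haploid, uniparental). With
`theta_nuc = 0.01` this reproduces the empirical `theta_mit = 0.025`
(the mean mammalian cytochrome-b diversity), and with 0.004 the
rodent-excluded value 0.01. Effective population sizes never appear as
absolute numbers: branch lengths stated in `N_e` generations are
resolved through `theta_nuc = 4 N_e mu_nuc`, i.e. `g` N_e generations
equal `(g/4) theta_nuc` substitutions/site.

The focal species tree is the 4-taxon asymmetric tree
`(((sp1,sp2),sp3),sp4)` with the sp1-sp2 split at `tau1_Myr * u_nuc` and
internal branches of 4 and 8 N_e generations (long enough that the
outgroup nodes are essentially free of lineage sorting). The radiation
tree adds an external outgroup sp5 (stem 12 N_e) above a 5-taxon
caterpillar whose two short internal branches are (0.5, 1.6) N_e
("moderate") or (0.1, 0.2) N_e ("fast", inside the anomaly zone); the
sp1-sp2 split sits at 8 N_e. The radiation runs use `theta_nuc = 0.01`,
pairing the radiation with the high-discordance diversity condition; the
paper-grid conditions are 2 theta x 2 rate x 5 depths
({0.025, 0.01} x {0.01, 0.02} subs/site/Myr x {0.5, 1, 3, 5, 10} Myr).

## Synthetic-data generator

`coalsim.simulate_gene_genealogy` draws genealogies under the neutral
MSC: within a population with `j` lineages the next coalescence is
exponential with rate `j(j-1)/theta_eff`, uncoalesced lineages pass to
the parent population, the root population extends to infinity, and the
coalescing pair is uniform. Simulation runs on the nuclear scale with
`theta_eff = h * theta`; ages are then multiplied by `r` so each
genealogy is on its own locus's substitution scale. One RNG substream
per (seed, replicate, locus) makes loci independent ("free
recombination") and every replicate exactly reproducible
(`numpy.random.SeedSequence` keyed streams).

`seqsim.evolve_alignment` evolves 1000-bp alignments (configurable)
along the genealogy under HKY85 with equal base frequencies — which is
exactly the Kimura two-parameter model, so the per-branch transition
probabilities are closed-form in `kappa` (10 mitochondrial, 2 nuclear)
— with 4-category discrete-Gamma rate heterogeneity (`alpha = 1`,
equal-probability categories represented by their conditional means, so
the category rates average to exactly 1). Root states are uniform.

What the generator deliberately does **not** emulate: migration or any
gene flow (complete-isolation model), recombination within loci,
population-size change through time, indels, unequal base frequencies,
and selection. Passing tests therefore speak to the pure
lineage-sorting + substitution process; real data add all of the above.

## Gene-tree pipeline (the "classical phylogenetics" arm)

Per replicate the loci are concatenated and analysed as partitions:
maximum-likelihood pairwise distances per partition under K80+Gamma
(kappa and alpha at the partition's simulation values; saturated pairs —
raw difference >= 0.749 — are capped and flagged), combined across
partitions weighted by length; neighbor joining (scikit-bio) on the
combined matrix with negative branches clamped to zero; rooting on the
known outgroup (sp4, or sp5 when present) — never midpoint, since the
design guarantees outgroup monophyly. Ultrametricisation is
Langley-Fitch: branch substitution counts `length * L` are Poisson with
mean `duration * L` under a single rate (absorbed into the age scale),
the two root-child branches merged into one observation because the
root position along that path is unidentifiable under a clock. The
log-likelihood is concave in the node ages and is maximised by
coordinate ascent (per-node 1-D root finding, convergence when the
log-likelihood improves by < 1e-10). The clock tree is then rescaled by
the K-score-minimising scalar `k* = sum(b_ref b_clk)/sum(b_clk^2)`
(least squares through the origin against the non-clock tree). The
sp1-sp2 tMRCA is the age of the MRCA of the union of sp1 and sp2 tips
(also when they are non-monophyletic), divided by the length-weighted
mean per-lineage rate of the partitions.

delta is `100 * (tMRCA_Myr - tau1_Myr) / tau1_Myr`, averaged over
replicates. A calibration worth knowing: the *true* genealogical mean
tMRCA at the focal condition is 2.85 Myr for a 1 Myr split and 2.53 Myr
for a 0.5 Myr split (cross-checked against msprime); the distance+NJ+
clock pipeline is per-replicate unbiased for it, so the package reports
delta near 185% and 405% at those depths. An estimation pipeline can
only report lower values by shrinking the deepest-clade age, which this
re-implementation deliberately does not do.

## Bayesian MSC sampler

`mscbayes.MSCDivergenceSampler` targets
`p(tau, theta, r, h, {G_l} | D)` on a fixed species-tree topology, with
the sequence likelihood by Felsenstein pruning under JC69 — the
deliberately simple model of the classic MCMCcoal program, kept to
reproduce its model-mismatch behaviour; an equal-frequency HKY variant
sits behind the `likelihood="hky85"` flag. Kernels (pruning and the MSC
log density) are numba-compiled; with equal frequencies a branch's
transition matrix reduces to three numbers per branch, so a child's
contribution to state x is `A L[x] + B L[ti(x)] + C sum(L)`.

Priors. Every population theta has an independent Gamma prior;
`derive_theta_prior` finds (shape, scale) from a mean and central 95%
interval by a 1-D search (the study default: mean 0.025, CI
0.003-0.07, i.e. Gamma(~2, ~0.0125); shapes above 100 are treated as
infeasible). Divergence times have exponential increments along
parent-child internal edges with a common, data-derived mean: the
average minimum sp1-sp2 divergence read off per-locus clock trees,
taken from the mitochondrial tree alone (rescaled by the rate ratio)
when one is present. Internally estimated locus rates have independent
mean-1 Gamma(5, 1/5) priors (a "Dirichlet-like" rates-nearly-equal
prior); estimated heredity multipliers have Gamma(4, mean/4) priors
centred on 1 (nuclear) or 0.25 (mitochondrial). Rate multipliers are
referenced to the nuclear mean rate, so tau is reported on the nuclear
scale; externally fixed multipliers (per-locus tree length over the
mean, per `estimate_rate_ratios_external`) are rescaled so the
nuclear-class mean is 1 before being fixed, which keeps tau on that
same scale.

Moves, each Metropolis-Hastings invariant: (a) gene-node age sliders
(uniform within the valid window; multiplicative for the root excess);
(b) subtree re-attachment by re-coalescence — the pruned lineage is
re-attached by simulating its coalescence into the remaining genealogy
under the MSC, which is exactly the conditional prior of the
attachment, so prior and proposal cancel and the acceptance ratio is
the likelihood ratio alone; (c) the rubber-band move on a species
divergence time, linearly deforming gene-node ages inside the
populations whose boundary is the moved tau (with the product of the
per-node stretch factors as the Jacobian); (d) multiplier moves on each
theta; (e) a whole-state scale ("mixing") move over tau, theta and all
gene-node ages (and 1/rates when rates are estimated, which leaves the
likelihood invariant); (f) multiplier moves on rate and heredity
multipliers when estimated. Step sizes are tuned during burn-in toward
acceptance rates of 0.2-0.5. One "sweep" visits half the gene nodes of
every locus, an SPR per ~8 internal nodes, one tau node, every theta
and a mixing move; the default chain (4000 sweeps, 1200 burn-in, thin
4) is the sweep-based scaled equivalent of the original
generation-based settings, chosen so one fit takes seconds rather than
minutes (the original 10^6-generation settings remain available through
the `experiments.PROFILES["paper"]` block).

Correctness is established three ways: with the likelihood switched off
the chain reproduces its priors; a Geweke-style successive-conditional
run (parameter sweeps alternating with data re-simulation from the
current genealogies) preserves the joint prior; and on a one-population
reduction the theta posterior matches a brute-force grid integration of
the same likelihood. A caveat that shaped the tests: the overall time
scale (tau, theta and gene ages jointly) is the slowest direction of
the chain, with integrated autocorrelation times near 100 sweeps in
weak-data regimes, so the calibration tests compare means and KS
statistics at the *effective* sample size (arviz ESS) rather than the
raw sample count — naive p-values would reject correct samplers.

A finding the emulation does not reproduce: with a mitochondrial locus
present and rates estimated internally, the original study reports
systematic *under*-estimation of tau1. Under our documented scale
convention that sign is unreachable: the mean-1 rate prior always
penalises the mitochondrial locus's tenfold multiplier more than small
nuclear multipliers, so the tau * r ridge resolves by inflating tau
(we measure +70% at tau1 = 3 Myr, against +11% with externally fixed
rates; the magnitude ordering, and the attenuation by external fixing,
match the original). The published downward sign presumably reflects an
internal scale-referencing choice of the original program that its
documentation does not state.

## Topology sampler (radiation experiment)

`spt_topo.SpeciesTreeTopologySampler` adds rooted-NNI moves over the
species tree: re-attach a species subtree across an internal branch,
re-draw the displaced node's age uniformly in its new window, keep the
gene trees, and reject if any gene tree becomes incompatible (the move
only touches the MSC density and tau prior, so it is cheap). Chains
start from a seed-derived random topology. The MAP topology is the
modal sampled topology; accuracy is percent-correct and rooted-clade
Robinson-Foulds distance (the symmetric difference of non-trivial
clade sets — values on 5 taxa are compatible with either convention,
and the rooted one matches the rooted trees being sampled). Because
this module mirrors the joint Bayesian topology methods of the *BEAST
family, which use HKY-class substitution models, its default likelihood
is the equal-frequency HKY variant rather than JC69; that choice is what lifts moderate-radiation accuracy to the
published range (~55-75% across replicate sets, against the printed
65/67), while the fast radiation stays at 8-17% (printed 10/17).
An importance-sampling estimate of the per-topology marginal likelihood
(prior draws of parameters and genealogies, averaged sequence
likelihood) serves as an independent oracle for the sampler's MAP on
small data sets, replacing an exhaustive 105-topology stepping-stone
scan that would cost far more for the same check.

## Numerical choices and degenerate inputs

Saturated pairwise distances are capped (default 5 subs/site) and
flagged; all-zero alignments yield a flagged zero-length star tree
rather than an error; NJ's negative branches are clamped to zero;
quartiles use the linear-interpolation (type-7) convention and whiskers
are the most extreme values inside Q1 - 1.5 IQR, Q3 + 1.5 IQR; MSC
densities of constraint-violating genealogies return -inf (so MCMC
rejects) instead of raising; ties are impossible in continuous time.
Sample-size experiments apply n to every locus including the
mitochondrial one. The point estimator for tau1 is the posterior mean.

## Known limitations

- The gene-tree arm estimates topologies from distances (NJ), not by a
  full ML search; at these simulated sizes both are consistent, and the
  acceptance surface is distribution-level, but individual trees can
  differ from an ML search's.
- delta at the shallowest depth is reported at its true value (~400%),
  above the published 300%, for the reason documented above.
- The hybrid-strategy internal-rate bias has the opposite sign from the
  original report (see above); its magnitude ordering is reproduced.
- 5 vs 10 nuclear loci give the same mean delta within Monte-Carlo
  error under concatenation; only the across-class ordering
  (nuclear-only > mixed > mitochondrial) is a robust prediction.
- The topology sampler shares the reference methods' generative model
  but uses a simpler move set and far shorter chains; its accuracy is
  compared through overlapping binomial intervals only.
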