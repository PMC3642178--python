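# Methods

`oxbowflow` tests whether meander-loop cutoff (MLC) — the natural severing
of a river meander that passively transfers the land inside the loop, and
everything living on it, to the opposite bank — leaves a recoverable
population-genetic signature. The package provides (i) a forward-time
simulator of the demographic mechanism, (ii) the statistical toolkit such a
study uses (diversity, disequilibrium, differentiation, clustering,
migration, and a private-allele channel test), and (iii) a battery that
scores the seven MLC predictions from the computed evidence. Everything
runs end-to-end on synthetic data; field data in GENEPOP + FASTA +
metadata form can be substituted for the simulator at any point.

## The simulator

**Model.** Discrete-generation Wright–Fisher metapopulation. A single
ancestral deme (size `n_ancestral`, default 240 diploids for the
three-oxbow layout, 200 otherwise) is initialised with i.i.d. discretised
normal microsatellite allele sizes (sd `init_allele_sd` = 2.5 repeat
units around the midpoint of the reflecting bounds [5, 60]) and run for
`ancestral_burnin` = 60 generations to build coancestry. At the split,
two banks of `demes_per_bank` demes (default deme size N = 100) are
founded from the pool and evolve for `t_split` = 500 generations with
stepping-stone migration `m_along` = 0.02 between adjacent same-bank
demes and `m_cross` = 0 across the river (a hard barrier by default).

Each oxbow is an extra *loop* deme attached to a host deme on the west
bank with migration `m_loop` = 0.3 — pre-cutoff the loop is contiguous
habitat on its bank, so it tracks its host closely. (With a weak
attachment the loop would be a long-term peripheral isolate, already
diverged from its control at the moment of cutoff, which contradicts the
mechanism being modelled; we measured exactly that failure before raising
the coupling.) At `t_cutoff` = 20 generations before present the loop is
relabelled to the east bank, exchanges no migrants for `t_iso` = 10
generations (the receding oxbow), then exchanges `m_along` with its new
east-bank neighbour only — a narrow passage, matching the observation
that populations inside ancient loops stay semi-isolated and can diverge.

Sampling maps demes to field roles: loop deme → *cis*; its old host
across the new channel → *control*; its new neighbour → *trans*; the
distal deme on each bank → *pure* (reference) sites.

**Markers.** Thirteen unlinked microsatellites mutate by ±1 repeat
(strict stepwise model, rate 0.008/locus/generation, reflecting bounds to
stay 3-digit safe). mtDNA is a single maternally inherited 809-bp locus:
each offspring copies the mtDNA of one uniformly chosen parent (no
explicit sexes — the downstream analyses need a maternal haploid marker,
not sex-specific dispersal), with per-site mutation 6e-5. mtDNA is
monomorphic at the bank split, so the two bank haplogroups are
reciprocally monophyletic by construction and their expected uncorrected
divergence is `2 * t_split * mu` ≈ 6%, the depth characteristic of the
emulated system; microsatellites, with their much larger effective size
and high homoplasy, show the weak cross-bank contrast the field data do.
The defaults were chosen so that both of these marker-level contrasts and
the post-cutoff drift/admixture balance at cis sites are realistic; they
are the package's study conditions and are not adjusted per analysis.

**Fixtures.** `tiny` (2 sites × 8 individuals × 3 loci) for unit tests;
`paper_shape` (15 sampling locations pooling to 11 analysis sites, 260
individuals, three oxbows of decreasing age — cutoffs 40/30/15
generations) emulating the field sampling design including multi-location
sites; `no_cutoff_null` — the same sampling layout with `t_split` = 0 and
no transfer, so every site is an offspring draw from one panmictic pool.
In the null the cis/trans/control labels are arbitrary by exchangeability,
which calibrates every direction test at a 50% success rate. A null that
kept the bank split would not calibrate: with diverged banks and no
transfer, adjacency alone decides several predictions deterministically
(e.g. a never-transferred loop deme is trivially closest to its host), so
the exchangeable null is the meaningful false-positive control.

**What the generator does not emulate.** Real microsatellite data carry
null alleles, stutter/scoring error, and complex mutation (multi-step,
length constraints varying by locus); the field system has continuous
space, sex-biased dispersal, and repeated/overlapping cutoff events.
Passing recovery tests therefore show the inference machinery detects the
MLC signature under the idealised mechanism, not that the field data
would yield the same power.

## Statistics

All estimators are computed from first principles (no installed package
handles microsatellite GenotypeTables): Nei's unbiased gene diversity
n/(n−1)(1−Σp²); observed heterozygosity by direct counting; Weir &
Cockerham's small-sample f (F_IS) and two-population θ (F_ST) from summed
variance components, monomorphic loci excluded; hypergeometric rarefied
allelic richness; Hedrick's G'_ST and Jost's D_est from Nei–Chesser
unbiased H_S/H_T with harmonic-mean sample size. The global D_est floors
negative per-locus values at 0 and uses the variance-adjusted harmonic
mean 1/(1/m + var·m⁻³) so occasional zero loci do not collapse the
estimate; the arithmetic mean is reported alongside. Hardy–Weinberg exact
tests enumerate the full conditional distribution for two alleles and use
Guo–Thompson Monte-Carlo (default 10⁵ shuffles, probability-ordering
rejection) otherwise; linkage disequilibrium uses a G statistic on the
two-locus genotype table with a permutation null; Bonferroni correction
is inclusive at p ≤ α/m. A one-level AMOVA (θ among member locations,
permutation p) justifies pooling multi-location sites; pooling is applied
at load time and recommended only when p > 0.05.

## Haplogroup assignment and clustering

Haplogroups are assigned by uncorrected p-distance (pairwise deletion of
gaps/Ns) to the nearest pure-site reference haplotype; exact ties are
left unassigned. With ~6% between-group versus shallow within-group
divergence this reproduces the clade decision of a full likelihood tree
at a tiny fraction of the cost.

Clustering is a Pritchard-style admixture model (Dirichlet(1) prior on
cluster frequencies, Dirichlet(α) on admixture, Gibbs over allele-copy
origins; α fixed at 1 or sampled by Metropolis). The model log-likelihood
is estimated from the post-burnin trace as mean(lnL) − var(lnL)/2, and K
is chosen both by that estimate and by the Evanno ΔK across replicate
runs. Cluster labels are canonicalised by descending mean ancestry among
west-pure individuals, making replicate runs comparable without external
label matching. Default chain lengths (20 000 sweeps, 5 000 burnin) are a
scaled-down version of the reference tool's run plan; the pipeline uses
shorter chains still (800/200) because the simulated studies mix within a
few hundred sweeps.

## Migration

**Recent immigration.** A first-generation-migrant assignment mixture:
an individual sampled at r is an immigrant from s with prior probability
m[r][s]; each row of m is a free Dirichlet (no BayesAss-style bound).
Genotype likelihoods under a candidate origin use that site's *resident*
frequencies with a per-site inbreeding parameter F (the multilocus F_IS
floored at 0) absorbing contact-zone heterozygote deficits. Resident
frequencies are profiled, not sampled: site counts shrunk toward the
pooled frequencies of all sites with τ = 5 gene copies of prior mass,
leave-one-out at the home site. The shrinkage is the working equivalent
of the hierarchical common-pool prior in full Bayesian migration models:
we found that with freely fitted per-site frequencies the sampler sits in
an "everyone is a resident" mode (self-fitted frequencies absorb any
residual cross-river similarity) and the asymmetry signal vanishes. A
Gibbs sampler then alternates latent origins and migration rows; point
estimates are posterior means, intervals are shortest-interval 95% HPDIs,
and convergence is the across-chain spread of posterior means over
independent replicate chains (default tolerance 0.1).

**Equilibrium Nm.** The private-alleles method: the mean within-site
frequency of alleles private to one site of a pair is converted to Nm via
the published log10-linear calibration lines for reference sample sizes
10/25/50, interpolated log-linearly at the observed mean sample size. An
algebraic inversion oracle validates the stored coefficients; a pair with
no private alleles returns an explicit undefined result, never a number.

## The channel test

Private alleles (observed in one pure site, absent from the other) are
filtered to a diagnostic set: prevalence ≥ 0.15 in the pure site of
origin, frequency ≥ 0.10 in the whole dataset (both inclusive), and at
most one allele per locus (highest overall frequency wins; ties go to the
lower allele code — the tie-break is a package convention). The two mtDNA
haplogroups enter as a mirrored pair of pseudo-alleles sharing one
allele-group level by default (configurable to two levels). Each scored
site × allele group contributes a k-of-n row (possession = carrying ≥ 1
copy; for mtDNA, haplogroup membership); k = 0 rows are retained, and
pure sites are included by default since they anchor the native effect.

Both channel hypotheses are binomial-logit mixed models: fixed native
effect (historical channel groups cis with control; current groups cis
with trans) and crossed random intercepts for latitude and allele group,
fitted by maximum likelihood under the Laplace approximation (joint mode
over all random intercepts, Newton inner loop, Nelder-Mead outer
optimisation with restarts). ML rather than any REML-like variant keeps
the AICs comparable; the AIC penalty counts 4 parameters (two fixed
effects, two variances). ΔAIC = AIC(current) − AIC(historical), so
positive values favour the historical channel; identical designs (no cis
sites) short-circuit to ΔAIC = 0 exactly. Complete separation or a
runaway coefficient flags the fit instead of failing silently. The
Laplace error is O(1/n) in the binomial totals; the test suite verifies
agreement with a dense Gauss-Hermite quadrature oracle on small crossed
designs and with an independent reference GLMM implementation.

## The prediction battery

Verdicts score the direction of point estimates, as in the original
scoreboard; HPDIs and p-values are stored as evidence so stricter rules
can be applied downstream. P1 (cis closer to control than trans) uses
haplogroup compositions for mtDNA and all three differentiation metrics
for microsatellites, marked ambiguous when the metrics disagree. P7 (cis
divergence evident) is scored "expected" if either a best-K cluster
concentrates at cis or the largest pairwise D_est at that latitude
involves cis. P6 is evaluated once with all latitudes pooled. Missing
upstream artifacts yield "n/a" cells with reasons, never failures; every
verdict is a pure function of the stored evidence.

For seed-level validation, P1 and P2 are scored at the northern oxbow
(the oldest, with the most consistent signal, as in the field system) and
P3 as the mean immigration asymmetry over the three latitudes with
replicate chains averaged — the study-level form of the claim that rates
were higher control → cis at all three latitudes.

## Numerical choices and problem sizes

Genotype probabilities are floored at 1e-300 before logs; Dirichlet draws
use normalised gammas; the HWE Monte-Carlo uses log-probability
comparison with a 1e-9 tolerance; the Bonferroni boundary is inclusive;
rarefaction uses log-gamma binomials. Chains and replicate counts in the
shipped validation suite are scaled for a single CPU: 25 mechanism seeds
and 50 null seeds, 600–800-sweep admixture chains, 2 × 1600-sweep
migration chains per latitude, and 100-replicate drift checks. These
sizes were chosen as the smallest at which the Monte-Carlo noise of each
check is clearly below the effect being asserted.

## Known limitations

The migration model detects first-generation immigrants plus residual
similarity; it does not estimate historical migration rates. A direct
consequence, confirmed by the validation suite: when a transfer is
followed by isolation (the modelled mechanism), no first-generation
migrants exist between cis and control in either direction, so the
directional-immigration comparison (prediction 3) has zero expected
asymmetry at the seed level — its recovery test fails the 80% bar at
roughly chance rates while its matched null calibration passes,
i.e. the estimator is honest rather than powerful here. Replicate
chains on one dataset still agree closely (the within-study consistency
a field analysis can check), which is precisely why single-study
directional trends should be interpreted cautiously. The Laplace
GLMM underestimates marginal likelihoods for tiny binomial totals. The
simulator is discrete-deme and ignores sex-biased dispersal, so
mtDNA/nuclear contrasts caused by male-biased movement are out of scope.
Private-allele Nm inherits the infinite-island assumptions of its
calibration and is approximate by design.
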