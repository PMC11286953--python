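# Methods

`demoscan` implements a demography-controlled scan for adaptive divergence
among four closely related tree stands (labelled N3, N4 on the north slope
and S1, S5 on the south slope of a single mountain population).  The
pipeline has three layers: a staged demographic model fitted to folded joint
site-frequency spectra, a simulated neutral reference that propagates the
fit's parameter uncertainty, and three divergence statistics ranked against
that reference with false-discovery-rate control.

## The demographic model

The model has 21 parameters: four current diploid effective sizes
(`POPSIZE_N3`…`POPSIZE_S5`), six symmetric per-generation migration rates
(one per unordered stand pair), three merger times `TIME1 ≤ TIME2 ≤ TIME3`
under the fixed topology (S5-(S1-(N3-N4))), five epoch boundaries
`TIMEA ≤ … ≤ TIMEE`, and three forward-time exponential growth rates.  Read
forward in time: a deep expansion (`TIMEE→TIMED`, rate `GROWTHRATE2`),
stability, a long contraction (`TIMEC→TIMEB`, rate `GROWTHRATE1`, matching
progressive historical deforestation), stability at the minimum extent, and
a recent re-expansion with progressive splitting into the four stands
(`TIMEA→present`, rate `GROWTHRATE0`) with continuous migration among the
extant stands.  All times are generations; sizes are diploid Ne; growth
rates are per generation.

Numerical choices:

* msprime's `growth_rate` is a forward-time rate, so epoch rates pass
  through unchanged, anchored at the epoch boundary nearest the present.
* When stands merge (backwards), the ancestral deme takes the **sum** of the
  merging demes' sizes at that time.  This conserves total population mass,
  and makes the ancestral size equal the minimum-extent size when all
  growth rates are zero.  The alternative (ancestor inherits one child's
  size) would make the minimum extent depend on an arbitrary choice of
  "receiving" stand.
* Migration is active from the present back to each pair's merger and is
  symmetric per pair.  After a merger the simulator zeroes rates involving
  the absorbed demes.
* Default mutation rate 9.5e-10 per base per generation (a published beech
  estimate); default recombination 2e-8 per base (≈2 cM/Mb), exposed in the
  configuration because the source derivation prints no value.

The package ships the published summary (lower CI / median / mode / upper
CI) of 100 maximum-likelihood runs for all 21 parameters
(`demoscan.PUBLISHED_ESTIMATES`), and uses the medians as the default generating
parameter set.

## Folded joint SFS and composite likelihood

Joint spectra are computed per stand pair at fixed projected haploid sizes.
Sites with missing genotypes are projected down by hypergeometric
expectation (each site contributes its expected cell weights); sites with
fewer called chromosomes than the projection are dropped and counted.  The
default projection is the smallest per-stand called-chromosome count across
sites, rounded down to an even number.  Folding pools each cell `(i, j)`
with its complement `(n_a−i, n_b−j)`; the representative cell is the one
with the smaller pooled count (lexicographic tie-break on exact ties), so
totals are conserved exactly.

The composite log-likelihood of observed spectra under expected proportions
is `Σ obs_count · ln(expected proportion)` over unmasked polymorphic cells,
with a floor of `1/(10·total expected count)` on empty expected cells.
Because proportions are invariant under a joint rescaling of all sizes and
times (with migration rescaled inversely), the *estimation* objective also
scores the monomorphic class: expected spectra are computed as
branch-length spectra (the branch spectrum times the mutation rate is the
expected site spectrum, with far lower Monte-Carlo noise than counting
simulated mutations), converted to per-base SNP probabilities, and the
observed count of invariant bases enters the likelihood.  This anchors the
absolute parameter scale; without it sizes are unidentifiable in principle.

Estimation runs Nelder–Mead in transformed coordinates (log sizes and
rates, log time-increments) so hard invariants hold by construction, from
random starts drawn log-uniformly within the starting ranges; the search
may leave the ranges.  Every candidate within one run is evaluated with the
same simulation seed (common random numbers), making the noisy objective a
fixed surface.  Defaults: 150–200 simulated fragments per evaluation,
`maxfev = 200`.

## Parameter-uncertainty propagation

The run-to-run distribution of estimates is summarised by *correlation
blocks*: parameters joined by `|Pearson r| ≥ 0.7` (connected components).
Each block's *core* — the member with the largest summed `|r|` to the rest
— is redrawn uniformly between its minimum and maximum estimate; dependent
parameters follow their fitted linear regression on the core plus Gaussian
residual noise.  Negative migration draws are clamped to zero; draws
violating positivity or time ordering are rejected and redrawn.  Each of
the resulting parameter sets is simulated into an independent fragment set
(750 × 1000 bp at full scale) and all fragments are compiled into one
composite null dataset, tagged by source set.

Before the scan, the compiled null is given the same missingness rate as
the empirical data (i.i.d. masking), so that the hypergeometric projection
and the filters treat both datasets identically; without this matching the
region-level statistic picks up a small systematic shift that the bias
classification (correctly) reports.

When a full refit is not requested, the pipeline emulates the run ensemble
by drawing each parameter from a triangular distribution over its published
confidence bounds (mode at the published mode), restoring time ordering by
sorting each draw's event times.  This reproduces the *spread* of the
published estimates; it does not reproduce their correlation structure,
which is unknown from the summary table alone.

## Divergence statistics and the scan

* **G2D** (region level, ≥2 SNPs): the multinomial G statistic
  `2 Σ n_c ln((n_c/n)/p_c)` comparing a region's folded joint-SFS cell
  counts with genome-wide cell proportions.  Proportions for empirical
  regions come from the empirical dataset and for null regions from the
  null dataset, so each statistic is measured against its own genome-wide
  background.
* **AFD** (SNP level): absolute allele-frequency difference from non-missing
  genotypes.
* **Φ_ST** (SNP level): the mode of the locus-specific posterior of an
  AMOVA-style fixation index.  The hierarchical model is a deliberately
  simplified stand-in for the full Bayesian analysis of molecular variance:
  per locus, a pair-wide frequency π ~ U(0,1) and index φ ~ U(0,1) define a
  Balding–Nichols distribution for stand frequencies, which are integrated
  out analytically (beta-binomial likelihood).  Sampling is
  Metropolis-within-Gibbs, vectorised across loci, two chains, with 10%
  independence proposals to cross flat plateaus; the mode comes from a
  boundary-reflected kernel density estimate.  Loci whose split-chain
  diagnostic exceeds 1.2 are flagged and fall back to the deterministic
  moment (AMOVA) estimator, which is also reported for every locus.

Each empirical statistic is ranked in the upper tail of the corresponding
null statistic distribution: `p = max(r, 1)/N` with `r` the number of null
values ≥ the observation (ties count towards `r`; the floor keeps p in
`[1/N, 1]`).  p-values become Storey q-values with π₀ from the smoother
method (cubic smoothing spline on the π₀(λ) grid, read at λ = 0.95; fixed
λ = 0.5 fallback when the smoother is ill-conditioned).  Outliers are
flagged at FDR 0.01.

Each method × pair test is classified from the shift of the simulated
statistic distribution relative to the empirical one (two-sided rank-sum
test at α = 0.05, a conventional level the source analysis leaves
unstated): non-significant → unbiased; simulated shifted left → liberal;
shifted right → conservative.

The "standard" (non-demography-controlled) scan computes Savage–Dickey
Bayes factors at φ = 0 from the same posterior machinery,
`BF₁₀ = prior(0)/posterior(0)` with boundary-reflected KDEs, flagging loci
at BF > 3 (a conventional threshold, exposed in the configuration).

## Filtering

The curation chain removes, in order: whole regions with variant density
above 0.05 per base (full region length, invariant bases included); whole
regions where every called genotype across all their SNPs is heterozygous
(paralogue signature; threshold 1.0, exposed); sites with more than 20%
missing genotypes (applied per site — the source protocol lists the 20%
bound among variant-calling parameters without stating the unit, and the
per-site reading is the conservative one); and monomorphic sites (counting
called genotypes only).  Filtering only ever drops sites or samples, never
edits a genotype.  Coordinate liftover uses a region→scaffold
correspondence table; regions mapping ambiguously are refused with a
distinct error from unmapped positions.  The spatial distribution of
regions along chromosomes is tested for Poisson conformity by chi-square on
per-window counts (default window: chromosome length / 50; adjacent count
classes pooled to expected ≥ 1; df = cells − 2).

## Diversity and differentiation

π per base averages heterozygosity `2p̂q̂·n/(n−1)` over **all** nucleotides
of a region, invariant ones included, and stand values are length-weighted
means over regions.  Global and pairwise F_ST use the Weir–Cockerham (1984)
variance components as a multi-locus ratio of sums; negative pairwise
values are reported raw but truncated to zero when averaged or fed to
UPGMA.  The hierarchical decomposition (slope / stand-within-slope /
individual / allele) uses Henderson's method-I moment equations solved
numerically per locus and summed over loci; confounded designs (one stand
per slope) fall back to a minimum-norm solution in which only the sum of
the confounded components is meaningful.  Jost's D uses the two-population
form `D = 2(H_T − H_S)/(1 − H_S)` from sample allele frequencies, combined
across loci as a ratio of sums; the multi-locus combination used by the
original analysis software is not documented, so this choice is stated
rather than asserted as identical.  Confidence intervals bootstrap target
regions (not SNPs) with replacement, 1000 replicates at full scale, at the
95% and 99% percentile levels.  UPGMA clustering breaks ties
lexicographically and emits newick.

## The synthetic study design

The generator emulates the study's structure: four stands of 21/25/24/26
diploids (within the reported 20–26, matching the reported pair totals
N3+S1 = 45 and N4+S5 = 51), ~9k target regions, 2.9% missing genotypes
masked i.i.d., and near-zero genome-wide differentiation.  Region lengths
default to 1000 bp so synthetic data and the simulated null stay
commensurable; an "empirical" mode draws right-skewed lengths with mean
390 bp.  Haplotypes are simulated under the staged model and paired into
diploids at random.  At the published parameter medians the model yields a
lower SNP density than the real capture data (~0.6 SNPs/kb against ~10/kb)
because the fitted effective sizes are an order of magnitude below what the
observed diversity alone would imply; analyses that need more SNPs scale
the number of regions rather than move the fitted parameters.

The injection harness displaces the allele frequency of chosen loci in one
stand of a pair by Δp (upwards from frequencies ≤ 0.5, downwards otherwise,
clamped to [0, 1], so the realised displacement is non-decreasing in Δp)
and redraws that stand's genotypes binomially; all other loci
are untouched, giving an exact truth set for power and FDR studies.

What the generator does **not** emulate: read-level error, capture bias,
linkage between regions, linked selection, and spatially structured
missingness.  Passing tests therefore demonstrate the statistical
machinery's calibration under the model's assumptions, not robustness to
those real-data artefacts.

## Problem sizes used by the test and acceptance runs

Reduced scales keep the suites reproducible on a single CPU: the compiled
null uses 10 parameter sets × 50–300 fragments (full scale: 100 × 750);
synthetic datasets use 100–1000 regions (full scale ~8800); the
parameter-recovery study uses the two-population reduced model (5 free
parameters, 2000 observed fragments, 8–20 estimation runs, 150 simulated
fragments per likelihood evaluation).  Type-I control is checked at FDR
0.01 over 20 replicate draws from the null; power uses 20 injected loci at
Δp ∈ {0.1, 0.3, 0.5, 0.8}.

## Known limitations

* The 21-parameter refit is functional but expensive; the shipped pipeline
  defaults to the published-summary ensemble for the uncertainty stage.
* The Φ_ST sampler is a simplified stand-in for the full hierarchical
  AMOVA model; its genome-wide hierarchy is replaced by independent
  per-locus priors, so absolute posterior-mode values are comparable only
  within a run, which is all the rank-based scan requires.
* The triangular-emulation ensemble loses cross-parameter correlations of
  the original ML runs.
* Background selection, which can mimic expansion signatures in the SFS, is
  not modelled.
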