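# Methods

This note records the models, estimators, numerical choices and known
limitations of introflow, in the package's own words.

## The coalescent engine

`coalsim` implements the continuous-time structured coalescent
backwards in time with exponential waiting times (Hudson-style).  State
is a set of lineages distributed over demes; between demographic events
a coalescence in deme *k* (diploid size Ne_k) occurs at rate
C(n_k, 2)/(2 Ne_k) and each lineage in deme *a* migrates to deme *b* at
the backward rate m[a→b] (the probability per generation that a lineage
sampled in *a* traces its parent to *b*).  Events are applied at fixed
times, pastwards: a **split** (child's lineages move to the parent
deme), an **admixture pulse** (forward-time source→dest with proportion
φ: each lineage currently in dest relocates to source with probability
φ, drawn from a dedicated RNG stream), a **migration-matrix change**, or
a **deme-size change**.  Exactly one root deme must remain after all
splits; if lineages are stranded in disconnected demes with no further
events, a structural error names them.

Loci are independent, non-recombining replicates.  Mutations are
dropped as Poisson(μ · L · total branch length) under infinite sites:
each mutation is assigned to a branch with probability proportional to
its length and to a unique integer position (uniform, then sorted), so
every simulated site is polymorphic with derived counts in
[1, 2n−1].  The ancestral allele is written as `A` and the derived as
`T` (arbitrary labels).  Time is counted in generations throughout the
engine; conversion to years happens only in `demography.scale_params`.

**Seed policy.** One root seed; locus *i* derives two child streams via
`SeedSequence(seed, spawn_key=(i, k))` — k=0 for genealogy and
mutations, k=1 for pulse relocation draws.  Identical (model, sampling,
seed) inputs reproduce a dataset bit for bit.  A φ = 0 pulse moves no
lineages and leaves the genealogy *distribution* unchanged; it is not
stream-identical to the event-free model, because reaching the event
time truncates one waiting-time draw (harmless by memorylessness).

**Study presets.** `study_null`/`study_pulse` encode a five-deme system
calibrated to the system's published absolute times at 10 y/generation: ecotype
splits at 356 and 3 693 generations (~3.56 and ~36.93 kya), the
donor/recipient species split at 640 000 generations (6.4 My), an
outgroup join at 1 280 000 generations (a chosen, data-free depth), and
μ = 6.675 × 10⁻⁸ per site per generation.  The diploid size of every
deme defaults to 200 000: large enough that 2Ne is of the same order as
the species-split depth, so ancestral polymorphism straddles the split
and the ABBA–BABA framework has incomplete lineage sorting to work
with — with desk-scale Ne (10⁴) the 6.4-My split leaves literally no
shared polymorphism and D is undefined.  Widespread outcrossing plants
plausibly occupy this range.  The pulse preset adds one HS→TP_E pulse
at 100 generations with φ = 0.1 by default.  The four `pair_IM_*`
presets are a single two-deme isolation-with-migration template whose
migration epochs differ: constant over [0, T), only the recent half,
only the early half, or two different rates — so model selection
compares nested-like structures.  Their default sizes and rates sit
inside the fitting bounds below.

**Degradation.** `degrade` masks diploid genotype calls independently
at a given rate and draws per-site QUAL from a constant or a frozen
scipy distribution, emulating RAD-seq sparsity upstream of the filter
stage.  The simulated sequence length per run is configurable
(`n_loci × locus_length`); defaults are desk-scale choices, not data
constraints.

## Genotypes, filters, polarization, windows

Coordinates are 0-based half-open internally; VCF positions convert at
the boundary.  The variant filter keeps sites with missing-call
fraction **strictly below** 0.20, QUAL **strictly above** 30 and joint
minor-allele frequency **strictly above** 0.05 — boundary sites are
excluded, and this is deliberate and visible (a MAF of exactly 0.05
drops).  MAF is computed over all samples jointly, mirroring a
study-wide VCFtools-style filter.  Per-rule exclusion counts are
reported; a site failing several rules is counted under each.

Polarization declares the outgroup's major allele ancestral and flips
frequencies accordingly; sites where the outgroup sits at exactly 0.5
are dropped (determinism over random tie-breaking), as are sites where
any involved population has fewer than 2 non-missing alleles.  Windows
tile each contig half-open at the given width (default 10 kb) and a
trailing partial window is discarded.

## Introgression statistics

Site patterns from polarized frequencies:
ABBA = (1−p1)p2p3(1−p4), BABA = p1(1−p2)p3(1−p4).  D is the ratio of
genome-wide sums.  Standard errors come from a **weighted delete-one
block jackknife** over contiguous SNP blocks (default 1000 SNPs; 500
for f3): the ratio is recomputed with each block deleted and the
variance uses the Busing et al. (1999) delete-m_j formula with block
weight = informative-site count (sites with ABBA+BABA > 0); with equal
weights it reduces exactly to the classical s/√n for a mean.  An
unweighted variant is a flag.  Positive D(P1, P2; P3, O) means excess
P2–P3 sharing; swapping P1 and P2 negates D exactly.

f_dM follows the dynamic-donor substitution: per site the numerator is
ABBA−BABA; the denominator substitutes p_D = max(p2, p3) into the P2
and P3 slots when p2 ≥ p1, else p_D = max(p1, p3) into the P1 and P3
slots with a sign flip.  Windows with fewer than 5 usable sites, or a
zero denominator, are omitted and counted.  Outliers are windows
strictly above the type-7 empirical quantile (default 95%); ties at the
threshold are excluded, so a degenerate all-equal scan yields no
outliers.

f3(C; A, B) is the plain mean of (c−a)(c−b) with jackknife Z; no
within-population bias correction is applied, which makes the test
conservative for detecting admixture (the uncorrected statistic is
biased upward, away from negative values).  Z < −3 calls C admixed.

## Windowed population genetics

π is the mean per-site unbiased heterozygosity 2p(1−p)·n/(n−1) averaged
over **accessible variant sites** in the window — with
reduced-representation data the invariant accessible length is unknown,
so these are per-variant-site levels and SNP density (segregating
sites / window width) carries the per-bp scale.  Dxy is the mean of
p_x(1−p_y) + p_y(1−p_x).  FST is Hudson's ratio of averages,
1 − mean(Hw)/mean(Hb), with the unbiased within-heterozygosity; on
identical sample frequency vectors this is exactly 1 − n/(n−1), a known
small-sample property of the unbiased estimator, not a bug.
Weir–Cockerham θ is available by flag for AMOVA-style comparisons.

Tajima's D and Fu & Li's tests use sites with complete data in the
focal population so the sample size in the normalizing constants is
fixed; η is taken equal to S (infinite-sites reading of biallelic SNP
data).  Fu & Li's D/F count external mutations as derived singletons
(outgroup polarization required); D*/F* use total singletons and need
no outgroup.  LD r² is the squared genotype-dosage correlation
(composite LD; input is unphased), computed pairwise-complete and
binned by distance; the half-decay distance is the midpoint of the
first bin at or below half the maximum bin mean.  The selection scan
Z-transforms FST across windows and takes log10 of the π ratio; the
default outlier rule is the **conjunction** (top 5% of both scores),
with a union mode available — the conjunction is the stricter reading
of "top 5% of Z(FST) and log10(θπ ratio)".

## Ka/Ks and the molecular clock

NG86 counting: per-codon synonymous site fractions from the universal
code (changes to stop codons count as nonsynonymous sites); observed
differences averaged over all orderings of the differing positions with
equal weights, discarding pathways that pass through a stop codon
(falling back to all pathways if none survive).  Proportions are
Jukes–Cantor corrected, undefined at p ≥ 3/4.  NG86 is used rather than
a YN00-style ML codon model: the downstream use is the ω < 1
classification with a Fisher exact test on the rounded count table
{(Nd, N−Nd), (Sd, S−Sd)}, for which the lighter counting method is an
adequate and fully transparent substitute; ω values from the two
methods differ in the second decimal, not in the classification.
`clock_convert` solves T = Ks/(2r) for whichever of the three
quantities is missing.  The per-generation mutation rate used by the
simulator (6.675 × 10⁻⁸) is a configurable constant, not derived: the
printed clock inputs (Ks ≈ 1, T ≈ 74 My, 10 y/generation) give
6.757 × 10⁻⁸, and the inputs behind the slightly smaller published
constant are not stated.

## Demographic inference

The observed unfolded joint SFS accumulates sites with sufficient
non-missing alleles, hypergeometrically projected down when a smaller
grid is requested; fixed–fixed corners are masked.  The expected SFS is
estimated from the same coalescent engine by **branch-length
accumulation**: each branch contributes its length to the entry indexed
by its derived-leaf counts, which is the exact conditional expectation
of infinite-sites mutations given the genealogy and needs an order of
magnitude fewer simulations than mutation sampling.  Unobserved entries
get a pseudocount (half a unit of branch weight per simulated locus)
before renormalization.

The composite log-likelihood is Σ obs·ln(prob) over unmasked entries.
Used on the SFS shape alone it is nearly invariant under jointly
rescaling sizes and times (with weak migration the normalized SFS
barely moves), so `fit_model` optionally **anchors the absolute scale
with the monomorphic-site count**: when the observed SFS is built with
a known surveyed sequence length, the per-site probabilities
q_ij = μ·E[B_ij] and q_mono = 1 − Σq are used and the monomorphic class
enters the likelihood.  This is what makes (Ne, T) separately
identifiable at fixed μ, and it presumes no ascertainment (all SNPs
from a known length — true for simulator output, not for MAF-filtered
data).

Optimization is multi-start Nelder-Mead on log-parameters with common
random numbers (one simulation seed per start, shared by all its
evaluations, so each start sees a deterministic surface).  The first
start sits at the log-midpoint of the bounds; a wide initial simplex
(0.7 log-units) plus one restart from the incumbent with a half-width
simplex counteracts premature contraction on curved likelihood ridges.
Default bounds follow the published sampling ranges for this system: Ne log-uniform over
500–30 000 diploids (1000–60 000 haploids), migration 10⁻⁵–10⁻² per
generation; epoch-boundary times are free parameters with declared
bounds since no published values exist.  Desk-scale defaults (a few
hundred genealogies per evaluation, 2–5 starts, ≤40–60 iterations) are
the package's own working sizes; all are configurable upward.

The **direction test** fits the same base model with a pulse in each
direction, freeing only φ, and compares composite likelihoods; the
recovery experiments in the test suite fix migration at its generative
value so the refit targets (Ne, T) — freeing m as well lengthens the
ridge and needs more simulation per evaluation than a desk-scale run
warrants.  `model_select` ranks by max composite likelihood or AIC
(−2CL + 2k), with ties kept in input order.  `scale_params` multiplies
generation-scaled times by the generation time and can linearly
recalibrate all times so a named node matches an absolute age (e.g.
pinning the species split at 6.4 My).

## Marginal likelihoods and Bayes factors

`power_schedule(K)` maps Gauss–Legendre nodes from (−1, 1) to
β ∈ (0, 1) while keeping the raw weights (which sum to 2); the
estimator M = Σ w_k·E_k/2 performs the interval change, exactly as the
printed worked scheme does, and integrates a constant log-likelihood
exactly for any K.  Each E_k is the posterior-mean log-likelihood under
prior × likelihood^β, sampled by componentwise Gaussian random-walk
Metropolis–Hastings whose step sizes adapt toward ~30% acceptance
during burn-in only and are frozen afterwards (preserving detailed
balance).  At β = 0 the chain targets the prior, and the likelihood
power is skipped so an unbounded likelihood cannot poison the chain.
Per-β Monte-Carlo SEs use batch means (robust to autocorrelation) and
propagate as √(Σ(w_k/2)²SE_k²), assuming independent chains across β —
a mildly optimistic assumption, stated here.  E_k should be
non-decreasing in β; violations beyond 3 combined SEs are counted and
flagged, not failed.

The conjugate-normal built-in (known σ, normal prior on the mean) has a
closed-form evidence and is the validation target.  The SFS adapter
treats the composite likelihood as a true likelihood inside TI; under
linkage this overstates evidence, so Bayes factors computed through it
are qualitative direction support, not calibrated probabilities.
`bayes_factor` applies B = exp(M1 − M0) with the B > 100 rule read
literally as the decisive cutoff.

## What the synthetic data do and do not show

The generator reproduces the statistical skeleton the analyses assume:
deep species divergence with ILS, recent ecotype splits, a single
unidirectional pulse, exchangeable non-recombining loci, missingness
that is independent across genotype calls, and constant QUAL.  It does
not model intra-locus recombination, linked selection, gene conversion,
mutation-rate heterogeneity, sequencing error, or the restriction-site
dropout structure of real RAD libraries (missingness there is
locus-correlated, not independent).  Passing calibration therefore
demonstrates estimator correctness and pipeline wiring under the
stated model — not robustness to those real-data pathologies, which is
the usual caveat for simulation-validated scan software.

## Numerical details worth knowing

- Jackknife variance is clamped to zero when all leave-one-out
  estimates agree to 1e−12 relative (identical blocks would otherwise
  produce SE ~1e−17 and an astronomically large Z).
- A zero jackknife SE with nonzero D is reported as an infinite Z with
  a warning and a `degenerate` status, never silently.
- Windows with zero genotyped sites are retained with `n_sites = 0` and
  NaN statistics; windows failing the f_dM site minimum are dropped and
  counted, which keeps scan output joinable to window lists.
- Monomorphic or all-missing site pairs are skipped in LD; π ratios
  with a zero denominator are excluded from the selection-scan ranking
  and counted.
- The filter counts a multi-rule failure once per rule, so the counts
  need not sum to the number of dropped sites.
- All end-to-end runs are reproducible byte for byte from (config,
  seed); pipeline reports avoid timestamps for this reason.
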