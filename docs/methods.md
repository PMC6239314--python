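# Methods

`founderage` dates a founder variant — a mutation carried today by many
chromosomes descending from a single ancestral copy — from the decay of
linkage disequilibrium (LD) around it, together with its present-day
frequency. This note describes the models, their assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Data model

A panel is an ordered set of STR/SNP markers flanking a focal variant in
a window of (by default) at most 5 Mb, with a piecewise-linear genetic
map. Genetic distances are converted to recombination fractions with
Haldane's map function by default (`morgan` is available); at the
sub-centimorgan scale of a conserved core the choice is numerically
irrelevant, and across a 5 Mb window the two differ by ~2.5%. When no
interpolated map is available the default is a uniform 1 cM/Mb map, the
conventional genome-wide human average; this is a documented assumption,
not data. STR alleles are integer codes in ascending size order; the
missing/unphased code is `.`; physical coordinates are 1-based.

## Phasing

**Families.** Pedigree phasing assigns a site's parental origin only
where Mendelian transmission logically forces it: for a heterozygote the
two orientations are checked against the parents' genotypes, and a site
with both orientations transmissible stays unphased. Because single-locus
transmission constrains only membership of each child allele in a
parental genotype, this per-site rule equals the intersection of all
Mendelian-consistent full phase assignments (the test suite verifies
this against brute-force enumeration). The focal variant participates
as an extra binary locus, so the variant-bearing chromosome of a carrier
is identified whenever one parent is a non-carrier.

**Unrelated samples.** `em_haplotype_inference` is standard
gene-counting EM over multilocus phase configurations (log-likelihood
monotone by construction, multiple restarts, frequency floor 1e-12).
Joint EM over a dozen multiallelic loci is, however, unidentifiable in a
~50-sample panel: nearly every 12-locus haplotype is a singleton, so any
phase assignment fits equally well. The pipeline therefore phases
unrelated samples *marker by marker against the variant* with a
two-locus anchored EM (`phase_unrelated_by_anchor`): the only usable
information is the pairwise LD between each marker and the variant, and
the marker allele is assigned to the variant-bearing chromosome only
when the phase posterior reaches 0.95 (default); uncertain sites stay
unphased, which the estimators treat as missing. Non-carriers receive a
frequency-neutral arbitrary split (their phase never enters the dating).

**Shared core.** The conserved founder core is the contiguous marker
window around the variant whose modal allele is carried by at least a
threshold fraction (default 1.0) of carrier chromosomes, grown outward
from the variant on each side. Markers monomorphic in the population are
transparent: agreement there is no evidence of shared ancestry, so they
neither break nor join the core.

## The genealogy model shared by both estimators

Both estimators model the carrier chromosomes as leaves of an
*intra-allelic genealogy* — the tree relating all sampled copies of the
mutant allele back to the founding mutation at age `t` generations.

The mutant-class trajectory is anchored at both ends: one copy at the
founding event and `C = n/f` copies today (`n` sampled carrier
chromosomes, `f` the sampled proportion), with the exponential shape of
a surviving supercritical birth-death class in between,

    N(s) = 1 + (C - 1) (e^{d(t-s)} - 1) / (e^{dt} - 1),

`s` the age and `d` the per-generation growth rate. Conditioned on
`C`, `k` lineages coalesce at rate `lambda k(k-1)/N(s)` with
`lambda = 1 + d`: this is the ancestral process of a linear birth-death
population (a birth at rate `lambda N` merges a sampled pair with
probability `k(k-1)/(N(N-1))`), and is 2`lambda` times the naive
Kingman rate — using the Kingman rate measurably under-covers young
truths in the recovery experiments. The age enters twice: all lineages
must coalesce before the founding event, and the copy number itself has
the closed-form linear birth-death likelihood
`P(C | t) = (1 - beta)(beta)^{C-n}` (geometric conditioned on survival
and on at least `n` copies), which is how the allele frequency informs
the age. The normalising probability of full coalescence by `t` is
omitted (it approaches 1 as the trajectory reaches one copy, where the
pair rate exceeds `lambda k(k-1)`).

Recombination is a jump-to-stationarity process per marker: along a
branch of length `L`, marker `i` retains its allele with probability
`e^{-theta_i L}` and otherwise jumps to a draw from the population
allele frequencies, which that lineage's descendants inherit. The
marginal retention over a root-to-leaf path of length `t` is exactly
`e^{-theta_i t}` — the classical star-model decay — but the tree
structure makes retention (and post-recombination backgrounds) strongly
correlated between related chromosomes.

A separate, simpler sampler (`sample_intraallelic_genealogy`) draws
genealogies under the deterministic trajectory `N(s) = e^{d(t-s)}` with
Kingman-type rates; it is retained as the reference implementation of
that classical formulation and is validated against a master-equation
oracle.

## LD-decay Bayesian estimator (`run_age_mcmc`)

`model="genealogy"` (default) runs Metropolis-Hastings over the age and
the full time-tree. Per iteration: a reflected Gaussian random-walk move
on `t` (step adapted to 0.44 acceptance during burn-in, frozen after), a
joint time-scaling move multiplying `t` and all node ages by a common
factor (Jacobian included), two node-age moves (uniform within the local
interval), two nearest-neighbour interchanges, and a periodic
whole-topology refresh at the current ages. Because a coalescent's
ranked topology is uniform, topology moves accept on the likelihood
ratio alone. The likelihood peels each marker over the tree
(Felsenstein pruning under the jump process, with per-node scaling) and
marginalises the ancestral allele at the root against the population
frequencies — its natural prior — which removes a sampling dimension
and avoids the severe young-age bias of plugging in the modal carrier
haplotype. The prior on `t` is uniform on [1, `max_age`] (default 500).
Four chains from overdispersed starts by default, pooled after a
split-R-hat check; the mode is the argmax of the integer-generation
histogram and the interval is the central 95% quantile range (an HPD
variant was considered and rejected to keep the summary identical across
both estimators' outputs).

`model="star"` is the fast composite approximation (per-chromosome,
per-marker independence): it is retained for teaching and for the
prior-recovery and oracle tests, but it both underestimates the age and
overstates certainty when carriers are strongly related — on synthetic
study-shaped panels its mode is biased ~-35% with ~20% interval
coverage, which is why it is not the default.

Carrier alleles absent from the control sample get the 1e-12 frequency
floor (with a warning): a rare ancestral allele may simply be missing
from a 32-person control group.

### Known behaviour of the posterior mode

The posterior is calibrated (94-100% central-interval coverage in the
recovery experiments at true ages 20-100) but right-skewed, essentially
lognormal in `t`. The copy-number likelihood alone displaces the mode:
under the generating law `ln C ≈ d t + ln(lambda/d) + ln W` with
`W ~ Exp(1)`, and `E[ln W] = -EulerGamma`, so the mode of a single
realisation sits `gamma/d ≈ 6` generations below the truth on average at
`d = 0.095`; the genealogy term adds ordinary skew on top. The
posterior mean is nearly unbiased. Users who need a point estimate with
small repeated-sampling bias should quote the posterior mean or median;
the mode is reported because it is the conventional summary for this
analysis class.

## Birth-death ML estimator (`profile_likelihood`)

The data summary is the partition of carrier chromosomes into
flanking-haplotype classes, summarised by the *intact count* `k`: the
number of chromosomes matching the ancestral haplotype at every marker
(`statistic="classes"` keeps the raw partition instead). With the
ancestral haplotype estimated from the carriers themselves (the
per-marker modal allele), `k` is inflated by a selection effect —
recombinant clades share their post-crossover background and can
masquerade as conserved haplotypes. The default likelihood therefore
*simulates the entire statistic pipeline*: for each Monte-Carlo
genealogy (drawn from the same growth-conditioned coalescent as above,
common random numbers across the age grid), marker data are simulated
branch-by-branch — first-crossover-censors-distal semantics, shared
backgrounds, coincidental matches — and the same modal-ancestral
intact-count is recomputed; the likelihood at each candidate age is the
fraction of replicates reproducing the observed `k`, times the
copy-number term. An exact alternative (`method="exact_ancestral"`)
computes the intact-count distribution analytically on each genealogy by
a bottom-up class-size polynomial, appropriate when the ancestral
haplotype is known externally (e.g. from family segregation); its exit
rate can be pre-discounted for coincidental re-entry with
`effective_class_exit_rate`.

The ML age is the grid argmax of a locally averaged curve (+-2 grid
points, suppressing residual Monte-Carlo jitter on flat shoulders; the
reported curve itself is unsmoothed); the 95% interval is central
normalised-likelihood mass over the grid (flat prior), matching the
interval phrasing of the published analyses rather than a 2-unit support
interval. Non-unimodal curves beyond Monte-Carlo noise trigger a
warning. When the sampled proportion is itself a rough projection
rather than a known quantity, `f_uncertainty_log_sd` integrates the
implied copy number out over the birth-death law times a lognormal
measurement model (7-point log-grid quadrature); the study-scale runs
use log-sd 1.0, reflecting the factor-~3.6 spread among the published
figures from which `f` could be derived.

Only `d` is identified by the published analysis; the rates use the
discrete-generation scaling `mu = 1`, `lambda = 1 + d`. STR mutation is
not modelled in either estimator (the dating markers are treated as
pure recombination clocks).

## Demography module

* Regional carrier projection: `region_pop x (world_affected /
  world_pop) x variant_share`, rounded half-up — with the published
  inputs (150,000 affected worldwide; world 7.465e9; region 8.035e7;
  30% variant share) this gives 484 chromosomes (= carrier persons,
  carriers being heterozygous).
* `sampled_proportion(51, 484) = 0.1054`: the proportion implied by the
  published counts does **not** reproduce the 0.0294 used historically
  with these data; no combination of the published inputs does. The
  proportion is therefore always an explicit configuration input, and
  this discrepancy is surfaced in reports.
* Luria-Delbruck clock correction `g0`: the expected number of
  generations before the first recombination anywhere in the flanking
  interval while the class is still small. The default simulation
  draws the first-event generation under deterministic growth
  `(1+d)^g` with per-copy recombination probability `c` per generation
  (inverse-CDF sampling, Monte-Carlo SE reported); the closed-form
  variant evaluates `ln(1 + d/c)/ln(1 + d)`. With `d = 0.095` and
  `c` from 0.0076 cM both give ~75-79 generations; the historically
  reported 4.25 is not reproducible from these inputs by any standard
  formula we know, and is stored as a reference constant only — it is
  never asserted as the output of either method. `corrected_age`
  shifts a posterior by `g0`, preserving the interval width.

## Synthetic data generator

The generator emulates the shape of a founder-variant dating study: 51
carrier chromosomes (35 in three families plus 16 unrelated), 32
unrelated controls, 9 STRs + 3 SNPs in a 5 Mb window with a tight
4-marker core (0.0076 cM between the core-flanking markers at the
default map), one SNP monomorphic in the population, growth 0.095. The
real marker names are used with synthetic physical positions (the
study's interpolated map was never published) and synthetic control
allele frequencies chosen to be typical of small STR/SNP panels.

Mechanics: the ancestral haplotype is drawn from the control
frequencies; the class grows by an exact forward linear birth-death
simulation conditioned on at least the required number of survivors
(optionally on a copy-number band, to pin the realised class size to an
externally implied value); carrier chromosomes are uniformly sampled
leaves of the extracted genealogy; recombination is laid down per branch
on the genetic scale with first-crossover-censors-distal semantics and
population replacement material inherited by descendants; optional
stepwise STR mutation (default rate 0 — the dating models assume pure
recombination clocks); controls are drawn at linkage equilibrium
(`background_pool_size` injects background LD by drawing from a small
haplotype pool instead); carriers are diploidised against control
chromosomes (dominant disease, heterozygous carriers). Families are
expanded from one founder lineage each with explicitly simulated
meioses, so the emitted pedigree + genotypes are Mendelian-consistent by
construction and family carrier chromosomes are realistic near-copies.

What the generator does *not* emulate: background LD among controls (off
by default), genotyping error, missing data patterns, ascertainment of
families through multiply-affected probands, and population structure.
Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to those real-data
complications.

For dating, family chromosomes are pseudo-replicates of their founder
lineage; the workflows reduce them to one chromosome per family
(`one_chromosome_per_family`) and scale the per-lineage sampled
proportion to keep the implied copy number fixed. The alternative
policy (all chromosomes) is available throughout.

## Problem sizes used in the shipped experiments

The reproduction script and acceptance tests use scaled-down but
mixing-checked settings chosen by inspecting split-R-hat and
Monte-Carlo standard errors: recovery experiments run 15-25 replicates
per age with 12,000 MCMC iterations x 2 chains (the chain makes ~6 tree
moves per iteration) and 1,500-2,000 birth-death replicates per grid
point; study-scale runs use 60,000 iterations x 2 chains and 10,000
birth-death replicates, and the reproduction script reports the median
of three stand-in datasets to damp the stand-in's own sampling noise.
Doubling any of these leaves the reported summaries unchanged within
one generation.

## Known limitations

* The genealogy prior is a deterministic-trajectory approximation of the
  conditioned birth-death class; path stochasticity enters only through
  `P(C | t)` and, optionally, the lognormal uncertainty on `f`.
* The composite treatment across markers ignores crossover interference
  between markers on the same flank beyond the shared-branch structure.
* Statistical phasing of unrelated samples uses only variant-marker LD;
  long-range phase between distal markers is not inferred (and is not
  needed by the estimators).
* The posterior-mode skew discussed above is intrinsic; intervals, not
  modes, are the recommended inferential output.
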