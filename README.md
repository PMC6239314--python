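# founderage

Dating founder variants from linkage-disequilibrium decay and allele
frequency.

When a disease mutation in today's population descends from a single
ancestral chromosome — a *founder variant* — every carrier chromosome
initially shares the founder's marker haplotype, and recombination
erodes that sharing at a calculable rate. `founderage` implements the
classical dating workflow around such a variant as a tested, end-to-end
pipeline:

* **haplotype determination** around the focal variant: Mendelian
  pedigree analysis for families, variant-anchored EM phasing for
  unrelated samples, and detection of the conserved ancestral core
  haplotype;
* **Bayesian age estimation from LD decay**: Metropolis-Hastings over
  the variant age *t* (generations) and the intra-allelic genealogy
  relating the carrier chromosomes, with per-marker recombination
  peeled along the tree and the ancestral haplotype integrated out;
* **maximum-likelihood age estimation under a linear birth-death
  model** of the mutant-allele class, combining the extent of
  intra-allelic haplotype variation with the allele frequency;
* **demographic side computations**: regional carrier projection,
  generation/year conversion, and the Luria-Delbruck growing-population
  clock correction;
* a **synthetic founder-panel generator** with known truth (age,
  ancestral haplotype, genealogy, class size), so every stage is
  testable without any external data.

The intended users are statistical geneticists analysing marker panels
around a putative founder mutation — the motivating configuration is a
dominant glaucoma variant typed with 9 STRs + 3 SNPs in a 5 Mb window on
51 carrier and 32 control individuals — and methodologists who want a
transparent, reproducible reimplementation of this analysis class.

## The models in brief

Carrier chromosomes are leaves of the intra-allelic genealogy rooted at
the founding mutation at age *t*. The mutant class has one copy at the
founding and `C = n/f` copies today (*f* = sampled proportion), with a
surviving birth-death trajectory between; *k* lineages coalesce at rate
`λk(k−1)/N(s)` with `λ = 1 + d` and growth *d* per generation. Along a
branch of length *L*, marker *i* retains its allele with probability
`e^(−θᵢL)` (θᵢ = recombination fraction to the variant) and otherwise
jumps to a population draw inherited by descendants; the marginal
per-chromosome retention is the classical `e^(−θᵢt)`. The age is
informed jointly by the LD decay on the tree and by the closed-form
birth-death copy-number law `P(C | t)`. Full details, assumptions and
design decisions: [`docs/methods.md`](docs/methods.md).

## Worked example

`python examples/03_date_variant.py` simulates a study-shaped panel (51
carrier chromosomes, 32 controls, growth 0.095) whose true age is 43
generations, then dates it with both estimators:

```
LD-decay Bayesian estimate (intra-allelic coalescent MCMC):
  posterior mode : 35 generations (700 years at 20 y/gen)
  95% interval   : 24.1 - 72.4 generations
  split R-hat    : 1.001

Birth-death maximum-likelihood estimate:
  intact ancestral class: 0 of 51 chromosomes
  ML age       : 38 generations
  95% interval : 22.7 - 74.7 generations

true age used by the simulation: 43 generations
```

Both 95% intervals bracket the truth; the posterior mode sits below the
posterior mean because the age posterior is right-skewed (see the
methods note). In the recovery experiments shipped with the test suite,
both estimators' intervals cover the true age in ≥ 90% of seeded
replicates at true ages 20, 43, 59 and 100 generations.

`python examples/04_demography_and_correction.py` prints the closed-form
demographic quantities: the regional projection of 484 variant
chromosomes, the 860 / 1180-year conversions of 43 / 59 generations at
20 years per generation, and both computations of the Luria-Delbruck
clock correction alongside the tracked historical reference value.

## Layout

```
src/founderage/     datamodel, io, phasing, coalescent, birthdeath,
                    demography, simulate, trees, workflow, cli
tests/              unit, property and acceptance tests
examples/           one narrative script per capability
docs/methods.md     models, assumptions, parameters, limitations
scripts/acceptance.py   end-to-end reproduction script
```
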