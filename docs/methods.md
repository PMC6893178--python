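# Methods

This note documents the models implemented in `tfg`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the limits of what the test suite demonstrates.

## Coordinate conventions and the retention rule

All positions live on a single homology axis: 0-based, origin at the 5′ end
of the shared homology, total length *L* = `len5 + len_target + len3`.
Base *i* occupies the half-open interval [*i*, *i*+1) with center *i*+0.5;
the DSB coordinate is a between-base integer in (0, *L*); intervals are
half-open.

The pop-out crossover is modelled as continuous-uniform on (0, *L*).  A
modification is retained iff the crossover falls on the opposite side of
the modification's base center from the DSB — crossovers on the DSB side of
a modification are non-productive wherever they fall, including beyond the
DSB.  Under this rule the Monte-Carlo retention frequency of a single
modification at base *m* (DSB at higher coordinate) is (*m* + 0.5)/*L*.

The analytic `retention_probability` reports the *strict productive-side
fraction* *m*/*L* (resp. (*L* − *m* − 1)/*L*): the length of homology
strictly on the productive side of the base over the total.  The two
conventions differ by 0.5/*L* (< 2·10⁻⁴ for kb-scale designs), far below
both Monte-Carlo resolution at 10⁵ events and any design-relevant
precision; the package treats the strict fraction as the canonical analytic
value and the base-center rule as the canonical event-level rule.  Ties
(crossover exactly at a base center) have probability zero under the
continuous model.

Positions between the DSB and the nearer homology end are supported by the
same rule with the sides swapped and are flagged "DSB-distal" in screen
reports.  A gap-repair conversion tract around the DSB is deliberately not
modelled (retention near the DSB is governed solely by the ratio rule);
crossover position is uniform, with no recombination-hotspot or
sequence-dependent bias.

## Design optimization

`optimize_design` searches arm allocations exhaustively at 1-bp granularity
under a total-homology cap, each arm at least `min_arm`, placing the DSB in
the shorter arm at `min(min_arm_dsb, shorter arm)` from the nearer homology
end (`min_arm_dsb` defaults to `min_arm`).  Because every target base lies
on the 5′ side of a 3′-arm DSB, the worst-case retention for an allocation
is simply `len5 / L`, so the optimum pushes homology onto the productive
side — the asymmetric-arm strategy.  Allocations that would place the DSB
coordinate exactly on the first target base (where the ratio rule is
undefined) are skipped; their mirror images are enumerated instead.

## The synthetic library

The generator emulates an error-prone-PCR (Taq/Mn²⁺) plasmid library after
sub-cloning of the mutagenized fragment:

* **Clones.**  `n_clones` independent clones (default 17,000), each
  recombinant with probability `recombinant_fraction` (default 0.9).
  Non-recombinant clones are modelled as mutation-free vector.
* **Substitutions.**  Each base of the mutagenized window of a recombinant
  clone is substituted independently with probability `per_base_rate`
  (default 1/434 ≈ 2.30·10⁻³).  This per-base Bernoulli model (implemented
  exactly as a Binomial count plus uniform positions without replacement)
  guarantees at most one substitution per site; at these rates it is
  indistinguishable from a per-clone Poisson draw at reported precision.
  Only single-base substitutions are modelled: no indels, no multi-base
  changes, no PCR jackpot/sibling structure, no per-cycle error
  accumulation.
* **Spectrum.**  Uniform over the three alternative bases by default (no
  substitution bias is assumed); a transition-biased preset
  (`SubstitutionSpectrum.transition_biased`) is available for Taq-like
  chemistry.
* **Window.**  The default mutagenized window runs from 53 bp into the ORF
  to the DSB coordinate, i.e. (2553, 4559) on the default geometry, giving
  an in-ORF mutagenized length of 1,606 bp.  The 53-bp offset represents
  the upstream cloning site of the mutagenized fragment and was chosen so
  the default rate yields 1606/434 ≈ 3.70 expected ORF mutations per
  recombinant clone, internally consistent with the 1/434 density; the true
  offset of such a cloning site is vector-specific and configurable.
* **Template.**  When no real locus sequence is supplied, a synthetic
  template is generated: uniform random flanks and an ORF of uniform random
  sense codons between ATG and a stop.  Effect fractions
  (silent/missense/nonsense) are therefore properties of the random
  template and the genetic code, not of any particular gene; on uniform
  sense codons with a uniform spectrum the silent fraction is ≈ 0.23 and
  the nonsense fraction ≈ 0.04.  Real loci have their own codon usage, so
  library summaries report measured fractions rather than asserting fixed
  ones.

Effect classification translates the affected codon before and after with
the standard genetic code: same amino acid → silent, stop gained →
nonsense, otherwise missense (including loss of the terminal stop, which is
rare and has no separate category); positions outside the ORF are
noncoding.

## The screen model

`simulate_screen` composes five stages, each on an independent RNG
substream spawned from the screen seed:

1. **Transformation** — a multinomial draw of `n_transformants` (default
   164,000) with equal clone probabilities.
2. **Selective passages** — default three.  Growth is neutral: the screen
   media are supplemented so target-locus genotype does not affect fitness.
   Each passage grows transformants to `final_density_cells` (default
   3·10¹⁰) and transfers `cells_per_transfer` (default 10⁹) as a
   multinomial bottleneck.  Non-transformed cells (default initial pool
   10⁹) do not divide and their viable titer decays by
   `nontransformed_survival_per_passage` (default 0.1, an "essentially
   eliminated after three passages" choice; the true per-passage survival
   is organism- and media-specific).  Because the transfer vastly exceeds
   the number of original transformants, clones are not lost at
   bottlenecks.
3. **Annotation** — every distinct mutation in the library gets an effect
   label and, if missense, a sticky deleterious mark drawn once as
   Bernoulli(*f*): deleteriousness is a property of the allele, reused
   across every event and colony.
4. **Pop-out** — per scored colony, a uniform crossover and the retention
   rule above.  A `background_foar_fraction` of colonies (default 0.02)
   bypass pop-out entirely and score wild; this represents non-homologous
   integrants and spontaneous counterselection-resistant mutants, an
   order-of-magnitude anchor rather than a measured rate.  Colonies from
   non-recombinant clones carry no mutations and score wild.
5. **Phenotype** — mutant iff any retained mutation is deleterious; mutants
   are hypomorphic with probability *h* (default 0.11) else null.  Severity
   is a clone-level Bernoulli given mutant status — the minimal model
   consistent with an aggregate hypomorph fraction — not a per-mutation
   severity model, and any retained nonsense is null-causing regardless of
   codon position.  Colors: wild → white, null → red, hypomorph → pink.

## Closed-form mutant fraction and calibration

For deleterious mutations Poisson-distributed per clone (mean λ_del) with
positions uniform on the coding mutagenized window [*a*, *b*) 5′ of the
DSB, a colony is mutant iff the crossover falls 5′ of the most DSB-proximal
deleterious mutation, so

P(mutant) = (1 − background) · r · Σₙ≥₁ Pois(n; λ_del) · (a + (b − a)·n/(n+1)) / L,

with *r* the recombinant fraction.  The series is summed to numerical
exhaustion (Poisson tail below 10⁻¹⁴).  With λ_del = λ_ORF·(p_nonsense +
f·p_missense) this expectation is analytic and strictly increasing in *f*,
so `calibrate_deleterious_fraction` inverts it by bisection on [0, 1] to
10⁻⁶.  The observed mutant fraction confounds *f* with the background
colony rate; calibration is explicitly conditional on the assumed
background.

**Accuracy against the simulator.**  The closed form was checked against
the exact conditional expectation of the simulator on a 60,000-clone
library: bias ≈ +6·10⁻⁴ over 60 independent mark draws.  A single simulated
screen, however, fluctuates around the closed form with SD ≈ 4·10⁻³ —
dominated not by colony-count binomial error but by the sticky marks
themselves: the distinct-mutation space is only 3 × window ≈ 6,000 alleles,
each recurring in dozens of clones, so one Bernoulli mark moves many
colonies at once.  The oracle-equivalence and calibration-recovery tests
therefore average over six replicate screens and compare against the
empirical standard error of that mean, which is the actual sampling SD of
the quantity compared.

## Statistics module

* `p_at_least_one(λ) = 1 − e^(−λ)` (Poisson zero class; exact Binomial
  variant behind `exact_n`).
* `per_bp_multiplicity` = clones × recombinant fraction × mean ORF
  mutations / ORF length, divided by 3 in the per-alternative reading.
  Both readings are reported side by side: the per-alternative figure
  (≈ 11 on the defaults) is the natural "each specific substitution is
  sampled ~10×" claim, the any-change figure (≈ 34) the raw pileup.
* `representation`: expected unrepresented items n·(1 − 1/n)^draws (exact
  by linearity) and p(all present) ≈ exp(−expected missing); bottlenecks
  multiply per-item survival by 1 − e^(−B/n).
* `saturation`: per-base Poisson tails, expected uncovered bases, and
  p(every base covered ≥ k) ≈ exp(−expected uncovered).

Poisson approximations are used wherever a closed form is wanted; at
library scale they agree with exact Binomial/multinomial computations to
reported precision, and each is tested against a direct simulation oracle
on a small instance.

## Reproducibility

One global seed drives everything.  Pipeline stages and screen sub-stages
draw from independent substreams derived via `SeedSequence` salted with the
stage name (CRC-32), so adding or removing a stage does not perturb the
randomness of the others.  All seeds are echoed into every JSON report; TSV
outputs carry a header row and a comment line fixing the 0-based coordinate
convention, and identical seeds produce byte-identical outputs.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: 10⁵ pop-out events per
Monte-Carlo retention estimate; a 50,000-clone, 2,000-bp-window library for
density recovery; a 60,000-clone study-rate library with six replicate
100,000-colony screens for the closed-form and calibration checks; and
10³-replicate simulations of small occupancy instances.  These sizes put
Monte-Carlo error well below the tolerances asserted while keeping the full
suite under a minute of compute.

## What passing tests do and do not show

The generator reproduces the *statistical* structure of a real mutagenized
library (substitution density, recombinant fraction, stochastic positions,
genetic-code effect classes) but not sequence-specific structure: real
error-prone PCR has transition bias and position-dependent efficiency, real
loci have codon bias, real deleteriousness is not an i.i.d. coin flip per
missense allele, and real screens have colony-scoring error.  Passing tests
therefore validate the internal consistency of the model and its arithmetic
— the ratio rule, the saturation formulas, the calibration loop — not the
biological accuracy of any particular parameter value.  Known further
limitations: no conversion tracts at the DSB, no multimeric tandem arrays
or repeated pop-in/pop-out cycling, no fitness differences during passages,
and categorical (not image-based) colony colors.
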