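# tfg — population-scale pop-in, pop-out targeted forward genetics

`tfg` is a design and simulation toolkit for **targeted forward genetics**:
forward-genetic screens in which a saturated library of single-base
substitutions is installed at a chosen chromosomal locus by two-step
(pop-in, pop-out) allele replacement, and the resulting colonies are scored
for phenotype.  It is written for experimentalists planning such screens —
choosing homology-arm lengths and the double-strand-break (DSB) site,
sizing mutant libraries and transformations — and for anyone who wants a
quantitative, simulable model of the whole workflow.

## The model

A gene-targeting vector carries a region of homology to the target locus
(a 5′ arm, the target window such as an ORF, and a 3′ arm; total homology
*L*) plus a counterselectable marker (e.g. *ura4⁺*).  A restriction-site DSB
in the homology stimulates pop-in integration, producing a tandem
duplication; a later intrachromosomal crossover (pop-out) excises the
vector.  Modelling the pop-out crossover position *c* as uniform on
(0, *L*), a modification at base *m* survives pop-out with probability
equal to the fraction of homology on its **productive** (non-DSB) side:

> P(retain *m*) = *m* / *L*  (DSB 3′ of *m*), or (*L* − *m* − 1) / *L* (DSB 5′ of *m*).

This *homology length ratio rule* is the package's core statistic.  Around
it sit:

* a **library generator** emulating error-prone-PCR mutagenesis: per-base
  Bernoulli substitutions at rate 1/434 per bp over the mutagenized window,
  ~90 % recombinant clones, configurable substitution spectrum, and
  translation-based classification of each substitution as silent /
  missense / nonsense / noncoding;
* a **screen simulator**: multinomial transformation sampling, selective
  passages with bottlenecks (which also dilute away non-transformed cells),
  per-colony pop-out, and a minimal phenotype model — any retained nonsense
  mutation or retained "deleterious" missense mutation (a sticky
  Bernoulli(*f*) property of each allele) makes the colony mutant; mutants
  are hypomorphic with probability *h*, else null;
* **saturation statistics**: the Poisson zero-class 1 − e^(−λ) for the
  probability a clone carries ≥ 1 mutation, per-base coverage multiplicity,
  coupon-collector representation of clones among transformants, and
* **calibration**: closed-form expected mutant-colony fraction, inverted by
  bisection to estimate the deleterious-missense probability *f* from an
  observed screen.

## Worked example

Retention range for the asymmetric vector (2,500 bp 5′ homology, 1,659 bp
ORF, 800 bp 3′ homology, DSB 400 bp into the 3′ arm):

```
$ tfg design
total homology: 4959 bp; DSB at 4559
retention over target: 0.5041 (5'-most base) to 0.8385 (DSB-proximal base)
```

Every ORF position is retained in 50–84 % of pop-out events — the point of
putting most homology on the productive side of the target.

Library-scale arithmetic for 17,000 clones, 90 % recombinant, an average of
3.7 ORF mutations per clone and 164,000 transformants:

```
$ tfg coverage --clones 17000 --recombinant 0.9 --lambda-orf 3.7 \
               --orf-len 1659 --transformants 164000
{
  "expected_unrepresented_clones": 1.0981490177894848,
  "mean_protein_mutations_per_clone": 2.738,
  "p_at_least_one_per_clone": 0.9752764735296606,
  "per_bp_multiplicity_any_change": 34.12296564195298,
  "per_bp_multiplicity_per_alternative": 11.374321880650994,
  ...
}
```

So > 97 % of recombinant clones carry at least one ORF mutation, each base
is hit ~11 times per alternative base (~34 times counting any change), and
on average only ~1 of the 17,000 clones goes unrepresented among the
transformants.

Simulating the library and the screen end to end, then calibrating *f*
against an observed mutant-colony fraction of 15 %:

```
$ tfg simulate-library --clones 17000 --seed 1 --out lib.tsv
17000 clones (15318 recombinant); 71203 mutations; density 431.6 bp/mutation
$ tfg simulate-screen --library lib.tsv --colonies 2000 --seed 1 --out screen.json
2000 colonies: mutant fraction 0.165, hypomorphs among mutants 0.109
$ tfg calibrate --observed 0.15
{
  "deleterious_missense_prob": 0.0664834976196289,
  ...
}
```

i.e. a ~15 % mutant-colony rate is consistent with roughly 6–7 % of
missense substitutions being functionally deleterious (conditional on the
assumed 2 % background of colonies that bypassed pop-out — the two are
confounded in the observed fraction).

A full pipeline (design profile → template → library → screen → coverage
report) runs from a YAML configuration with one global seed:

```
$ tfg run config.yaml --set library.n_clones=17000
```

## Layout

| module | contents |
| --- | --- |
| `tfg.geometry` | `VectorDesign`, retention rule, profiles, arm-length optimizer |
| `tfg.library` | templates, `LibrarySpec`, library simulation, effect classification |
| `tfg.screen` | transformation, passages, pop-out, phenotypes, closed-form expectation |
| `tfg.stats` | saturation/coverage/representation arithmetic, calibration of *f* |
| `tfg.config` / `tfg.pipeline` / `tfg.cli` | YAML config, end-to-end pipeline, `tfg` CLI |

See `docs/methods.md` for the model's assumptions, parameter defaults, and
known limitations.
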