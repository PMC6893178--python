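"""Population-scale screen simulation: transformation through colony scoring.

Mirrors the bulk workflow: a linearized vector library is transformed into
cells (pop-in), transformants are expanded through selective passages that
dilute away non-transformed cells, one non-selective passage lets pop-out
recombinants accumulate, counterselective plating (FOA) recovers pop-out
colonies, and colonies are scored by phenotype.  Growth is neutral (the
screen media are supplemented so target-locus genotype does not affect
fitness), so passages only resample clone composition.

The pop-out event itself is a crossover drawn uniform over the shared
homology: mutations whose base centers lie on the DSB side of the crossover
are retained, the rest excise with the vector.  Phenotype follows a minimal
clone-level model: any retained nonsense mutation, or any retained missense
mutation marked deleterious (a sticky Bernoulli(f) property of the allele),
makes the colony mutant; mutants are hypomorphic with probability h, else
null.  Colony colors mirror the adenine-pathway readout: wild -> white,
null -> red, hypomorph -> pink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tfg.geometry import VectorDesign, is_dsb_distal
from tfg.library import (
    MISSENSE,
    NONSENSE,
    CloneGenotype,
    Mutation,
    classify_effect,
)

WILD = "wild"
NULL = "null"
HYPOMORPH = "hypomorph"
COLORS = {WILD: "white", NULL: "red", HYPOMORPH: "pink"}

__all__ = [
    "ScreenConfig",
    "PopoutOutcome",
    "ScreenResult",
    "sample_transformants",
    "simulate_passages",
    "simulate_popout",
    "annotate_mutations",
    "assign_phenotype",
    "simulate_screen",
    "expected_mutant_fraction",
    "WILD",
    "NULL",
    "HYPOMORPH",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the bulk screen.

    Defaults reproduce the study's workflow: ~164,000 transformants from a
    ~17,000-clone library, three selective passages transferring ~1e9 cells
    into cultures grown to ~3e10 cells, then colony scoring.  ``f`` is the
    probability that a missense mutation is deleterious (free parameter,
    calibrated against the observed mutant-colony fraction); ``h`` is the
    probability that a mutant is hypomorphic rather than null (observed
    ~11%).  ``background_foar_fraction`` models counterselection-resistant
    colonies that bypassed pop-out (non-homologous integrants, spontaneous
    marker mutations); default 2%, an order-of-magnitude anchor from the
    >=50-fold selective advantage of true tandem integrants.
    """

    n_transformants: int = 164_000
    n_passages_selective: int = 3
    cells_per_transfer: int = 1_000_000_000
    final_density_cells: int = 30_000_000_000
    nontransformed_survival_per_passage: float = 0.1
    n_nontransformed_cells: int = 1_000_000_000
    background_foar_fraction: float = 0.02
    deleterious_missense_prob: float = 0.06
    hypomorph_prob: float = 0.11
    n_colonies_scored: int = 2_000
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_transformants",
            "n_passages_selective",
            "cells_per_transfer",
            "final_density_cells",
            "n_colonies_scored",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "nontransformed_survival_per_passage",
            "background_foar_fraction",
            "deleterious_missense_prob",
            "hypomorph_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PopoutOutcome:
    """One pop-out event / scored colony.

    ``retained`` and the complement of the source clone's mutation set
    partition that set exactly; the retained set is the subset on the DSB
    side of the crossover.  ``crossover_pos`` is NaN for colonies that did
    not arise by pop-out (background colonies and colonies from
    non-recombinant vector).
    """

    source_clone_id: str | None
    crossover_pos: float
    retained: tuple[Mutation, ...]
    phenotype: str | None = None
    colony_color: str | None = None
    background: bool = False


@dataclass
class ScreenResult:
    """Colony-level outcomes plus aggregate counts for one simulated screen."""

    outcomes: list[PopoutOutcome]
    residual_nontransformed_fraction: float
    config: ScreenConfig

    @property
    def n_scored(self) -> int:
        return len(self.outcomes)

    @property
    def phenotype_counts(self) -> dict[str, int]:
        counts = {WILD: 0, NULL: 0, HYPOMORPH: 0}
        for o in self.outcomes:
            counts[o.phenotype] += 1
        return counts

    @property
    def n_background(self) -> int:
        return sum(o.background for o in self.outcomes)

    @property
    def mutant_fraction(self) -> float:
        c = self.phenotype_counts
        return (c[NULL] + c[HYPOMORPH]) / self.n_scored

    @property
    def hypomorph_fraction_of_mutants(self) -> float:
        c = self.phenotype_counts
        n_mut = c[NULL] + c[HYPOMORPH]
        return c[HYPOMORPH] / n_mut if n_mut else 0.0

    def colony_frame(self) -> pd.DataFrame:
        """One row per scored colony (TSV-ready)."""
        rows = [
            {
                "colony_id": f"col{i:06d}",
                "source_clone_id": o.source_clone_id or "",
                "crossover_pos": o.crossover_pos,
                "n_retained": len(o.retained),
                "phenotype": o.phenotype,
                "color": o.colony_color,
                "background_flag": int(o.background),
            }
            for i, o in enumerate(self.outcomes)
        ]
        return pd.DataFrame(rows)

    def aggregate_report(self, design: VectorDesign | None = None) -> dict:
        """JSON-ready aggregate: counts, fractions, retained-position histogram."""
        hist: dict[int, int] = {}
        max_dist = None
        n_distal = 0
        for o in self.outcomes:
            for m in o.retained:
                hist[m.pos] = hist.get(m.pos, 0) + 1
                if design is not None:
                    d = abs(m.pos - design.dsb_pos)
                    max_dist = d if max_dist is None else max(max_dist, d)
                    n_distal += is_dsb_distal(design, m.pos)
        report = {
            "n_colonies_scored": self.n_scored,
            "phenotype_counts": self.phenotype_counts,
            "mutant_fraction": self.mutant_fraction,
            "hypomorph_fraction_of_mutants": self.hypomorph_fraction_of_mutants,
            "n_background_colonies": self.n_background,
            "residual_nontransformed_fraction": self.residual_nontransformed_fraction,
            "retained_position_histogram": {str(k): v for k, v in sorted(hist.items())},
        }
        if design is not None:
            report["max_distance_from_dsb_bp"] = max_dist
            report["n_retained_dsb_distal"] = n_distal
        return report


def sample_transformants(
    n_clones: int, n_transformants: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of transformants with equal clone probabilities.

    Returns per-clone copy counts (length ``n_clones``).
    """
    if n_clones <= 0:
        raise ValueError("library must be nonempty")
    if n_transformants <= 0:
        raise ValueError("n_transformants must be positive")
    return rng.multinomial(n_transformants, np.full(n_clones, 1.0 / n_clones))


def simulate_passages(
    counts: np.ndarray, config: ScreenConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Selective passages: neutral growth plus a multinomial bottleneck.

    Each passage grows the transformed population uniformly to
    ``final_density_cells`` (no fitness differences), then transfers
    ``cells_per_transfer`` cells into fresh medium as a multinomial
    bottleneck over clones.  Non-transformed cells do not divide; their
    viable titer decays by ``nontransformed_survival_per_passage`` per
    passage and they are carried along proportionally at each transfer.

    Returns the final clone copy counts and the residual non-transformed
    fraction of the final culture.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValueError("no transformants to passage")
    t = counts.astype(float)
    n_nt = float(config.n_nontransformed_cells)
    for _ in range(config.n_passages_selective):
        grown_t = config.final_density_cells  # transformed biomass after growth
        n_nt *= config.nontransformed_survival_per_passage
        frac_nt = n_nt / (grown_t + n_nt)
        n_nt = config.cells_per_transfer * frac_nt
        n_t_transfer = int(round(config.cells_per_transfer * (1 - frac_nt)))
        t = rng.multinomial(n_t_transfer, t / t.sum()).astype(float)
    residual = n_nt / (n_nt + t.sum())
    return t.astype(np.int64), residual


def simulate_popout(
    clone: CloneGenotype, design: VectorDesign, rng: np.random.Generator
) -> PopoutOutcome:
    """One pop-out recombination event for a recombinant clone.

    The crossover position is uniform on ``(0, L)``; a mutation is retained
    iff the crossover lies on the opposite side of the mutation's base
    center from the DSB (crossovers on the DSB side of a modification are
    invariably non-productive, wherever they fall).  For the usual geometry
    -- all mutations 5' of a DSB at high coordinate -- the retained set is
    the contiguous run of mutations between the crossover and the DSB.
    Phenotype is left unassigned.

    Raises
    ------
    ValueError
        For a non-recombinant clone ("no tandem duplication").
    """
    if not clone.recombinant:
        raise ValueError("no tandem duplication: non-recombinant clone cannot pop out")
    L = design.total_homology
    dsb = design.dsb_pos
    c = rng.uniform(0.0, L)
    retained = tuple(
        m for m in clone.mutations if (m.pos + 0.5 < c) != (m.pos + 0.5 < dsb)
    )
    return PopoutOutcome(clone.clone_id, c, retained)


def annotate_mutations(
    clones: Sequence[CloneGenotype],
    template: str,
    orf_interval: tuple[int, int],
    f: float,
    rng: np.random.Generator,
) -> tuple[dict[Mutation, str], dict[Mutation, bool]]:
    """Effect labels and sticky deleterious marks for every distinct mutation.

    A missense mutation is deleterious with probability ``f``, drawn once
    per distinct mutation (the mark is a property of the allele and is
    reused across all pop-out events and colonies); nonsense mutations are
    always deleterious, everything else never is.  Mutations are processed
    in sorted order so the draw is deterministic given the generator state.
    """
    distinct = sorted({m for c in clones for m in c.mutations})
    effects: dict[Mutation, str] = {}
    marks: dict[Mutation, bool] = {}
    for m in distinct:
        eff = classify_effect(template, orf_interval, m)
        effects[m] = eff
        if eff == NONSENSE:
            marks[m] = True
        elif eff == MISSENSE:
            marks[m] = bool(rng.random() < f)
        else:
            marks[m] = False
    return effects, marks


def assign_phenotype(
    outcome: PopoutOutcome,
    effects: Mapping[Mutation, str],
    deleterious: Mapping[Mutation, bool],
    h: float,
    rng: np.random.Generator,
) -> PopoutOutcome:
    """Attach phenotype and colony color to a pop-out outcome.

    Mutant iff any retained mutation is deleterious (nonsense, or missense
    carrying a sticky deleterious mark); mutants are hypomorphic with
    probability ``h``, else null.  A random draw is consumed only for
    mutant colonies.

    Raises
    ------
    ValueError
        If a retained mutation has no effect annotation.
    """
    for m in outcome.retained:
        if m not in effects:
            raise ValueError(f"missing effect annotation for {m}")
    mutant = any(deleterious.get(m, False) for m in outcome.retained)
    if mutant:
        phen = HYPOMORPH if rng.random() < h else NULL
    else:
        phen = WILD
    return replace(outcome, phenotype=phen, colony_color=COLORS[phen])


def simulate_screen(
    clones: Sequence[CloneGenotype],
    template: str,
    design: VectorDesign,
    config: ScreenConfig,
) -> ScreenResult:
    """Full bulk screen: transformation, passages, pop-out, phenotyping.

    A ``background_foar_fraction`` of scored colonies bypass pop-out and are
    wild-genotype (flagged ``background``); colonies from non-recombinant
    clones carry no mutations and score wild.  Deterministic given
    ``config.seed`` (independent substreams per stage).
    """
    ss = np.random.SeedSequence(config.seed)
    r_trans, r_pass, r_marks, r_col = (np.random.default_rng(s) for s in ss.spawn(4))

    orf_interval = design.orf_interval
    counts = sample_transformants(len(clones), config.n_transformants, r_trans)
    counts, residual_nt = simulate_passages(counts, config, r_pass)
    effects, marks = annotate_mutations(
        clones, template, orf_interval, config.deleterious_missense_prob, r_marks
    )

    total = counts.sum()
    if total == 0:
        raise ValueError("screen requires surviving transformants")
    probs = counts / total
    n = config.n_colonies_scored
    is_bg = r_col.random(n) < config.background_foar_fraction
    idx = r_col.choice(len(clones), size=n, p=probs)
    outcomes: list[PopoutOutcome] = []
    h = config.hypomorph_prob
    for i in range(n):
        if is_bg[i]:
            o = PopoutOutcome(None, math.nan, (), WILD, COLORS[WILD], background=True)
            outcomes.append(o)
            continue
        clone = clones[idx[i]]
        if not clone.recombinant:
            o = PopoutOutcome(clone.clone_id, math.nan, (), WILD, COLORS[WILD])
            outcomes.append(o)
            continue
        o = simulate_popout(clone, design, r_col)
        outcomes.append(assign_phenotype(o, effects, marks, h, r_col))
    return ScreenResult(outcomes, residual_nt, config)


def expected_mutant_fraction(
    design: VectorDesign,
    mean_deleterious_per_clone: float,
    window: tuple[int, int] | None = None,
    recombinant_fraction: float = 1.0,
    background: float = 0.0,
) -> float:
    """Closed-form expectation of the scored mutant-colony fraction.

    Model: deleterious mutation positions are uniform on ``window`` (the
    coding part of the mutagenized region, entirely on the 5' side of the
    DSB) and per-clone counts are Poisson with the given mean.  A colony is
    mutant iff the crossover falls 5' of the most DSB-proximal deleterious
    mutation, so conditional on ``n >= 1`` deleterious mutations the mutant
    probability is ``E[max of n uniforms] / L = (a + (b - a) n/(n+1)) / L``.
    The Poisson mixture is scaled by the recombinant fraction (colonies from
    non-recombinant vector are wild) and by ``1 - background``.

    The typical per-clone mean is small (a few), so the series is summed to
    numerical exhaustion rather than truncated at a fixed term.
    """
    lam = mean_deleterious_per_clone
    if lam < 0:
        raise ValueError("mean_deleterious_per_clone must be >= 0")
    if window is None:
        window = design.coding_mutagenized_window
    if window is None:
        raise ValueError("no window given and design has no coding mutagenized window")
    a, b = window
    if b > design.dsb_pos:
        raise ValueError("window must lie on the 5' side of the DSB")
    if lam == 0:
        return 0.0
    L = design.total_homology
    n_max = int(sps.poisson.ppf(1 - 1e-14, lam)) + 2
    ns = np.arange(1, n_max + 1)
    pmf = sps.poisson.pmf(ns, lam)
    e_max = (a + (b - a) * ns / (ns + 1.0)) / L
    q = float(np.sum(pmf * e_max))
    return (1.0 - background) * recombinant_fraction * q
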