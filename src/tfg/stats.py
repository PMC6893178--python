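"""Library saturation, coverage and representation arithmetic, and
calibration of the deleterious-missense fraction.

Closed forms use Poisson approximations throughout (exact Binomial variants
are available behind a flag where the distinction could matter); on the
library scales involved the two agree to reported precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

from scipy import optimize
from scipy import stats as sps

from tfg.geometry import VectorDesign
from tfg.screen import expected_mutant_fraction

__all__ = [
    "CoverageReport",
    "Representation",
    "SaturationReport",
    "p_at_least_one",
    "expected_protein_mutations",
    "per_bp_multiplicity",
    "representation",
    "saturation",
    "coverage_report",
    "calibrate_deleterious_fraction",
]


def p_at_least_one(mean_mutations: float, exact_n: int | None = None) -> float:
    """Probability a clone carries >= 1 mutation, ``1 - exp(-lambda)``.

    ``exact_n`` switches to the Binomial zero-class over ``n`` bases at rate
    ``lambda / n``.
    """
    if mean_mutations < 0:
        raise ValueError("mean_mutations must be >= 0")
    if exact_n is not None:
        return 1.0 - (1.0 - mean_mutations / exact_n) ** exact_n
    return -math.expm1(-mean_mutations)


def expected_protein_mutations(
    mean_bp_mutations: float, silent_fraction: float
) -> float:
    """Mean protein-altering mutations per clone: ``lambda * (1 - silent)``."""
    if mean_bp_mutations < 0 or not 0 <= silent_fraction <= 1:
        raise ValueError("inputs must be non-negative with silent_fraction in [0, 1]")
    return mean_bp_mutations * (1.0 - silent_fraction)


def per_bp_multiplicity(
    n_clones: int,
    recombinant_fraction: float,
    mean_orf_mutations: float,
    orf_len: int,
    per_alternative: bool = True,
) -> float:
    """How many times an average ORF base is mutated across the library.

    ``n_clones * recombinant_fraction * mean_orf_mutations / orf_len``;
    with ``per_alternative`` the figure is divided by 3 to count each of a
    base's three possible substitutions separately (the reading that
    reproduces the ~10x coverage figure; the any-change variant is about
    three-fold higher and is reported alongside it in coverage reports).
    """
    if orf_len <= 0:
        raise ValueError("orf_len must be positive")
    if n_clones < 0 or mean_orf_mutations < 0 or not 0 <= recombinant_fraction <= 1:
        raise ValueError("invalid library parameters")
    fold = n_clones * recombinant_fraction * mean_orf_mutations / orf_len
    return fold / 3.0 if per_alternative else fold


@dataclass(frozen=True)
class Representation:
    """Occupancy summary: how completely draws cover a set of items."""

    expected_missing: float
    p_all_present: float


def representation(
    n_items: int, n_draws: int, bottlenecks: Sequence[int] = ()
) -> Representation:
    """Expected unrepresented items after sampling and optional bottlenecks.

    ``expected_missing = n * (1 - 1/n)^draws`` (exact by linearity);
    ``p_all_present ~= exp(-expected_missing)`` (Poisson approximation to
    inclusion-exclusion).  Each bottleneck of ``B`` cells multiplies the
    per-item survival by ``1 - exp(-B / n_items)``, treating composition as
    uniform; survivals compose multiplicatively across stages.
    """
    if n_items <= 0 or n_draws <= 0:
        raise ValueError("n_items and n_draws must be positive")
    p_present = 1.0 - (1.0 - 1.0 / n_items) ** n_draws
    for b in bottlenecks:
        if b <= 0:
            raise ValueError("bottleneck sizes must be positive")
        p_present *= -math.expm1(-b / n_items)
    expected_missing = n_items * (1.0 - p_present)
    return Representation(expected_missing, math.exp(-expected_missing))


@dataclass(frozen=True)
class SaturationReport:
    """Per-base coverage tail of a saturated library."""

    expected_uncovered: float
    p_every_bp_covered: float


def saturation(per_bp_mean_coverage: float, k: int, length: int) -> SaturationReport:
    """Probability every base of a ``length``-bp window is hit >= ``k`` times.

    Per-base counts are Poisson with the given mean; expected uncovered
    bases = ``length * P(X < k)`` and the all-covered probability is
    approximated as ``exp(-expected_uncovered)``.
    """
    if per_bp_mean_coverage < 0 or k < 1 or length <= 0:
        raise ValueError("require mean >= 0, k >= 1, length > 0")
    p_below = float(sps.poisson.cdf(k - 1, per_bp_mean_coverage))
    expected_uncovered = length * p_below
    return SaturationReport(expected_uncovered, math.exp(-expected_uncovered))


@dataclass(frozen=True)
class CoverageReport:
    """Library-scale coverage summary assembled from the closed forms."""

    mean_mutations_per_clone: float
    mean_protein_mutations_per_clone: float
    density_bp_per_mutation: float
    p_at_least_one_per_clone: float
    per_bp_multiplicity_per_alternative: float
    per_bp_multiplicity_any_change: float
    expected_unrepresented_clones: float | None
    p_every_bp_covered_k: float
    expected_uncovered_bp: float

    def to_dict(self) -> dict:
        return asdict(self)


def coverage_report(
    n_clones: int,
    recombinant_fraction: float,
    mean_orf_mutations: float,
    orf_len: int,
    silent_fraction: float = 0.26,
    n_transformants: int | None = None,
    k: int = 1,
) -> CoverageReport:
    """Assemble the full coverage summary for a library design.

    ``expected_unrepresented_clones`` is filled only when a transformant
    count is given.  Saturation (``k``-fold per-alternative coverage of each
    ORF base) uses the per-alternative multiplicity as the Poisson mean.
    """
    mult_alt = per_bp_multiplicity(
        n_clones, recombinant_fraction, mean_orf_mutations, orf_len, True
    )
    mult_any = per_bp_multiplicity(
        n_clones, recombinant_fraction, mean_orf_mutations, orf_len, False
    )
    sat = saturation(mult_alt, k, orf_len)
    rep = (
        representation(n_clones, n_transformants)
        if n_transformants is not None
        else None
    )
    return CoverageReport(
        mean_mutations_per_clone=mean_orf_mutations,
        mean_protein_mutations_per_clone=expected_protein_mutations(
            mean_orf_mutations, silent_fraction
        ),
        density_bp_per_mutation=orf_len / mean_orf_mutations,
        p_at_least_one_per_clone=p_at_least_one(mean_orf_mutations),
        per_bp_multiplicity_per_alternative=mult_alt,
        per_bp_multiplicity_any_change=mult_any,
        expected_unrepresented_clones=rep.expected_missing if rep else None,
        p_every_bp_covered_k=sat.p_every_bp_covered,
        expected_uncovered_bp=sat.expected_uncovered,
    )


def calibrate_deleterious_fraction(
    observed_mutant_fraction: float,
    design: VectorDesign,
    mean_orf_mutations: float,
    nonsense_fraction: float,
    missense_fraction: float,
    recombinant_fraction: float = 1.0,
    background: float = 0.0,
    window: tuple[int, int] | None = None,
    tol: float = 1e-6,
) -> float:
    """Solve for the deleterious-missense probability ``f``.

    Inverts the closed-form ``expected_mutant_fraction`` with a bisection
    root-find on ``f`` in ``[0, 1]`` to ``tol``; the expectation is analytic
    and strictly increasing in ``f`` whenever the missense rate is nonzero,
    so the root is unique.  Note the observed fraction confounds ``f`` with
    the background colony rate: calibration is conditional on the assumed
    ``background``.

    Raises
    ------
    ValueError
        If the observed fraction lies outside the attainable interval
        (the values at ``f = 0`` and ``f = 1``), naming that interval.
    """

    def g(f: float) -> float:
        lam = mean_orf_mutations * (nonsense_fraction + f * missense_fraction)
        return expected_mutant_fraction(
            design, lam, window, recombinant_fraction, background
        )

    lo, hi = g(0.0), g(1.0)
    obs = observed_mutant_fraction
    if not lo <= obs <= hi:
        raise ValueError(
            f"observed mutant fraction {obs:.6f} outside the attainable "
            f"interval [{lo:.6f}, {hi:.6f}] for these parameters"
        )
    if obs == lo:
        return 0.0
    if obs == hi:
        return 1.0
    return float(optimize.bisect(lambda f: g(f) - obs, 0.0, 1.0, xtol=tol))
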