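"""Synthetic mutagenized gene-targeting vector libraries.

Emulates a plasmid library produced by error-prone (Taq/Mn2+) PCR of the
target region followed by sub-cloning: every clone is either recombinant
(carries the mutagenized insert) or not (mutation-free vector), and each
recombinant clone carries an independent set of single-base substitutions
scattered over the mutagenized window.  The study conditions this generator
reproduces by default: ~17,000 independent clones, ~90% recombinant, one
substitution per 434 bp of mutagenized sequence, single-base substitutions
only, stochastic positions.

Substitutions are drawn per base as independent Bernoulli events (exactly
equivalent to drawing a Binomial count and then positions uniformly without
replacement, which is how it is implemented); this guarantees at most one
mutation per site, matching the clone-genotype invariant.  The substitution
spectrum defaults to uniform over the three alternative bases; a
transition-biased preset is available for Taq-like chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _STANDARD.forward_table if set(c) <= set(BASES))
)

SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
NONCODING = "noncoding"

__all__ = [
    "SubstitutionSpectrum",
    "Mutation",
    "CloneGenotype",
    "LibrarySpec",
    "LibrarySummary",
    "generate_template",
    "simulate_library",
    "classify_effect",
    "summarize_library",
    "SILENT",
    "MISSENSE",
    "NONSENSE",
    "NONCODING",
    "SENSE_CODONS",
    "STOP_CODONS",
]


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Conditional substitution probabilities, ref base -> alternative base.

    ``probs[ref]`` maps each of the three alternatives of ``ref`` to its
    conditional probability; each row sums to 1.
    """

    probs: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for ref in BASES:
            if ref not in self.probs:
                raise ValueError(f"spectrum missing row for {ref}")
            row = self.probs[ref]
            alts = set(BASES) - {ref}
            if set(row) != alts:
                raise ValueError(f"row {ref} must cover exactly {sorted(alts)}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative probability in row {ref}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"row {ref} must sum to 1")

    @classmethod
    def uniform(cls) -> "SubstitutionSpectrum":
        """Uniform over the three alternatives (default; no reported bias)."""
        third = 1.0 / 3.0
        return cls({r: {a: third for a in BASES if a != r} for r in BASES})

    @classmethod
    def transition_biased(cls, ratio: float = 4.0) -> "SubstitutionSpectrum":
        """Transitions weighted ``ratio``-fold over each transversion.

        Taq polymerase under Mn2+ favors transitions (A<->G, C<->T).
        """
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        probs: dict[str, dict[str, float]] = {}
        for r in BASES:
            w = {a: (ratio if a == transition[r] else 1.0) for a in BASES if a != r}
            tot = sum(w.values())
            probs[r] = {a: v / tot for a, v in w.items()}
        return cls(probs)

    def _arrays(self) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
        out = {}
        for r in BASES:
            alts = tuple(sorted(self.probs[r]))
            out[r] = (alts, np.array([self.probs[r][a] for a in alts]))
        return out


@dataclass(frozen=True, order=True)
class Mutation:
    """A single-base substitution at a homology coordinate."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be one of {BASES}")


@dataclass(frozen=True)
class CloneGenotype:
    """One library clone: recombinant status plus its substitution set."""

    clone_id: str
    recombinant: bool
    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        if not self.recombinant and self.mutations:
            raise ValueError("non-recombinant clones carry no mutations")
        positions = [m.pos for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError("no two mutations may share a position")
        if positions != sorted(positions):
            object.__setattr__(self, "mutations", tuple(sorted(self.mutations)))


@dataclass(frozen=True)
class LibrarySpec:
    """Stochastic parameters of the mutagenized plasmid library.

    ``per_base_rate`` is the independent substitution probability per base of
    the mutagenized window; the mean substitutions per recombinant clone is
    ``per_base_rate * (window length)``.
    """

    n_clones: int
    recombinant_fraction: float
    per_base_rate: float
    window: tuple[int, int]
    spectrum: SubstitutionSpectrum = field(default_factory=SubstitutionSpectrum.uniform)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if not 0 <= self.recombinant_fraction <= 1:
            raise ValueError("recombinant_fraction must be in [0, 1]")
        if not 0 <= self.per_base_rate < 1:
            raise ValueError("per_base_rate must be in [0, 1)")
        a, b = self.window
        if a >= b:
            raise ValueError(f"empty window {self.window}")

    @classmethod
    def ade6_default(cls, seed: int | None = None) -> "LibrarySpec":
        """The study library: 17,000 clones, 90% recombinant, 1/434 bp."""
        return cls(
            n_clones=17_000,
            recombinant_fraction=0.9,
            per_base_rate=1.0 / 434.0,
            window=(2553, 4559),
            seed=seed,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_template(
    len5: int, orf_len: int, len3: int, seed=None
) -> tuple[str, tuple[int, int]]:
    """Random locus template with a well-formed central ORF.

    The ORF starts with ATG, ends with a stop codon, and its internal codons
    are drawn uniformly from the 61 sense codons (so it contains no internal
    stop).  Flanks are uniform random bases.  Stands in for a real target
    locus when no sequence is supplied.

    Returns
    -------
    (sequence, orf_interval)
        The template string and the half-open ORF interval
        ``(len5, len5 + orf_len)``.
    """
    if orf_len % 3 != 0 or orf_len < 6:
        raise ValueError(f"orf_len must be a multiple of 3 and >= 6, got {orf_len}")
    if len5 < 0 or len3 < 0:
        raise ValueError("flank lengths must be non-negative")
    rng = _as_rng(seed)
    flank5 = "".join(rng.choice(BASES, size=len5)) if len5 else ""
    flank3 = "".join(rng.choice(BASES, size=len3)) if len3 else ""
    n_internal = orf_len // 3 - 2
    internal = "".join(rng.choice(SENSE_CODONS, size=n_internal)) if n_internal else ""
    stop = str(rng.choice(STOP_CODONS))
    seq = flank5 + "ATG" + internal + stop + flank3
    return seq, (len5, len5 + orf_len)


def simulate_library(template: str, spec: LibrarySpec) -> list[CloneGenotype]:
    """Draw a full clone library from ``spec`` over ``template``.

    Each clone is recombinant with probability ``recombinant_fraction``;
    each base of the window of a recombinant clone is substituted
    independently with probability ``per_base_rate``, the alternative drawn
    from the spectrum.  Deterministic given ``spec.seed``.
    """
    a, b = spec.window
    if not (0 <= a < b <= len(template)):
        raise ValueError(
            f"window {spec.window} outside template of length {len(template)}"
        )
    rng = _as_rng(spec.seed)
    w = b - a
    spectrum = spec.spectrum._arrays()
    recomb = rng.random(spec.n_clones) < spec.recombinant_fraction
    counts = rng.binomial(w, spec.per_base_rate, size=spec.n_clones)
    clones: list[CloneGenotype] = []
    width = max(6, len(str(spec.n_clones)))
    for i in range(spec.n_clones):
        cid = f"c{i:0{width}d}"
        if not recomb[i]:
            clones.append(CloneGenotype(cid, recombinant=False))
            continue
        k = int(counts[i])
        if k == 0:
            clones.append(CloneGenotype(cid, recombinant=True))
            continue
        pos = np.sort(rng.choice(w, size=k, replace=False)) + a
        muts = []
        for p in pos:
            ref = template[p]
            alts, probs = spectrum[ref]
            alt = alts[rng.choice(len(alts), p=probs)]
            muts.append(Mutation(int(p), ref, alt))
        clones.append(CloneGenotype(cid, recombinant=True, mutations=tuple(muts)))
    return clones


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_effect(
    template: str, orf_interval: tuple[int, int], mutation: Mutation
) -> str:
    """Coding effect of a single-base substitution.

    ``noncoding`` outside the ORF; inside it, the affected codon is
    translated before and after with the standard genetic code: identical
    amino acid -> ``silent``; stop gained -> ``nonsense``; anything else
    (including loss of the terminal stop) -> ``missense``.

    Raises
    ------
    ValueError
        If the mutation's ref base does not match the template.
    """
    pos = mutation.pos
    if not 0 <= pos < len(template):
        raise ValueError(f"position {pos} outside template")
    if template[pos] != mutation.ref:
        raise ValueError(
            f"reference mismatch at {pos}: template has {template[pos]}, "
            f"mutation claims {mutation.ref}"
        )
    start, end = orf_interval
    if not start <= pos < end:
        return NONCODING
    ci = (pos - start) // 3
    off = (pos - start) % 3
    cstart = start + 3 * ci
    codon = template[cstart : cstart + 3]
    new_codon = codon[:off] + mutation.alt + codon[off + 1 :]
    aa_old = _translate_codon(codon)
    aa_new = _translate_codon(new_codon)
    if aa_new == aa_old:
        return SILENT
    if aa_new == "*":
        return NONSENSE
    return MISSENSE


@dataclass
class LibrarySummary:
    """Summary statistics of a clone library.

    Means and fractions are over recombinant clones (non-recombinant clones
    are mutation-free vector and dilute the library rather than contribute
    mutations).  ``density_bp_per_mutation`` is total mutagenized bases
    across recombinant clones divided by total mutations (``None`` when no
    mutation was drawn).  ``effect_fractions`` is normalized over coding
    mutations only; ``noncoding_fraction`` is reported separately over all
    mutations.
    """

    n_clones: int
    n_recombinant: int
    n_mutations: int
    mean_mutations_per_clone_window: float
    mean_mutations_per_clone_orf: float
    density_bp_per_mutation: float | None
    fraction_clones_with_orf_mutation: float
    effect_fractions: dict[str, float]
    noncoding_fraction: float
    per_position_counts: np.ndarray


def summarize_library(
    clones: Sequence[CloneGenotype],
    template: str,
    orf_interval: tuple[int, int],
    window: tuple[int, int] | None = None,
) -> LibrarySummary:
    """Aggregate per-clone and per-position statistics of a library.

    ``window`` is the mutagenized interval used for the bp-per-mutation
    density; when omitted it is inferred as the ORF interval.
    """
    if not clones:
        raise ValueError("empty clone collection")
    if window is None:
        window = orf_interval
    wlen = window[1] - window[0]
    s, e = orf_interval
    recombinant = [c for c in clones if c.recombinant]
    n_rec = len(recombinant)
    per_pos = np.zeros(len(template), dtype=int)
    effect_counts = {SILENT: 0, MISSENSE: 0, NONSENSE: 0, NONCODING: 0}
    effect_cache: dict[tuple[int, str], str] = {}
    total = 0
    total_orf = 0
    with_orf = 0
    for c in recombinant:
        orf_hits = 0
        for m in c.mutations:
            total += 1
            per_pos[m.pos] += 1
            key = (m.pos, m.alt)
            eff = effect_cache.get(key)
            if eff is None:
                eff = classify_effect(template, orf_interval, m)
                effect_cache[key] = eff
            effect_counts[eff] += 1
            if s <= m.pos < e:
                orf_hits += 1
        total_orf += orf_hits
        if orf_hits:
            with_orf += 1
    coding = total - effect_counts[NONCODING]
    effect_fracs = {
        k: (effect_counts[k] / coding if coding else 0.0)
        for k in (SILENT, MISSENSE, NONSENSE)
    }
    return LibrarySummary(
        n_clones=len(clones),
        n_recombinant=n_rec,
        n_mutations=total,
        mean_mutations_per_clone_window=total / n_rec if n_rec else 0.0,
        mean_mutations_per_clone_orf=total_orf / n_rec if n_rec else 0.0,
        density_bp_per_mutation=(n_rec * wlen / total) if total else None,
        fraction_clones_with_orf_mutation=with_orf / n_rec if n_rec else 0.0,
        effect_fractions=effect_fracs,
        noncoding_fraction=effect_counts[NONCODING] / total if total else 0.0,
        per_position_counts=per_pos,
    )
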