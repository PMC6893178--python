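"""Targeting-vector geometry and the homology-length-ratio retention model.

Pop-in, pop-out allele replacement integrates a gene-targeting vector at its
genomic target locus (pop-in, stimulated by a double-strand break in the
vector's homology region) and later excises it by intrachromosomal
recombination between the resulting tandem repeats (pop-out).  A crossover on
the DSB side of a given modification excises the modified copy
(non-productive); a crossover on the non-DSB ("productive") side leaves the
modification in the chromosome.  Under a crossover position that is uniform
over the shared homology, the probability that a modification is retained
equals the fraction of homology on its productive side -- the homology
length ratio rule.  This module represents vector geometry on a single
homology axis and implements that rule.

Coordinate conventions
----------------------
Coordinates are 0-based on the homology axis, origin at the 5' end of the
homology region.  Base ``i`` occupies the half-open interval ``[i, i + 1)``
with center ``i + 0.5``; ``dsb_pos`` is a between-base coordinate in
``(0, L)`` where ``L`` is the total homology length.  Intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FIVE_PRIME = "five-prime"
THREE_PRIME = "three-prime"

__all__ = [
    "VectorDesign",
    "total_homology",
    "productive_side",
    "retention_probability",
    "retention_profile",
    "optimize_design",
    "distance_from_dsb",
    "is_dsb_distal",
    "FIVE_PRIME",
    "THREE_PRIME",
]


@dataclass(frozen=True)
class VectorDesign:
    """Geometry of a pop-in, pop-out gene-targeting vector.

    Parameters
    ----------
    len5, len_target, len3
        Lengths (bp) of the 5' homology arm, the central target region
        (typically the ORF being mutagenized), and the 3' homology arm.
        All must be positive.  Total homology ``L = len5 + len_target + len3``.
    dsb_pos
        Between-base coordinate of the recombination-initiating double-strand
        break on the homology axis, ``0 < dsb_pos < L``.
    mutagenized_window
        Optional half-open interval ``[start, end)`` on the homology axis
        within which library mutations may occur.  Must lie inside ``[0, L)``.
    """

    len5: int
    len_target: int
    len3: int
    dsb_pos: int
    mutagenized_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("len5", "len_target", "len3"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        L = self.len5 + self.len_target + self.len3
        if not 0 < self.dsb_pos < L:
            raise ValueError(
                f"dsb_pos must lie strictly inside the homology (0, {L}), got {self.dsb_pos}"
            )
        if self.mutagenized_window is not None:
            a, b = self.mutagenized_window
            if not (0 <= a < b <= L):
                raise ValueError(
                    f"mutagenized_window must be a non-empty sub-interval of [0, {L}), got {self.mutagenized_window}"
                )

    @property
    def total_homology(self) -> int:
        return self.len5 + self.len_target + self.len3

    @property
    def orf_interval(self) -> tuple[int, int]:
        """Half-open interval of the central target region."""
        return (self.len5, self.len5 + self.len_target)

    @property
    def coding_mutagenized_window(self) -> tuple[int, int] | None:
        """Intersection of the mutagenized window with the target region."""
        if self.mutagenized_window is None:
            return None
        a, b = self.mutagenized_window
        s, e = self.orf_interval
        lo, hi = max(a, s), min(b, e)
        return (lo, hi) if lo < hi else None

    @classmethod
    def ade6(cls) -> "VectorDesign":
        """The fission-yeast ade6 vector used to develop the method.

        2,500 bp 5' homology, 1,659 bp ORF, 800 bp 3' homology; DSB (SpeI)
        400 bp into the 800 bp 3' arm; mutagenized window from 53 bp into
        the ORF to the DSB (in-ORF mutagenized length 1,606 bp).
        """
        return cls(
            len5=2500,
            len_target=1659,
            len3=800,
            dsb_pos=2500 + 1659 + 400,
            mutagenized_window=(2500 + 53, 2500 + 1659 + 400),
        )


def total_homology(design: VectorDesign) -> int:
    """Total shared homology length ``L`` in base pairs."""
    return design.total_homology


def _check_pos(design: VectorDesign, pos: int) -> None:
    L = design.total_homology
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} outside homology [0, {L})")


def productive_side(design: VectorDesign, pos: int) -> str:
    """Side of position ``pos`` that does NOT contain the DSB.

    Pop-out crossovers on the non-DSB side of a modification are invariably
    productive (they leave the modification in the chromosome), so this is
    the side whose homology length sets the retention probability.

    Raises
    ------
    ValueError
        If ``pos`` is outside the homology or coincides with ``dsb_pos``
        ("mutation at DSB is undefined").
    """
    _check_pos(design, pos)
    if pos == design.dsb_pos:
        raise ValueError("mutation at DSB is undefined")
    return FIVE_PRIME if pos < design.dsb_pos else THREE_PRIME


def retention_probability(design: VectorDesign, pos: int) -> float:
    """Probability that a modification at base ``pos`` survives pop-out.

    Equals the fraction of homology strictly on the productive (non-DSB)
    side of the base: ``pos / L`` when the DSB lies 3' of the base, and
    ``(L - pos - 1) / L`` when the DSB lies 5' of it.  Always in ``[0, 1)``;
    zero only for the base adjacent to the non-DSB homology end.
    """
    side = productive_side(design, pos)  # validates pos
    L = design.total_homology
    if side == FIVE_PRIME:
        return pos / L
    return (L - pos - 1) / L


def retention_profile(
    design: VectorDesign, window: tuple[int, int] | None = None
) -> pd.Series:
    """Per-base retention probabilities over ``window``.

    Parameters
    ----------
    design
        Vector geometry.
    window
        Half-open interval on the homology axis; defaults to the design's
        mutagenized window.  Must be non-empty, lie inside the homology, and
        exclude ``dsb_pos``.

    Returns
    -------
    pandas.Series
        Indexed by base position (name ``pos``), values named
        ``retention_probability``; monotone in distance from the non-DSB
        homology end.
    """
    if window is None:
        window = design.mutagenized_window
    if window is None:
        raise ValueError("no window given and design has no mutagenized_window")
    a, b = window
    if a >= b:
        raise ValueError(f"empty window {window}")
    L = design.total_homology
    if not (0 <= a and b <= L):
        raise ValueError(f"window {window} outside homology [0, {L})")
    if a <= design.dsb_pos < b:
        raise ValueError(f"window {window} must exclude dsb_pos {design.dsb_pos}")
    pos = np.arange(a, b)
    vals = np.where(pos < design.dsb_pos, pos / L, (L - pos - 1) / L)
    return pd.Series(vals, index=pd.Index(pos, name="pos"), name="retention_probability")


def distance_from_dsb(design: VectorDesign, pos: int) -> int:
    """Distance (bp) between a homology position and the DSB coordinate."""
    _check_pos(design, pos)
    return abs(pos - design.dsb_pos)


def is_dsb_distal(design: VectorDesign, pos: int) -> bool:
    """True when ``pos`` lies between the DSB and the nearer homology end.

    Such positions sit beyond the DSB; the ratio rule still applies with the
    sides swapped, and reports flag them as "DSB-distal".
    """
    _check_pos(design, pos)
    L = design.total_homology
    if design.dsb_pos >= L - design.dsb_pos:  # DSB in the 3' half
        return pos > design.dsb_pos
    return pos < design.dsb_pos


def optimize_design(
    target_window_len: int,
    max_total_homology: int,
    min_arm: int,
    min_arm_dsb: int | None = None,
) -> VectorDesign:
    """Choose arm lengths maximizing worst-case retention over the target.

    Searches integer allocations of ``max_total_homology`` between the two
    arms exhaustively at 1-bp granularity (each arm at least ``min_arm``),
    placing the DSB in the shorter arm at distance
    ``min(min_arm_dsb, shorter arm length)`` from the nearer homology end
    (``min_arm_dsb`` defaults to ``min_arm``).  Returns the design whose
    minimum retention probability over the target window is largest; the
    target window is recorded as the design's ``mutagenized_window``.

    This mirrors the asymmetric-arm strategy: putting most homology on the
    productive side of the target raises retention for every target base.

    Raises
    ------
    ValueError
        If ``max_total_homology < target_window_len + 2 * min_arm``.
    """
    if min_arm <= 0 or target_window_len <= 0:
        raise ValueError("target_window_len and min_arm must be positive")
    if max_total_homology < target_window_len + 2 * min_arm:
        raise ValueError(
            f"infeasible constraints: need total homology >= "
            f"{target_window_len + 2 * min_arm}, got cap {max_total_homology}"
        )
    if min_arm_dsb is None:
        min_arm_dsb = min_arm

    L = max_total_homology
    best: tuple[float, VectorDesign] | None = None
    for len5 in range(min_arm, L - target_window_len - min_arm + 1):
        len3 = L - target_window_len - len5
        if len3 <= len5:
            # DSB in the 3' (shorter or equal) arm: every target base lies on
            # its 5' side, so the worst base is the one nearest the 5' end.
            dsb = L - min(min_arm_dsb, len3)
            worst = len5 / L
        else:
            # DSB in the 5' arm; the mirrored allocation is enumerated in the
            # branch above, so skip the boundary collision where the DSB
            # coordinate would coincide with the first target base.
            d = min(min_arm_dsb, len5)
            if d == len5:
                continue
            dsb = d
            worst = len3 / L
        window = (len5, len5 + target_window_len)
        cand = VectorDesign(len5, target_window_len, len3, dsb, window)
        if best is None or worst > best[0]:
            best = (worst, cand)
    assert best is not None
    return best[1]
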