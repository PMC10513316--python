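"""Allele-specific primer and blocker design around a single-nucleotide
substitution.

Geometry of the assay: the allele-specific primer places its 3' terminal
base exactly on the SNV and carries the mutant base, so extension from
wild-type template starts from a terminal mismatch; the blocker is fully
complementary to the wild-type sequence, spans the SNV at its center and
ends in a 3'-phosphate so it competes for the wild-type template without
priming.  Candidates can be generated on either side of the SNV:

* ``downstream`` -- the allele primer sits on the forward strand and the
  amplicon extends 3' of the SNV (paired with reverse opposite primers);
* ``upstream`` -- the allele primer is the reverse-complement strand
  ending on the SNV and the amplicon extends 5' of it.

Because a blocker with too high a melting temperature suppresses the
mutant reaction as well, candidates are scored on the Tm gap between
blocker and allele primer, with penalties for the hottest member of each
length family.  The score is an explicit, configurable heuristic: the
assay combinations ultimately used in the wet workflow were selected
empirically, and the heuristic is only expected to agree with that
choice, not to define it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, List, Literal, Optional, Sequence

from Bio.Seq import reverse_complement

from blockamp.thermo import Oligo, ThermoContext, tm as _tm

Orientation = Literal["upstream", "downstream"]

ORIENTATIONS = ("upstream", "downstream")

#: default target for (blocker Tm - allele-primer Tm), degrees C
DEFAULT_TM_GAP = 5.0
#: default penalty applied per "hottest of its family" flag
DEFAULT_FAMILY_MAX_PENALTY = 2.0


@dataclass(frozen=True)
class SnvLocus:
    """A single-nucleotide substitution with its forward-strand flanks."""

    left_flank: str
    wt_base: str
    mut_base: str
    right_flank: str

    def __post_init__(self) -> None:
        for name in ("wt_base", "mut_base"):
            b = getattr(self, name).upper()
            if len(b) != 1 or b not in "ACGT":
                raise ValueError(f"{name} must be a single ACGT base, got {b!r}")
            object.__setattr__(self, name, b)
        if self.wt_base == self.mut_base:
            raise ValueError("wt_base and mut_base must differ")
        object.__setattr__(self, "left_flank", self.left_flank.upper())
        object.__setattr__(self, "right_flank", self.right_flank.upper())

    @property
    def wt_context(self) -> str:
        return self.left_flank + self.wt_base + self.right_flank

    @property
    def mut_context(self) -> str:
        return self.left_flank + self.mut_base + self.right_flank


@dataclass(frozen=True)
class AssayCandidate:
    """One allele-primer / blocker / opposite-primer combination."""

    allele_primer: Oligo
    opposite_primer: Oligo
    blocker: Oligo
    orientation: Orientation
    tm_allele: float
    tm_blocker: float
    tm_opposite: float
    allele_is_family_max: bool = False
    blocker_is_family_max: bool = False
    score: float = 0.0


def _check_orientation(orientation: str) -> None:
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}"
        )


def make_allele_primer(
    locus: SnvLocus,
    length: int,
    orientation: Orientation,
    name: Optional[str] = None,
) -> Oligo:
    """Allele-specific primer of ``length`` whose 3' base is the mutant
    base at the SNV.

    ``downstream`` primers read the forward strand ending at the SNV;
    ``upstream`` primers are the reverse-complement strand ending at the
    SNV.  Requires length-1 bases of flank on the corresponding side.
    """
    _check_orientation(orientation)
    if length < 1:
        raise ValueError("primer length must be >= 1")
    flank = locus.left_flank if orientation == "downstream" else locus.right_flank
    if length - 1 > len(flank):
        raise ValueError(
            f"allele primer of length {length} needs {length - 1} flank bases, "
            f"only {len(flank)} available on the {orientation} side"
        )
    if orientation == "downstream":
        bases = (locus.left_flank[len(locus.left_flank) - (length - 1):]
                 if length > 1 else "") + locus.mut_base
    else:
        template = locus.mut_base + locus.right_flank[: length - 1]
        bases = reverse_complement(template)
    return Oligo(
        name=name or f"allele_{orientation}_{length}",
        bases=bases,
        role="allele_primer",
    )


def make_blocker(
    locus: SnvLocus,
    length: int,
    orientation: Orientation,
    name: Optional[str] = None,
) -> Oligo:
    """Blocker of ``length`` fully complementary to the wild-type
    sequence, SNV at the central position, 3'-phosphorylated.

    The SNV sits at position ceil(length/2) of the oligo as written
    5'->3' (exact center for odd lengths, one base 5' of center for even
    lengths).  ``downstream`` blockers are written on the forward strand,
    ``upstream`` blockers on the reverse strand.
    """
    _check_orientation(orientation)
    if length < 3:
        raise ValueError("blocker length must be >= 3 to flank the SNV")
    center = math.ceil(length / 2)  # 1-based position of the SNV in the oligo
    if orientation == "downstream":
        n_left, n_right = center - 1, length - center
    else:
        n_left, n_right = length - center, center - 1
    if n_left > len(locus.left_flank) or n_right > len(locus.right_flank):
        raise ValueError(
            f"blocker of length {length} needs {n_left}+{n_right} flank bases; "
            f"have {len(locus.left_flank)}+{len(locus.right_flank)}"
        )
    window = (
        (locus.left_flank[len(locus.left_flank) - n_left:] if n_left else "")
        + locus.wt_base
        + locus.right_flank[:n_right]
    )
    bases = window if orientation == "downstream" else reverse_complement(window)
    return Oligo(
        name=name or f"blocker_{orientation}_{length}",
        bases=bases,
        role="blocker",
        three_prime_phosphate=True,
    )


def score_candidate(
    candidate: AssayCandidate,
    target_gap_celsius: float = DEFAULT_TM_GAP,
    family_max_penalty: float = DEFAULT_FAMILY_MAX_PENALTY,
) -> float:
    """Heuristic candidate score; higher is better.

    The base score falls with the deviation of (blocker Tm - allele Tm)
    from the target gap; a fixed penalty is added when the allele primer
    (or the blocker) is the hottest member of its length family, since
    hot allele primers extend wild-type template despite the blocker and
    hot blockers suppress the mutant reaction too.
    """
    gap = candidate.tm_blocker - candidate.tm_allele
    score = -abs(gap - target_gap_celsius)
    if candidate.allele_is_family_max:
        score -= family_max_penalty
    if candidate.blocker_is_family_max:
        score -= family_max_penalty
    return score


def enumerate_candidates(
    locus: SnvLocus,
    allele_lengths: Sequence[int],
    blocker_lengths: Sequence[int],
    opposite_primers: Sequence[Oligo],
    orientation: Orientation = "downstream",
    context: ThermoContext = ThermoContext(),
    target_gap_celsius: float = DEFAULT_TM_GAP,
    family_max_penalty: float = DEFAULT_FAMILY_MAX_PENALTY,
) -> List[AssayCandidate]:
    """Cartesian product of allele primers x blockers x opposite primers
    for one orientation, with Tms, family-maximum flags and scores.

    The output size is exactly ``len(allele_lengths) * len(blocker_lengths)
    * len(opposite_primers)``; any empty input yields an empty list.
    """
    _check_orientation(orientation)
    alleles = [make_allele_primer(locus, n, orientation) for n in allele_lengths]
    blockers = [make_blocker(locus, n, orientation) for n in blocker_lengths]
    tm_a = {o.name: _tm(o, context) for o in alleles}
    tm_b = {o.name: _tm(o, context) for o in blockers}
    tm_o = {o.name: _tm(o, context) for o in opposite_primers}
    max_a = max(tm_a.values(), default=float("nan"))
    max_b = max(tm_b.values(), default=float("nan"))
    out: List[AssayCandidate] = []
    for a, b, opp in product(alleles, blockers, opposite_primers):
        cand = AssayCandidate(
            allele_primer=a,
            opposite_primer=opp,
            blocker=b,
            orientation=orientation,
            tm_allele=tm_a[a.name],
            tm_blocker=tm_b[b.name],
            tm_opposite=tm_o[opp.name],
            allele_is_family_max=(tm_a[a.name] == max_a and len(alleles) > 1),
            blocker_is_family_max=(tm_b[b.name] == max_b and len(blockers) > 1),
        )
        out.append(
            replace(
                cand,
                score=score_candidate(cand, target_gap_celsius, family_max_penalty),
            )
        )
    return out


def rank_candidates(candidates: Iterable[AssayCandidate]) -> List[AssayCandidate]:
    """Candidates sorted best-first by score; ties keep input order."""
    return sorted(candidates, key=lambda c: c.score, reverse=True)
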