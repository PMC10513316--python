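"""Nearest-neighbor duplex thermodynamics for short DNA oligos.

Melting ("phase transition") temperatures are computed with the Breslauer
1986 nearest-neighbor stacking parameters, the classic two-state formula

    Tm = dH / (dS + R ln(C/4)) - 273.15 + 16.6 log10([Na+]eq)

with a Schildkraut-Lifson monovalent-salt correction and the von
Ahsen/Owczarzy conversion of free magnesium (divalent minus dNTP) to a
monovalent equivalent.  This is the documented behaviour of the Primer3
lineage when its Breslauer table is selected, which is the calculation
the assay's oligo panel was designed under.

Default buffer: 50 mM monovalent cations, 2 mM Mg2+, 0.2 mM dNTPs,
0.4 uM oligo (PCR primer in excess over template, hence the C/4 term for
a non-self-complementary duplex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple, Union

from Bio.Seq import reverse_complement

Role = Literal["allele_primer", "opposite_primer", "blocker", "barcoded_primer"]

ROLES: Tuple[str, ...] = (
    "allele_primer",
    "opposite_primer",
    "blocker",
    "barcoded_primer",
)

#: gas constant, cal/(mol*K)
R_GAS = 1.987

# Breslauer et al. 1986 stacking parameters for helix formation,
# keyed by the 5'->3' dinucleotide of the top strand.
# delta-H in kcal/mol, delta-S in cal/(mol*K); both negative (stabilising).
NN_DELTA_H = {
    "AA": -9.1, "AC": -6.5, "AG": -7.8, "AT": -8.6,
    "CA": -5.8, "CC": -11.0, "CG": -11.9, "CT": -7.8,
    "GA": -5.6, "GC": -11.1, "GG": -11.0, "GT": -6.5,
    "TA": -6.0, "TC": -5.6, "TG": -5.8, "TT": -9.1,
}
NN_DELTA_S = {
    "AA": -24.0, "AC": -17.3, "AG": -20.8, "AT": -23.9,
    "CA": -12.9, "CC": -26.6, "CG": -27.8, "CT": -20.8,
    "GA": -13.5, "GC": -26.7, "GG": -26.6, "GT": -17.3,
    "TA": -16.9, "TC": -13.5, "TG": -12.9, "TT": -24.0,
}

#: helix-initiation entropy (e.u.); the Breslauer set carries no
#: enthalpic initiation term.
INITIATION_DELTA_S = -10.8


def _validate_bases(bases: str) -> str:
    seq = bases.upper()
    for i, b in enumerate(seq):
        if b not in "ACGT":
            raise ValueError(
                f"non-ACGT base {b!r} at position {i + 1} of {bases!r}"
            )
    return seq


@dataclass(frozen=True)
class Oligo:
    """A primer or blocker, written 5'->3'.

    A blocker carries a 3'-phosphate so it cannot be extended by the
    polymerase; this is enforced at construction.
    """

    name: str
    bases: str
    role: Role = "opposite_primer"
    three_prime_phosphate: bool = False
    five_prime_phosphate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_bases(self.bases))
        if not self.bases:
            raise ValueError(f"oligo {self.name!r} has an empty sequence")
        if self.role not in ROLES:
            raise ValueError(f"unknown oligo role {self.role!r}")
        if self.role == "blocker" and not self.three_prime_phosphate:
            raise ValueError(
                f"blocker {self.name!r} must carry a 3'-phosphate"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> str:
        return reverse_complement(self.bases)


@dataclass(frozen=True)
class ThermoContext:
    """Ion and oligo concentrations used for the Tm calculation.

    Units: mM for ions and dNTPs, uM for the oligo.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 2.0
    dntp_mM: float = 0.2
    oligo_uM: float = 0.4

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "oligo_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.oligo_uM == 0:
            raise ValueError("oligo_uM must be positive")


@dataclass(frozen=True)
class DuplexThermo:
    """Helix-formation enthalpy/entropy and the derived melting point.

    delta_H in kcal/mol (negative for any natural-base duplex), delta_S
    in cal/(mol*K) including the initiation term, tm_celsius in degrees C.
    """

    delta_H: float
    delta_S: float
    tm_celsius: float


def monovalent_equivalent(context: ThermoContext) -> float:
    """Monovalent-cation equivalent (mM) of the context's ion mix.

    Free divalent ions (Mg2+ beyond what the dNTPs chelate) are converted
    with the 120*sqrt(mM) rule of the Primer3 lineage; fully chelated
    magnesium contributes nothing.
    """
    free_divalent = max(context.divalent_mM - context.dntp_mM, 0.0)
    return context.monovalent_mM + 120.0 * math.sqrt(free_divalent)


def duplex_thermo(
    oligo: Union[Oligo, str], context: ThermoContext = ThermoContext()
) -> DuplexThermo:
    """Breslauer nearest-neighbor thermodynamics of ``oligo`` against its
    perfect complement, under ``context``.

    Raises ``ValueError`` for sequences shorter than two bases or with
    characters outside ACGT.
    """
    seq = oligo.bases if isinstance(oligo, Oligo) else _validate_bases(oligo)
    if len(seq) < 2:
        raise ValueError(
            f"need at least 2 bases for a duplex, got {len(seq)}"
        )
    dh = 0.0  # kcal/mol
    ds = INITIATION_DELTA_S  # cal/(mol*K)
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += NN_DELTA_H[pair]
        ds += NN_DELTA_S[pair]
    c_molar = context.oligo_uM * 1e-6
    tm_kelvin = (dh * 1000.0) / (ds + R_GAS * math.log(c_molar / 4.0))
    salt_molar = monovalent_equivalent(context) / 1000.0
    tm_c = tm_kelvin - 273.15 + 16.6 * math.log10(salt_molar)
    return DuplexThermo(delta_H=dh, delta_S=ds, tm_celsius=tm_c)


def tm(oligo: Union[Oligo, str], context: ThermoContext = ThermoContext()) -> float:
    """Melting temperature in degrees C (convenience wrapper)."""
    return duplex_thermo(oligo, context).tm_celsius


def rank_by_tm(
    oligos: Sequence[Oligo], context: ThermoContext = ThermoContext()
) -> List[Tuple[Oligo, float]]:
    """Oligos with their Tm, hottest first; ties keep input order."""
    scored = [(o, tm(o, context)) for o in oligos]
    return sorted(scored, key=lambda pair: pair[1], reverse=True)
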