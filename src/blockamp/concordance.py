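"""Cross-method concordance analysis for per-sample mutation calls.

Each urine-sediment sample carries a Sanger-sequencing call, a call from
the blocker-mediated PCR assay, and optionally a sequencing-derived
mutant-allele ratio (absent, printed as "n.t.", when the sample was not
sequenced).  The summary reproduces the verification-table marginals:
per-method positive counts, concordant/discordant counts, which cell of
the 2x2 table the discordances fall in, and ratio extrema by agreement
class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

Call = Literal["positive", "negative"]

_CALL_ALIASES = {
    "+": "positive",
    "-": "negative",
    "−": "negative",  # minus sign as printed in tables
    "positive": "positive",
    "negative": "negative",
    "pos": "positive",
    "neg": "negative",
}

#: dash-like characters normalised to "-" in sample ids
_DASHES = "‐‑‒–—−"


def normalize_call(value: str) -> Call:
    try:
        return _CALL_ALIASES[value.strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised call {value!r}") from None


def normalize_sample_id(sample_id: str) -> str:
    out = sample_id.strip()
    for d in _DASHES:
        out = out.replace(d, "-")
    return out


@dataclass(frozen=True)
class SampleRecord:
    """One sample's calls; ratio_percent is None when not sequenced."""

    sample_id: str
    sanger: Call
    new_method: Call
    ratio_percent: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_id", normalize_sample_id(self.sample_id))
        object.__setattr__(self, "sanger", normalize_call(self.sanger))
        object.__setattr__(self, "new_method", normalize_call(self.new_method))

    @property
    def concordant(self) -> bool:
        return self.sanger == self.new_method


@dataclass(frozen=True)
class ConcordanceSummary:
    n_total: int
    n_match: int
    n_discordant: int
    n_sanger_pos: int
    n_sanger_neg: int
    n_new_pos: int
    n_new_neg: int
    discordant_ids: Tuple[str, ...]
    ratio_min_sanger_pos: Optional[float]
    ratio_max_sanger_pos: Optional[float]
    ratio_range_discordant: Optional[Tuple[float, float]]


def _check_unique_ids(records: Sequence[SampleRecord]) -> None:
    seen = Counter(r.sample_id for r in records)
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate sample ids: {', '.join(dups)}")


def summarize(records: Sequence[SampleRecord]) -> ConcordanceSummary:
    """Concordance summary over one or more verification tables.

    Ratio extrema are computed only over records that carry a ratio;
    empty subsets yield None.  The result is invariant under record
    order.
    """
    _check_unique_ids(records)
    discordant = [r for r in records if not r.concordant]
    sanger_pos_ratios = [
        r.ratio_percent
        for r in records
        if r.sanger == "positive" and r.ratio_percent is not None
    ]
    discordant_ratios = [
        r.ratio_percent for r in discordant if r.ratio_percent is not None
    ]
    return ConcordanceSummary(
        n_total=len(records),
        n_match=sum(r.concordant for r in records),
        n_discordant=len(discordant),
        n_sanger_pos=sum(r.sanger == "positive" for r in records),
        n_sanger_neg=sum(r.sanger == "negative" for r in records),
        n_new_pos=sum(r.new_method == "positive" for r in records),
        n_new_neg=sum(r.new_method == "negative" for r in records),
        discordant_ids=tuple(sorted(r.sample_id for r in discordant)),
        ratio_min_sanger_pos=min(sanger_pos_ratios, default=None),
        ratio_max_sanger_pos=max(sanger_pos_ratios, default=None),
        ratio_range_discordant=(
            (min(discordant_ratios), max(discordant_ratios))
            if discordant_ratios
            else None
        ),
    )


def discordance_pattern(
    records: Sequence[SampleRecord],
) -> Dict[Tuple[Call, Call], int]:
    """Full 2x2 contingency counts keyed by (sanger, new_method)."""
    counts: Dict[Tuple[Call, Call], int] = {
        (s, n): 0
        for s in ("positive", "negative")
        for n in ("positive", "negative")
    }
    for r in records:
        counts[(r.sanger, r.new_method)] += 1
    return counts
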