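"""qPCR outcome classification and dilution-series sensitivity modelling.

A well's outcome is a threshold cycle (Ct, absent when nothing amplified
within the run's cycle count) and a melting-curve peak temperature.
Amplification is *specific* when a Ct exists and the melt peak falls
inside the expected product window (80-81 degrees C by default, bounds
inclusive); peaks outside that window indicate non-specific product and
are discarded.  A sample is called positive when at least one replicate
shows specific amplification at or below the Ct cutoff.

The sensitivity model is the standard log-linear qPCR response: Ct is
fit by ordinary least squares against log10(template copies) over the
specific points of a serial-dilution series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

from scipy import stats

TemplateClass = Literal["Mu", "WT", "NC1", "NC2", "unknown"]

TEMPLATE_CLASSES = ("Mu", "WT", "NC1", "NC2", "unknown")


@dataclass(frozen=True)
class QpcrRecord:
    """One well: sample, template class, Ct (or None), melt peak (or None)."""

    sample_id: str
    template_class: TemplateClass = "unknown"
    ct: Optional[float] = None
    melt_peak_celsius: Optional[float] = None
    max_cycles: int = 45

    def __post_init__(self) -> None:
        if self.template_class not in TEMPLATE_CLASSES:
            raise ValueError(f"unknown template class {self.template_class!r}")
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")
        if self.ct is not None and not (0 < self.ct <= self.max_cycles):
            raise ValueError(
                f"ct={self.ct} outside (0, {self.max_cycles}] for {self.sample_id!r}"
            )


@dataclass(frozen=True)
class MeltWindow:
    """Closed melt-peak interval accepted as the specific product."""

    low: float = 80.0
    high: float = 81.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("melt window requires low < high")


@dataclass(frozen=True)
class DiscriminationCall:
    call: Literal["positive", "negative"]
    n_specific_replicates: int
    reason: str


@dataclass(frozen=True)
class DilutionPoint:
    """One well of the serial-dilution sensitivity experiment."""

    copies: int
    ct: Optional[float]
    specific: bool


def classify_specific(record: QpcrRecord, window: MeltWindow = MeltWindow()) -> bool:
    """True iff the well amplified and its melt peak lies inside the window.

    A Ct without a melt peak cannot be confirmed as the intended product
    and is treated as non-specific.
    """
    return (
        record.ct is not None
        and record.melt_peak_celsius is not None
        and window.low <= record.melt_peak_celsius <= window.high
    )


def call_sample(
    records: Sequence[QpcrRecord],
    window: MeltWindow = MeltWindow(),
    ct_cutoff: Optional[float] = None,
) -> DiscriminationCall:
    """Positive/negative call for one sample from its replicate wells.

    A single replicate with specific amplification at ct <= ct_cutoff is
    sufficient for a positive call.  The default cutoff is the run's
    cycle count; a 90-cycle screening run should normally be called with
    an explicit, stricter cutoff.
    """
    if not records:
        raise ValueError("call_sample needs at least one record")
    if ct_cutoff is None:
        ct_cutoff = max(r.max_cycles for r in records)
    fired = [
        r
        for r in records
        if classify_specific(r, window) and r.ct is not None and r.ct <= ct_cutoff
    ]
    n = len(fired)
    if n:
        ids = ", ".join(
            f"{r.sample_id} (ct={r.ct:.1f}, peak={r.melt_peak_celsius:.1f})"
            for r in sorted(fired, key=lambda r: (r.ct, r.sample_id))
        )
        reason = f"specific amplification at ct <= {ct_cutoff:g} in: {ids}"
    else:
        reason = (
            f"no specific amplification at ct <= {ct_cutoff:g} "
            f"in {len(records)} replicate(s)"
        )
    return DiscriminationCall(
        call="positive" if n >= 1 else "negative",
        n_specific_replicates=n,
        reason=reason,
    )


def build_dilution_series(start_copies: int, fold: float, steps: int) -> List[int]:
    """Copy numbers of a ``steps``-point serial dilution.

    Element i is round(start_copies / fold**i); e.g. a three-fold series
    from 9000 copies runs 9000, 3000, 1000, 333, 111, 37.
    """
    if start_copies < 1:
        raise ValueError("start_copies must be >= 1")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    # round half away from zero so x.5 boundaries never depend on parity
    return [int(math.floor(start_copies / fold**i + 0.5)) for i in range(steps)]


def fit_ct_vs_logcopies(
    points: Sequence[DilutionPoint],
) -> Tuple[float, float, float]:
    """OLS fit of Ct on log10(copies) over the specific, amplified points.

    Returns (slope, intercept, Pearson r).  Non-specific wells and wells
    that never amplified are excluded before fitting; at least two usable
    points are required.
    """
    usable = [
        p for p in points if p.specific and p.ct is not None and p.copies > 0
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 specific amplified points to fit, got {len(usable)}"
        )
    x = [math.log10(p.copies) for p in usable]
    y = [p.ct for p in usable]
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
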