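"""Synthetic inputs for every pipeline stage.

The generator replaces all wet-lab inputs: amplicon templates stitched
from the published oligo panel, standard-sample compositions, barcoded
nanopore-style reads with a per-base error model, and qPCR records with
a log-linear Ct response and melt-peak behaviour.

The fixture templates are *designed* sequences, not the genomic BRAF
locus: every published primer, blocker and annealing part occurs in them
character-exactly with the correct geometry around the T>A substitution,
but the stretches between those landmarks (unpublished) are fixed
arbitrary filler.  Spacers are chosen so the sequenced amplicon region
(annealing-part start through reverse-primer site) is exactly 137 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import reverse_complement

from blockamp.design import SnvLocus
from blockamp.nanopore_count import AlleleSignature, BarcodeSpec
from blockamp.qpcr_calls import DilutionPoint, QpcrRecord, TemplateClass

# ---------------------------------------------------------------------------
# fixture templates

# landmark segments recovered by stitching the published oligos
_SEG_UPSTREAM = "TCCTTTACTTACTACACCTCAGATATTTTTCTTCA"  # F1 merged with F2/F3
_SEG_LEFT_OF_SNV = "GATTTTGGTCTAGCCACAG"  # F6 minus its 3' (mutant) base
_SEG_RIGHT_OF_SNV = "GAAATCTCGATGGAGTGG"  # BF3 right arm merged with R3 site
_SEG_R45_SITE = "CCATTTCTCCATTAATTAAA"  # reverse-complement of R5 (R4 nested)
_SEG_R678_SITE = "ATTTTGTGGATGGTAAGAATTG"  # consensus of R6/R7/R8 sites

# fixed arbitrary spacers standing in for the unpublished genomic stretches;
# lengths make the annealing-start..reverse-primer-end region exactly 137 bp
_SPACER_1 = "CTCAAGCGGTAC"
_SPACER_2 = "TGACCGTTAGCA"
_SPACER_3 = "GTTCAACGGATC"

WT_BASE = "T"
MU_BASE = "A"

#: start of the nanopore annealing part (= primer F3) within the
#: detection template
_NANOPORE_START = len(_SEG_UPSTREAM) - 21


@dataclass(frozen=True)
class AmpliconTemplate:
    """Paired wild-type/mutant template strands differing at one offset."""

    name: str
    wt_seq: str
    mu_seq: str
    snv_offset: int

    def __post_init__(self) -> None:
        if len(self.wt_seq) != len(self.mu_seq):
            raise ValueError("wt_seq and mu_seq must have equal length")
        diffs = [
            i for i, (a, b) in enumerate(zip(self.wt_seq, self.mu_seq)) if a != b
        ]
        if diffs != [self.snv_offset]:
            raise ValueError(
                f"templates must differ exactly at snv_offset={self.snv_offset}, "
                f"found differences at {diffs}"
            )

    @property
    def wt_base(self) -> str:
        return self.wt_seq[self.snv_offset]

    @property
    def mut_base(self) -> str:
        return self.mu_seq[self.snv_offset]


def build_fixture_templates() -> Tuple[AmpliconTemplate, AmpliconTemplate]:
    """(detection, nanopore) templates for the whole pipeline.

    The detection template spans all selection primers (F1 through the
    R6-R8 site); the nanopore template is its 137-bp sub-region from the
    annealing part through the reverse-primer site.
    """
    left = _SEG_UPSTREAM + _SPACER_1 + _SEG_LEFT_OF_SNV
    right = (
        _SEG_RIGHT_OF_SNV + _SPACER_2 + _SEG_R45_SITE + _SPACER_3 + _SEG_R678_SITE
    )
    wt = left + WT_BASE + right
    mu = left + MU_BASE + right
    offset = len(left)
    detection = AmpliconTemplate("detection", wt, mu, offset)
    nanopore = AmpliconTemplate(
        "nanopore",
        wt[_NANOPORE_START:],
        mu[_NANOPORE_START:],
        offset - _NANOPORE_START,
    )
    return detection, nanopore


def fixture_locus() -> SnvLocus:
    """The fixture SNV with its full flanks, for the design module."""
    detection, _ = build_fixture_templates()
    return SnvLocus(
        left_flank=detection.wt_seq[: detection.snv_offset],
        wt_base=WT_BASE,
        mut_base=MU_BASE,
        right_flank=detection.wt_seq[detection.snv_offset + 1 :],
    )


def default_signature(k: int = 11) -> AlleleSignature:
    """SNV-centered k-mer signatures from the nanopore template.

    k=11 is long enough to be unique within the 137-bp amplicon (and to
    not collide with the barcode/pad parts) yet short enough to survive
    read errors reasonably often.  ``k`` must be odd and small enough
    not to overlap the annealing or reverse-primer parts.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("signature length k must be odd and >= 3")
    _, nano = build_fixture_templates()
    half = k // 2
    lo, hi = nano.snv_offset - half, nano.snv_offset + half + 1
    if lo < 21 or hi > len(nano.wt_seq) - 20:
        raise ValueError(f"k={k} overlaps the primer annealing regions")
    return AlleleSignature(
        wt_signature=nano.wt_seq[lo:hi], mu_signature=nano.mu_seq[lo:hi]
    )


# ---------------------------------------------------------------------------
# standard samples

@dataclass(frozen=True)
class StandardSample:
    """A template DNA solution mimicking a canine genome extract.

    Mu and WT carry 1.8e4 plasmid copies/uL (mutant or wild-type insert)
    in 50 ng/uL carrier salmon-sperm DNA; NC1 is carrier only; NC2 is
    water.
    """

    label: str
    mutant_copies_per_uL: float
    wildtype_copies_per_uL: float
    carrier_ng_per_uL: float

    def __post_init__(self) -> None:
        for name in (
            "mutant_copies_per_uL",
            "wildtype_copies_per_uL",
            "carrier_ng_per_uL",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


STANDARD_COPIES_PER_UL = 1.8e4
CARRIER_NG_PER_UL = 50.0


def standard_mu() -> StandardSample:
    return StandardSample("Mu", STANDARD_COPIES_PER_UL, 0.0, CARRIER_NG_PER_UL)


def standard_wt() -> StandardSample:
    return StandardSample("WT", 0.0, STANDARD_COPIES_PER_UL, CARRIER_NG_PER_UL)


def standard_nc1() -> StandardSample:
    return StandardSample("NC1", 0.0, 0.0, CARRIER_NG_PER_UL)


def standard_nc2() -> StandardSample:
    return StandardSample("NC2", 0.0, 0.0, 0.0)


def mix_standards(
    a: StandardSample, b: StandardSample, ratio: float = 0.5
) -> StandardSample:
    """Volume-mix two standards; ``ratio`` is the volume fraction of ``a``.

    Equal mixing of Mu and WT yields 9000 mutant copies/uL, the top of
    the sensitivity dilution series.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if ratio == 1.0:
        return a
    if ratio == 0.0:
        return b
    label = a.label if a.label == b.label else f"mix({a.label},{b.label})"
    w = ratio
    return StandardSample(
        label=label,
        mutant_copies_per_uL=w * a.mutant_copies_per_uL
        + (1 - w) * b.mutant_copies_per_uL,
        wildtype_copies_per_uL=w * a.wildtype_copies_per_uL
        + (1 - w) * b.wildtype_copies_per_uL,
        carrier_ng_per_uL=w * a.carrier_ng_per_uL + (1 - w) * b.carrier_ng_per_uL,
    )


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the barcoded-read simulator.

    Error rates are per base.  The substitution default is deliberately
    low: with exact signature matching, a substitution landing on the
    SNV is the only error mode that can convert a wild-type read into an
    apparent mutant, and the assay's observed floor on mutant-free
    samples (a measured ratio of 0.0% at >= 1000 reads, with true
    positives resolved down to 0.1%) bounds that mode to well below
    1e-3 per read.  The indel defaults carry the bulk of the error
    budget, as in homopolymer-dominated nanopore error profiles.
    """

    n_reads: int = 1000
    true_mu_fraction: float = 0.0
    sub_rate: float = 1e-4
    ins_rate: float = 2e-3
    del_rate: float = 3e-3
    p_forward: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_mu_fraction <= 1.0:
            raise ValueError("true_mu_fraction must be in [0, 1]")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.p_forward <= 1.0:
            raise ValueError("p_forward must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def _apply_errors(seq: str, cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    if cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
        return seq
    out: List[str] = []
    u = rng.random(len(seq))
    for i, base in enumerate(seq):
        if u[i] < cfg.del_rate:
            continue  # deletion
        if u[i] < cfg.del_rate + cfg.sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
        if rng.random() < cfg.ins_rate:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def simulate_reads(
    template: AmpliconTemplate,
    barcode: BarcodeSpec,
    config: ReadSimConfig,
) -> List[Tuple[str, str, str]]:
    """Simulate barcoded amplicon reads as (id, sequence, quality) triples.

    Each read is the assembled amplicon (pad + barcode + template body,
    which starts with the annealing part) from the mutant strand with
    probability ``true_mu_fraction``, with per-base substitution /
    insertion / deletion errors applied, reverse-complemented with
    probability 1 - p_forward.  Deterministic for a fixed seed; quality
    strings are constant placeholders (classification is sequence-only).
    """
    rng = np.random.default_rng(config.seed)
    prefix = barcode.pad_seq + barcode.barcode_seq
    # template body already starts with the annealing part
    fwd_wt = prefix + template.wt_seq
    fwd_mu = prefix + template.mu_seq
    reads: List[Tuple[str, str, str]] = []
    is_mu = rng.random(config.n_reads) < config.true_mu_fraction
    is_fwd = rng.random(config.n_reads) < config.p_forward
    for i in range(config.n_reads):
        seq = fwd_mu if is_mu[i] else fwd_wt
        seq = _apply_errors(seq, config, rng)
        if not is_fwd[i]:
            seq = reverse_complement(seq)
        reads.append((f"{barcode.barcode_id}_read{i:06d}", seq, "I" * len(seq)))
    return reads


# ---------------------------------------------------------------------------
# qPCR simulation

@dataclass(frozen=True)
class QpcrSimConfig:
    """Parameters of the qPCR simulator.

    The specific reaction follows ct = intercept + slope*log10(copies)
    with Gaussian cycle noise; the intercept default puts 9000 mutant
    copies at Ct ~ 30.  Wild-type and negative-control wells normally do
    not amplify; with probability ``wt_breakthrough_prob`` they show a
    breakthrough event, either late specific amplification (ct > 60) or
    non-specific product melting outside the specific window.
    """

    slope: float = -3.32  # cycles per log10(copies)
    intercept: float = 43.13  # cycles; 9000 copies -> ~30
    ct_noise_sd: float = 0.3
    wt_breakthrough_prob: float = 0.02
    specific_peak_mean: float = 80.5
    specific_peak_sd: float = 0.12
    nonspecific_peak_range: Tuple[float, float] = (73.0, 79.0)
    max_cycles: int = 90
    blocker_uM: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")
        if not 0.0 <= self.wt_breakthrough_prob <= 1.0:
            raise ValueError("wt_breakthrough_prob must be in [0, 1]")
        if self.blocker_uM not in (0.4, 1.2):
            raise ValueError("blocker_uM must be 0.4 or 1.2 (tested regimes)")


def simulate_qpcr(
    template_class: TemplateClass,
    mutant_copies: float,
    config: QpcrSimConfig = QpcrSimConfig(),
    rng: Optional[np.random.Generator] = None,
    sample_id: Optional[str] = None,
) -> QpcrRecord:
    """Simulate one well.

    Wells with mutant template amplify specifically on the log-linear
    curve; wells without mutant template (WT, NC1, NC2, or zero copies)
    do not amplify except for rare breakthrough events, which are late
    or non-specific and therefore removed by the downstream call logic.
    """
    if mutant_copies < 0:
        raise ValueError("mutant_copies must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sid = sample_id or f"{template_class}:{mutant_copies:g}"
    ct: Optional[float] = None
    peak: Optional[float] = None
    if mutant_copies > 0 and template_class in ("Mu", "unknown"):
        ct = (
            config.intercept
            + config.slope * math.log10(mutant_copies)
            + rng.normal(0.0, config.ct_noise_sd)
        )
        peak = rng.normal(config.specific_peak_mean, config.specific_peak_sd)
        if ct > config.max_cycles:
            ct = peak = None
    elif rng.random() < config.wt_breakthrough_prob:
        if rng.random() < 0.5:  # late specific breakthrough
            ct = rng.uniform(60.0, config.max_cycles)
            peak = rng.normal(config.specific_peak_mean, config.specific_peak_sd)
        else:  # non-specific product
            ct = rng.uniform(30.0, config.max_cycles)
            peak = rng.uniform(*config.nonspecific_peak_range)
    if ct is not None:
        ct = min(ct, config.max_cycles)
    return QpcrRecord(
        sample_id=sid,
        template_class=template_class,
        ct=ct,
        melt_peak_celsius=peak,
        max_cycles=config.max_cycles,
    )


def simulate_dilution_run(
    copies_series: Sequence[int],
    config: QpcrSimConfig = QpcrSimConfig(),
    replicates: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> List[DilutionPoint]:
    """Simulate a serial-dilution sensitivity run (Mu template wells)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    points: List[DilutionPoint] = []
    from blockamp.qpcr_calls import MeltWindow, classify_specific

    window = MeltWindow()
    for copies in copies_series:
        for _ in range(replicates):
            rec = simulate_qpcr("Mu", copies, config, rng=rng)
            points.append(
                DilutionPoint(
                    copies=copies,
                    ct=rec.ct,
                    specific=classify_specific(rec, window),
                )
            )
    return points


def simulate_qpcr_screen(
    config: QpcrSimConfig = QpcrSimConfig(),
    mutant_copies: float = 1.0e4,
    replicates: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[QpcrRecord]]:
    """Simulate one primer/blocker screening experiment.

    Returns records for the four template classes: Mu amplifies early
    and specifically; WT, NC1 and NC2 amplify never, late, or
    non-specifically.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: Dict[str, List[QpcrRecord]] = {}
    for label in ("Mu", "WT", "NC1", "NC2"):
        copies = mutant_copies if label == "Mu" else 0.0
        out[label] = [
            simulate_qpcr(label, copies, config, rng=rng, sample_id=f"{label}_{i}")
            for i in range(replicates)
        ]
    return out
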